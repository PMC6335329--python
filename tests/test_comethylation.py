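import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import comethdiff as cd
from comethdiff.io import BetaMatrix

from conftest import scalar_pair_oracle


def _pheno(n_control, n_case):
    return pd.DataFrame(
        {
            "sample_id": [f"c{i}" for i in range(n_control)]
            + [f"t{i}" for i in range(n_case)],
            "group": ["control"] * n_control + ["case"] * n_case,
        }
    )


def _gene_matrix(values, pheno):
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i:03d}" for i in range(values.shape[0])],
            columns=pheno["sample_id"],
        ),
        level="gene",
    )


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([0.1, 0.5, 0.3, 0.9])
        assert cd.pearson(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_exact_negative_linear_relation(self):
        assert cd.pearson(
            np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.3, 0.2])
        ) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_evaluated_formula_value(self):
        # deviations (-0.1, 0, 0.1) vs (-0.1, 0.1, 0); S_x = S_y = 0.1
        # r = (1/2) * 0.01 / 0.01 = 0.5
        r = cd.pearson(np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.3, 0.2]))
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        r = cd.pearson(np.array([0.4, 0.4, 0.4]), np.array([0.1, 0.2, 0.3]))
        assert np.isnan(r)

    def test_length_mismatch_and_short_input_raise(self):
        with pytest.raises(ValueError, match="mismatch"):
            cd.pearson(np.array([0.1, 0.2]), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError, match="at least 2"):
            cd.pearson(np.array([0.1]), np.array([0.2]))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_numpy_corrcoef(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.uniform(0, 1, n)
        y = rng.uniform(0, 1, n)
        assert cd.pearson(x, y) == pytest.approx(
            float(np.corrcoef(x, y)[0, 1]), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(0, 1, 20)
        a = float(rng.uniform(0.1, 3.0))
        b = float(rng.uniform(-1.0, 1.0))
        r = cd.pearson(x, y)
        assert cd.pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert cd.pearson(a * x + b, y) == pytest.approx(r, abs=1e-12)
        assert cd.pearson(-a * x + b, y) == pytest.approx(-r, abs=1e-12)


class TestCountPairs:
    def test_cohort_scale_pair_count(self):
        assert cd.count_pairs(21_225) == 225_239_700

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 0), (2, 1), (100, 4950)])
    def test_small_counts_match_enumeration(self, n, expected):
        assert cd.count_pairs(n) == expected
        assert expected == sum(1 for i in range(n) for _ in range(i + 1, n))


class TestAllPairs:
    def test_two_genes_give_one_row(self):
        pheno = _pheno(3, 3)
        rng = np.random.default_rng(0)
        m = _gene_matrix(rng.uniform(0, 1, (2, 6)), pheno)
        pairs = cd.all_pairs_correlations(m, pheno)
        assert len(pairs) == 1

    @pytest.mark.parametrize("chunk_size", [1, 7, 50])
    def test_chunk_size_does_not_change_results(self, chunk_size):
        pheno = _pheno(20, 25)
        rng = np.random.default_rng(1)
        m = _gene_matrix(rng.uniform(0, 1, (50, 45)), pheno)
        base = cd.all_pairs_correlations(m, pheno, chunk_size=50)
        other = cd.all_pairs_correlations(m, pheno, chunk_size=chunk_size)
        np.testing.assert_allclose(
            other[["r_control", "r_case"]], base[["r_control", "r_case"]],
            rtol=0, atol=1e-10,
        )

    def test_matches_scalar_oracle(self):
        pheno = _pheno(8, 9)
        rng = np.random.default_rng(2)
        m = _gene_matrix(rng.uniform(0, 1, (12, 17)), pheno)
        got = cd.all_pairs_correlations(m, pheno, chunk_size=5)
        expect = scalar_pair_oracle(m, pheno)
        pd.testing.assert_frame_equal(
            got[["gene1", "gene2"]], expect[["gene1", "gene2"]]
        )
        np.testing.assert_allclose(
            got[["r_control", "r_case"]], expect[["r_control", "r_case"]],
            rtol=0, atol=1e-10,
        )

    def test_enumeration_is_upper_triangle_of_sorted_genes(self, small_pairs):
        assert (small_pairs["gene1"] < small_pairs["gene2"]).all()
        assert not small_pairs.duplicated(["gene1", "gene2"]).any()
        genes = sorted(set(small_pairs["gene1"]) | set(small_pairs["gene2"]))
        assert len(small_pairs) == cd.count_pairs(len(genes))

    def test_zero_variance_gene_yields_undefined_rows(self):
        pheno = _pheno(4, 4)
        vals = np.random.default_rng(3).uniform(0, 1, (3, 8))
        vals[1] = 0.5  # constant gene in both conditions
        m = _gene_matrix(vals, pheno)
        pairs = cd.all_pairs_correlations(m, pheno)
        undef = pairs[pairs["gene1"].eq("g001") | pairs["gene2"].eq("g001")]
        assert undef["r_control"].isna().all()
        assert undef["r_case"].isna().all()

    def test_small_phenotype_group_is_an_error(self):
        pheno = _pheno(1, 5)
        m = _gene_matrix(np.random.default_rng(4).uniform(0, 1, (3, 6)), pheno)
        with pytest.raises(ValueError, match="fewer than 2"):
            cd.all_pairs_correlations(m, pheno)

    def test_missing_cells_fail_fast_with_count(self):
        pheno = _pheno(4, 4)
        vals = np.random.default_rng(5).uniform(0, 1, (3, 8))
        vals[0, 0] = np.nan
        vals[2, 5] = np.nan
        m = _gene_matrix(vals, pheno)
        with pytest.raises(ValueError, match="2 missing"):
            cd.all_pairs_correlations(m, pheno)

    def test_pairwise_mode_uses_complete_samples_per_pair(self):
        pheno = _pheno(6, 6)
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 1, (3, 12))
        vals[0, 2] = np.nan
        m = _gene_matrix(vals, pheno)
        pairs = cd.all_pairs_correlations(m, pheno, missing="pairwise")
        # oracle: pair (g000, g001) on control samples excluding c2
        mask = [i for i in range(6) if i != 2]
        expect = cd.pearson(vals[0, mask], vals[1, mask])
        got = pairs.set_index(["gene1", "gene2"]).loc[("g000", "g001"), "r_control"]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_estimator_is_unbiased_enough_at_known_rho(self):
        # mean of r-hat over 200 replicates within 3 SE of rho
        rho, n = 0.6, 80
        rng = np.random.default_rng(9)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(cov)
        estimates = []
        for _ in range(200):
            z = rng.standard_normal((n, 2)) @ chol.T
            estimates.append(cd.pearson(z[:, 0], z[:, 1]))
        se = (1 - rho**2) / np.sqrt(n)
        assert abs(np.mean(estimates) - rho) < 3 * se


class TestSummarizeDistribution:
    def test_simple_mean_and_sd(self):
        s = cd.summarize_distribution(np.array([-1.0, 0.0, 1.0]), n_bins=4)
        assert s.mean_r == pytest.approx(0.0)
        assert s.sd_r == pytest.approx(1.0)
        assert s.counts.sum() == s.n_pairs == 3

    def test_constant_values(self):
        s = cd.summarize_distribution(np.full(10, 0.5))
        assert s.mean_r == pytest.approx(0.5)
        assert s.sd_r == pytest.approx(0.0)

    def test_matches_two_pass_oracle_on_simulated_values(self):
        rng = np.random.default_rng(12)
        r = np.clip(rng.normal(0.2, 0.3, 10_000), -1, 1)
        s = cd.summarize_distribution(r, n_bins=20)
        mean = sum(r) / len(r)
        sd = (sum((v - mean) ** 2 for v in r) / (len(r) - 1)) ** 0.5
        assert s.mean_r == pytest.approx(mean, abs=1e-12)
        assert s.sd_r == pytest.approx(sd, abs=1e-12)
        assert s.counts.sum() == 10_000

    def test_nan_values_are_dropped_and_all_nan_raises(self):
        s = cd.summarize_distribution(np.array([0.1, np.nan, 0.3]))
        assert s.n_pairs == 2
        with pytest.raises(ValueError, match="no defined"):
            cd.summarize_distribution(np.array([np.nan]))
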