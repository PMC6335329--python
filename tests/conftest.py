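import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import comethdiff as cd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """50 genes, two correlated blocks and one injected differential pair."""
    spec = cd.SimulationSpec(
        n_genes=50,
        n_case=120,
        n_control=100,
        blocks=(cd.Block(0, 10, 0.5, 0.5), cd.Block(10, 20, 0.3, 0.6)),
        differential_pairs=(cd.DifferentialPair(25, 40, -0.6, 0.4),),
        seed=11,
    )
    matrix, phenotypes, truth = cd.generate(spec)
    return spec, matrix, phenotypes, truth


@pytest.fixture(scope="session")
def small_pairs(small_sim):
    _, matrix, phenotypes, _ = small_sim
    return cd.all_pairs_correlations(matrix, phenotypes, chunk_size=16)


@pytest.fixture()
def beta_frame():
    rng = np.random.default_rng(3)
    values = rng.uniform(0.05, 0.95, size=(6, 8))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )


def scalar_pair_oracle(matrix, phenotypes):
    """Brute-force per-pair correlation table via the scalar pearson."""
    from comethdiff.io import group_samples

    order = sorted(matrix.feature_ids)
    rows = []
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            row = {"gene1": order[a], "gene2": order[b]}
            for cond in ("control", "case"):
                samples = group_samples(phenotypes, cond)
                x = matrix.values.loc[order[a], samples].to_numpy(dtype=float)
                y = matrix.values.loc[order[b], samples].to_numpy(dtype=float)
                row[f"r_{cond}"] = cd.pearson(x, y)
            rows.append(row)
    return pd.DataFrame(rows)
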