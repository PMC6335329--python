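"""The co-methylation coefficient: Pearson correlation of gene-level beta values.

For genes i and j measured across the n samples of one condition, the
co-methylation coefficient is the sample Pearson correlation

    r(i, j) = (1 / (n - 1)) * sum_k [ (b_ik - mean_i) / S_i ] [ (b_jk - mean_j) / S_j ]

with S the (n - 1)-denominator standard deviation.  r > 0 means the two
genes' methylation levels rise and fall together (co-methylation); r < 0
means they move oppositely.  r is undefined when either gene is constant
(S = 0); undefined values are carried as NaN and counted, never silently
propagated into downstream interval counts.

The all-pairs engine evaluates every unordered gene pair in both
conditions via chunked standardized matrix products, so the full gene x
gene correlation matrix is never materialized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, check_phenotypes_match, group_samples

#: clamp tolerance for |r| slightly exceeding 1 through float rounding
R_CLAMP_TOL = 1e-12


def count_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n*(n-1)/2 in exact integer arithmetic."""
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    return n_genes * (n_genes - 1) // 2


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length vectors (two-pass, (n-1) SDs).

    Returns NaN when either vector has zero variance.  Values are clamped
    to [-1, 1] only within a 1e-12 floating tolerance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    # a bitwise-constant vector has S = 0 even when float rounding of the
    # mean leaves a tiny nonzero residual
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx) / (n - 1))
    sy = math.sqrt(float(dy @ dy) / (n - 1))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(dx @ dy) / ((n - 1) * sx * sy)
    if r > 1.0:
        if r > 1.0 + R_CLAMP_TOL:
            raise FloatingPointError(f"correlation {r} exceeds 1 beyond tolerance")
        r = 1.0
    elif r < -1.0:
        if r < -1.0 - R_CLAMP_TOL:
            raise FloatingPointError(f"correlation {r} below -1 beyond tolerance")
        r = -1.0
    return r


def _standardize(values: np.ndarray) -> np.ndarray:
    """Rows scaled to mean 0 and unit (n-1)-SD; zero-variance rows become NaN."""
    n = values.shape[1]
    centered = values - values.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1, keepdims=True) / (n - 1))
    constant = np.ptp(values, axis=1, keepdims=True) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / sd
    z[np.broadcast_to((sd == 0.0) | constant, z.shape)] = np.nan
    return z


def _pair_index_arrays(n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n_genes, k=1)
    return i, j


def all_pairs_correlations(
    genes: BetaMatrix,
    phenotypes: pd.DataFrame,
    chunk_size: int = 512,
    missing: str = "error",
) -> pd.DataFrame:
    """Correlation of every unordered gene pair, separately per condition.

    Returns a DataFrame with columns ``gene1, gene2, r_control, r_case``,
    one row per pair, enumerated row-major over the upper triangle of the
    lexicographically sorted gene list (so gene1 < gene2 and the order is
    reproducible).  Results are independent of ``chunk_size``.

    ``missing='error'`` (default) rejects matrices with missing cells,
    reporting how many there are; ``missing='pairwise'`` computes each pair
    on the samples where both genes are defined (scalar path, intended for
    desk-scale matrices).
    """
    if genes.level != "gene":
        raise ValueError("expected a gene-level matrix")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if missing not in ("error", "pairwise"):
        raise ValueError(f"missing must be 'error' or 'pairwise', got {missing!r}")
    check_phenotypes_match(genes, phenotypes)

    order = genes.feature_ids.sort_values()
    g = len(order)
    if g < 2:
        raise ValueError("need at least 2 genes")
    frame = genes.values.loc[order]

    cond_values: dict[str, np.ndarray] = {}
    for cond in ("control", "case"):
        samples = [s for s in group_samples(phenotypes, cond) if s in genes.sample_ids]
        if len(samples) < 2:
            raise ValueError(f"phenotype group {cond!r} has fewer than 2 samples")
        cond_values[cond] = frame[samples].to_numpy(dtype=float)

    if missing == "error":
        n_missing = sum(int(np.isnan(v).sum()) for v in cond_values.values())
        if n_missing:
            raise ValueError(
                f"{n_missing} missing cell(s) in the matrix; complete data required "
                "(pass missing='pairwise' to use pairwise-complete samples)"
            )

    i_idx, j_idx = _pair_index_arrays(g)
    result: dict[str, np.ndarray] = {}
    for cond, values in cond_values.items():
        if missing == "pairwise" and np.isnan(values).any():
            result[cond] = _pairwise_complete(values, i_idx, j_idx)
        else:
            result[cond] = _chunked_upper_triangle(values, chunk_size, i_idx, j_idx)

    gene_arr = order.to_numpy()
    return pd.DataFrame(
        {
            "gene1": gene_arr[i_idx],
            "gene2": gene_arr[j_idx],
            "r_control": result["control"],
            "r_case": result["case"],
        }
    )


def _chunked_upper_triangle(
    values: np.ndarray, chunk_size: int, i_idx: np.ndarray, j_idx: np.ndarray
) -> np.ndarray:
    g, n = values.shape
    z = _standardize(values)
    out = np.empty(i_idx.shape[0], dtype=float)
    # row-major upper-triangle offsets: pair (i, j) sits at a fixed position,
    # so each row block writes a contiguous slice
    pos = 0
    for start in range(0, g, chunk_size):
        stop = min(start + chunk_size, g)
        block = z[start:stop] @ z.T / (n - 1)  # (stop-start) x g
        for i in range(start, stop):
            row = block[i - start, i + 1 :]
            out[pos : pos + row.shape[0]] = row
            pos += row.shape[0]
    assert pos == out.shape[0]
    np.clip(out, -1.0, 1.0, out=out)
    return out


def _pairwise_complete(
    values: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray
) -> np.ndarray:
    out = np.empty(i_idx.shape[0], dtype=float)
    for k in range(i_idx.shape[0]):
        x = values[i_idx[k]]
        y = values[j_idx[k]]
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 2:
            out[k] = np.nan
            continue
        out[k] = pearson(x[mask], y[mask])
    return out


@dataclass
class CorrelationSummary:
    """Mean/SD and histogram of one condition's defined pair correlations."""

    n_pairs: int
    mean_r: float
    sd_r: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def summarize_distribution(r_values: np.ndarray, n_bins: int = 40) -> CorrelationSummary:
    """Mean, (n-1)-SD and an equal-width histogram over [-1, 1].

    Undefined (NaN) correlations are dropped; raises if none are defined.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no defined correlations to summarize")
    mean = float(r.mean())
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    counts, edges = np.histogram(r, bins=n_bins, range=(-1.0, 1.0))
    return CorrelationSummary(
        n_pairs=int(r.size), mean_r=mean, sd_r=sd, bin_edges=edges, counts=counts
    )
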