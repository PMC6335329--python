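"""Subsampling repeatability of pair correlations versus sample size.

The experiment: take disjoint groups of genes; for each group and each
sample size n, draw two disjoint sets of n samples from one condition,
compute all within-group pair correlations on each replicate, and report
the Pearson correlation between the two replicate pair-correlation vectors.
High agreement means the co-methylation estimates are stable at that n;
agreement typically rises toward 1 as n grows.

Randomness comes from one master seed; each (group, n) cell uses a
deterministic substream, so the curve is reproducible and independent of
evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comethylation import pearson
from .io import BetaMatrix, check_phenotypes_match, group_samples

logger = logging.getLogger(__name__)


@dataclass
class RepeatabilityConfig:
    """Design of the subsampling experiment.

    Defaults follow the original design: 5 disjoint groups of 100 genes,
    sample sizes spanning 2..150.
    """

    n_groups: int = 5
    group_size: int = 100
    sample_sizes: tuple[int, ...] = tuple(range(2, 151))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("every sample size must be >= 2")


def _replicate_pair_vector(values: np.ndarray) -> np.ndarray:
    """Upper-triangle pair correlations of a gene x sample block."""
    n = values.shape[1]
    centered = values - values.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1, keepdims=True) / (n - 1))
    constant = np.ptp(values, axis=1, keepdims=True) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / sd
    z[np.broadcast_to((sd == 0.0) | constant, z.shape)] = np.nan
    corr = z @ z.T / (n - 1)
    iu = np.triu_indices(values.shape[0], k=1)
    return np.clip(corr[iu], -1.0, 1.0)


def run_repeatability(
    genes: BetaMatrix,
    phenotypes: pd.DataFrame,
    group: str,
    cfg: RepeatabilityConfig,
) -> pd.DataFrame:
    """Replicate-agreement curve per gene group and sample size.

    Returns a DataFrame with columns ``group`` (1-based), ``n``,
    ``agreement`` (NaN where degenerate, e.g. a constant replicate vector)
    and ``n_pairs_used`` (pairs defined in both replicates).
    """
    if genes.level != "gene":
        raise ValueError("expected a gene-level matrix")
    check_phenotypes_match(genes, phenotypes)
    genes.require_complete()
    samples = [s for s in group_samples(phenotypes, group) if s in genes.sample_ids]
    n_avail = len(samples)
    max_n = max(cfg.sample_sizes)
    if 2 * max_n > n_avail:
        raise ValueError(
            f"sample size {max_n} needs 2*{max_n} samples but only {n_avail} "
            f"are available in group {group!r}"
        )
    gene_ids = genes.feature_ids.sort_values()
    if cfg.n_groups * cfg.group_size > len(gene_ids):
        raise ValueError(
            f"{cfg.n_groups} groups of {cfg.group_size} genes exceed the "
            f"{len(gene_ids)} genes available"
        )

    master = np.random.default_rng(np.random.SeedSequence([cfg.seed]))
    chosen = master.choice(len(gene_ids), cfg.n_groups * cfg.group_size, replace=False)
    gene_groups = chosen.reshape(cfg.n_groups, cfg.group_size)

    data = genes.values.loc[gene_ids, samples].to_numpy(dtype=float)

    rows = []
    for g_idx in range(cfg.n_groups):
        block = data[gene_groups[g_idx]]
        for n in cfg.sample_sizes:
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, g_idx, n]))
            draw = rng.choice(n_avail, 2 * n, replace=False)
            rep1, rep2 = draw[:n], draw[n:]
            assert not set(rep1) & set(rep2)
            v1 = _replicate_pair_vector(block[:, rep1])
            v2 = _replicate_pair_vector(block[:, rep2])
            mask = ~(np.isnan(v1) | np.isnan(v2))
            n_used = int(mask.sum())
            if n_used < 2:
                agreement = np.nan
            else:
                x, y = v1[mask], v2[mask]
                if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                    agreement = np.nan  # constant vector: agreement undefined
                else:
                    agreement = pearson(x, y)
            if n_used < v1.shape[0]:
                logger.debug(
                    "group %d n=%d: dropped %d undefined pair(s)",
                    g_idx + 1,
                    n,
                    v1.shape[0] - n_used,
                )
            rows.append(
                {
                    "group": g_idx + 1,
                    "n": n,
                    "agreement": agreement,
                    "n_pairs_used": n_used,
                }
            )
    return pd.DataFrame(rows)
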