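"""Synthetic beta-value matrices with controlled pairwise correlation structure.

Samples are drawn per condition from a multivariate normal whose
correlation matrix is assembled from correlated blocks plus explicitly
injected differential pairs, then each gene is mapped into a (lo, hi)
sub-interval of (0, 1) by an increasing affine (min-max) rescale.  Affine
maps preserve sample Pearson correlations exactly, so the emitted beta
matrix realizes the requested co-methylation structure while staying inside
the beta-value bounds.  Realistic 450K marginal shapes (bimodal beta
mixtures), batch effects and cell-composition confounding are deliberately
not modelled: the pipeline's statistics depend only on correlations.

Defaults mirror a blood-methylation case/control cohort: a few hundred
genes and case/control arms of 354 and 335 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import DEFAULT_SCHEME, assign_interval
from .io import BetaMatrix, ProbeGeneMap

PSD_TOL = 1e-8


@dataclass(frozen=True)
class Block:
    """Genes [start, stop) share a common pairwise correlation per condition."""

    start: int
    stop: int
    r_control: float
    r_case: float


@dataclass(frozen=True)
class DifferentialPair:
    """One gene pair with explicit correlation targets per condition."""

    gene_i: int
    gene_j: int
    r_control: float
    r_case: float


@dataclass
class SimulationSpec:
    n_genes: int = 300
    n_case: int = 354
    n_control: int = 335
    blocks: tuple[Block, ...] = ()
    differential_pairs: tuple[DifferentialPair, ...] = ()
    probes_per_gene: int = 3
    probe_noise_sd: float = 0.02
    beta_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.beta_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("beta_range must satisfy 0 < lo < hi < 1")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if min(self.n_case, self.n_control) < 2:
            raise ValueError("each condition needs at least 2 samples")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")
        for b in self.blocks:
            if not (0 <= b.start < b.stop <= self.n_genes):
                raise ValueError(f"block range [{b.start}, {b.stop}) out of bounds")
        for p in self.differential_pairs:
            if p.gene_i == p.gene_j:
                raise ValueError("a differential pair needs two distinct genes")
            if not (0 <= p.gene_i < self.n_genes and 0 <= p.gene_j < self.n_genes):
                raise ValueError("differential pair gene index out of bounds")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: target matrices and injected pairs."""

    target_control: pd.DataFrame
    target_case: pd.DataFrame
    differential_pairs: pd.DataFrame  # gene1, gene2, targets, target bins/distance


def _assemble_target(
    spec: SimulationSpec, condition: str, repair_psd: bool
) -> np.ndarray:
    g = spec.n_genes
    sigma = np.eye(g)
    for b in spec.blocks:
        r = b.r_control if condition == "control" else b.r_case
        sl = slice(b.start, b.stop)
        sigma[sl, sl] = r
        np.fill_diagonal(sigma[sl, sl], 1.0)
    for p in spec.differential_pairs:
        r = p.r_control if condition == "control" else p.r_case
        sigma[p.gene_i, p.gene_j] = r
        sigma[p.gene_j, p.gene_i] = r
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] < -PSD_TOL:
        if not repair_psd:
            raise ValueError(
                f"target correlation matrix for {condition} is not positive "
                f"semi-definite (smallest eigenvalue {eigvals[0]:.3e}); "
                "adjust targets or enable repair_psd"
            )
        sigma = _nearest_psd(sigma)
    return sigma


def _nearest_psd(sigma: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at 1e-10 followed by correlation re-normalization."""
    w, v = np.linalg.eigh(sigma)
    w = np.clip(w, 1e-10, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _sample_condition(
    sigma: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    # cholesky with a tiny jitter to tolerate semidefinite (repaired) targets
    g = sigma.shape[0]
    jitter = 1e-10
    for _ in range(6):
        try:
            chol = np.linalg.cholesky(sigma + jitter * np.eye(g))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:  # pragma: no cover - targets are PSD-validated upstream
        raise np.linalg.LinAlgError("could not factor target correlation matrix")
    z = rng.standard_normal((n, g))
    return z @ chol.T  # n x g


def _minmax_rescale(latent: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-gene increasing affine map of columns into [lo, hi]."""
    mins = latent.min(axis=0, keepdims=True)
    maxs = latent.max(axis=0, keepdims=True)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    return lo + (hi - lo) * (latent - mins) / span


def generate(
    spec: SimulationSpec, repair_psd: bool = False
) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a two-condition gene-level beta matrix plus ground truth.

    Returns ``(beta, phenotypes, truth)`` where ``beta`` holds case and
    control samples side by side, ``phenotypes`` labels them, and ``truth``
    records the target correlation matrices and each injected differential
    pair with its target interval distance.  Bit-identical for a fixed spec.
    """
    genes = spec.gene_names()
    arrays = {}
    targets = {}
    for idx, (cond, n) in enumerate(
        (("control", spec.n_control), ("case", spec.n_case))
    ):
        sigma = _assemble_target(spec, cond, repair_psd)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        arrays[cond] = _sample_condition(sigma, n, rng)
        targets[cond] = sigma

    lo, hi = spec.beta_range
    latent = np.vstack([arrays["control"], arrays["case"]])  # samples x genes
    beta = _minmax_rescale(latent, lo, hi)

    sample_ids = [f"ctrl_{k:04d}" for k in range(spec.n_control)] + [
        f"case_{k:04d}" for k in range(spec.n_case)
    ]
    values = pd.DataFrame(beta.T, index=pd.Index(genes, name="ID"), columns=sample_ids)
    matrix = BetaMatrix(values, level="gene")
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["control"] * spec.n_control + ["case"] * spec.n_case,
        }
    )

    pair_rows = []
    for p in spec.differential_pairs:
        g1, g2 = sorted((genes[p.gene_i], genes[p.gene_j]))
        b1 = assign_interval(p.r_control, DEFAULT_SCHEME)
        b2 = assign_interval(p.r_case, DEFAULT_SCHEME)
        pair_rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "r_control_target": p.r_control,
                "r_case_target": p.r_case,
                "bin_control_target": b1,
                "bin_case_target": b2,
                "target_distance": abs(b2 - b1),
            }
        )
    truth = SyntheticTruth(
        target_control=pd.DataFrame(targets["control"], index=genes, columns=genes),
        target_case=pd.DataFrame(targets["case"], index=genes, columns=genes),
        differential_pairs=pd.DataFrame(
            pair_rows,
            columns=[
                "gene1",
                "gene2",
                "r_control_target",
                "r_case_target",
                "bin_control_target",
                "bin_case_target",
                "target_distance",
            ],
        ),
    )
    return matrix, phenotypes, truth


def expand_to_probes(
    genes: BetaMatrix, spec: SimulationSpec
) -> tuple[BetaMatrix, ProbeGeneMap]:
    """Emit ``probes_per_gene`` noisy probe copies of each gene plus the map.

    Each probe is the gene value plus independent Gaussian noise of SD
    ``probe_noise_sd``, clipped to [0, 1]; with zero noise, averaging the
    probes back recovers the gene matrix exactly.
    """
    if genes.level != "gene":
        raise ValueError("expected a gene-level matrix")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    k = spec.probes_per_gene
    if k < 1:
        raise ValueError("probes_per_gene must be >= 1")
    gene_ids = list(genes.feature_ids)
    base = genes.values.to_numpy(dtype=float)
    tiled = np.repeat(base, k, axis=0)
    if spec.probe_noise_sd > 0:
        tiled = tiled + rng.normal(0.0, spec.probe_noise_sd, size=tiled.shape)
        np.clip(tiled, 0.0, 1.0, out=tiled)
    probe_ids = [f"{g}_p{j}" for g in gene_ids for j in range(k)]
    values = pd.DataFrame(
        tiled, index=pd.Index(probe_ids, name="ID"), columns=genes.sample_ids
    )
    mapping = pd.DataFrame(
        {"probe_id": probe_ids, "gene": np.repeat(gene_ids, k)}
    )
    return BetaMatrix(values, level="probe"), ProbeGeneMap(mapping)
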