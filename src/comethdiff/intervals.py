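"""Eight-interval correlation binning and control-to-case transition matrices.

Correlations are divided into eight fixed intervals of width 0.25, from
"strongest negative correlation" [-1, -0.75) up to "strongest positive
correlation" [0.75, 1].  Bins 1-7 are half-open [a, b); bin 8 is closed so
that r = 1 is representable.  A gene pair's change between conditions is
summarized by its interval distance |bin_case - bin_control| (the number of
intervals it "crossed"); pairs crossing at least three intervals are the
large-change pairs of interest.

The transition matrix counts pairs by (control bin, case bin); its row
percentages describe, for pairs starting in a given control interval, where
they end up in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EDGES: tuple[float, ...] = (-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_LABELS: tuple[str, ...] = (
    "strongest negative correlation",
    "strong negative correlation",
    "weak negative correlation",
    "weakest negative correlation",
    "weakest positive correlation",
    "weak positive correlation",
    "strong positive correlation",
    "strongest positive correlation",
)

_EDGE_TOL = 1e-12


@dataclass(frozen=True)
class IntervalScheme:
    """A strictly increasing edge sequence defining len(edges)-1 bins.

    Bin indices are 1-based.  All bins are half-open [a, b) except the last,
    which is closed so the upper endpoint is assignable.
    """

    edges: tuple[float, ...] = DEFAULT_EDGES
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("edges must be strictly increasing with >= 2 entries")
        if len(self.labels) != self.n_bins:
            raise ValueError(
                f"{len(self.labels)} labels for {self.n_bins} bins"
            )

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_label(self, index: int) -> str:
        return self.labels[index - 1]

    def bin_bounds(self, index: int) -> str:
        lo, hi = self.edges[index - 1], self.edges[index]
        close = "]" if index == self.n_bins else ")"
        return f"[{lo:g},{hi:g}{close}"


DEFAULT_SCHEME = IntervalScheme()


def assign_interval(r: float, scheme: IntervalScheme = DEFAULT_SCHEME) -> int:
    """1-based bin index of a correlation value; raises on NaN or out-of-range."""
    if np.isnan(r):
        raise ValueError("undefined correlation has no interval; exclude it first")
    return int(assign_intervals(np.array([r]), scheme)[0])


def assign_intervals(
    r: np.ndarray, scheme: IntervalScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Vectorized bin assignment.  NaN entries raise; use a mask upstream."""
    r = np.asarray(r, dtype=float)
    if np.isnan(r).any():
        raise ValueError("undefined correlation has no interval; exclude it first")
    lo, hi = scheme.edges[0], scheme.edges[-1]
    if (r < lo - _EDGE_TOL).any() or (r > hi + _EDGE_TOL).any():
        bad = r[(r < lo - _EDGE_TOL) | (r > hi + _EDGE_TOL)][0]
        raise ValueError(f"correlation {bad} outside [{lo}, {hi}]")
    clipped = np.clip(r, lo, hi)
    inner = np.asarray(scheme.edges[1:-1], dtype=float)
    bins = np.searchsorted(inner, clipped, side="right") + 1
    bins[clipped >= hi] = scheme.n_bins  # closed top bin
    return bins.astype(np.int64)


def interval_distance(bin_control: int, bin_case: int) -> int:
    """Number of intervals crossed between conditions: |bin_case - bin_control|."""
    return abs(int(bin_case) - int(bin_control))


@dataclass
class TransitionMatrix:
    """Counts of pairs by (control bin, case bin), rows = control."""

    counts: np.ndarray
    n_excluded: int = 0
    scheme: IntervalScheme = field(default_factory=IntervalScheme)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.scheme.n_bins
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.n_excluded < 0:
            raise ValueError("n_excluded must be non-negative")

    @property
    def n_pairs(self) -> int:
        """Total input pairs: counted + excluded-as-undefined."""
        return int(self.counts.sum()) + self.n_excluded

    @property
    def row_percentages(self) -> np.ndarray:
        """100 * count / row sum; rows with zero sum are NaN."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)

    def _labels(self, prefix: str) -> list[str]:
        return [
            f"{prefix}_{self.scheme.bin_bounds(i)}"
            for i in range(1, self.scheme.n_bins + 1)
        ]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self._labels("control"), columns=self._labels("case")
        )

    def percentages_frame(self, decimals: int = 5) -> pd.DataFrame:
        return pd.DataFrame(
            np.round(self.row_percentages, decimals),
            index=self._labels("control"),
            columns=self._labels("case"),
        )


def annotate_pairs(
    pairs: pd.DataFrame, scheme: IntervalScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Add bin_control, bin_case, interval_distance and delta columns.

    Pairs with an undefined correlation in either condition get NA bins and
    distance; delta = r_case - r_control where both are defined.
    """
    out = pairs.copy()
    rc = out["r_control"].to_numpy(dtype=float)
    ra = out["r_case"].to_numpy(dtype=float)
    defined = ~(np.isnan(rc) | np.isnan(ra))
    bc = np.full(len(out), pd.NA, dtype=object)
    ba = np.full(len(out), pd.NA, dtype=object)
    dist = np.full(len(out), pd.NA, dtype=object)
    if defined.any():
        b1 = assign_intervals(rc[defined], scheme)
        b2 = assign_intervals(ra[defined], scheme)
        bc[defined] = b1
        ba[defined] = b2
        dist[defined] = np.abs(b2 - b1)
    out["bin_control"] = pd.array(bc, dtype="Int64")
    out["bin_case"] = pd.array(ba, dtype="Int64")
    out["interval_distance"] = pd.array(dist, dtype="Int64")
    out["delta"] = ra - rc
    return out


def build_transition_matrix(
    pairs: pd.DataFrame, scheme: IntervalScheme = DEFAULT_SCHEME
) -> TransitionMatrix:
    """Count pairs by (control bin, case bin); undefined pairs excluded and counted."""
    rc = pairs["r_control"].to_numpy(dtype=float)
    ra = pairs["r_case"].to_numpy(dtype=float)
    defined = ~(np.isnan(rc) | np.isnan(ra))
    n_excluded = int((~defined).sum())
    k = scheme.n_bins
    if defined.any():
        bc = assign_intervals(rc[defined], scheme) - 1
        ba = assign_intervals(ra[defined], scheme) - 1
        flat = np.bincount(bc * k + ba, minlength=k * k)
        counts = flat.reshape(k, k)
    else:
        counts = np.zeros((k, k), dtype=np.int64)
    if n_excluded:
        logger.info("transition matrix: excluded %d undefined pair(s)", n_excluded)
    return TransitionMatrix(counts=counts, n_excluded=n_excluded, scheme=scheme)


def _distance_mask(k: int, exact: int | None = None, minimum: int | None = None):
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    d = np.abs(i - j)
    return d == exact if exact is not None else d >= minimum


def count_by_min_distance(tm: TransitionMatrix, k: int) -> int:
    """Pairs whose interval distance is at least k."""
    if not 0 <= k <= tm.scheme.n_bins - 1:
        raise ValueError(f"k must be in 0..{tm.scheme.n_bins - 1}")
    return int(tm.counts[_distance_mask(tm.scheme.n_bins, minimum=k)].sum())


def count_by_exact_distance(tm: TransitionMatrix, k: int) -> int:
    """Pairs whose interval distance is exactly k."""
    if not 0 <= k <= tm.scheme.n_bins - 1:
        raise ValueError(f"k must be in 0..{tm.scheme.n_bins - 1}")
    return int(tm.counts[_distance_mask(tm.scheme.n_bins, exact=k)].sum())


def extract_large_change_pairs(
    pairs: pd.DataFrame,
    scheme: IntervalScheme = DEFAULT_SCHEME,
    min_distance: int = 3,
) -> pd.DataFrame:
    """Pairs whose correlation crossed at least ``min_distance`` intervals.

    Returns the annotated subset (bin, distance and delta columns included);
    pairs undefined in either condition are never large-change pairs.
    """
    if not 1 <= min_distance <= scheme.n_bins - 1:
        raise ValueError(f"min_distance must be in 1..{scheme.n_bins - 1}")
    annotated = annotate_pairs(pairs, scheme)
    keep = annotated["interval_distance"].ge(min_distance).fillna(False)
    return annotated[keep].reset_index(drop=True)


def filter_by_delta(pairs: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Keep pairs with |r_case - r_control| strictly greater than threshold.

    Ties at exactly the threshold are excluded and logged: with printed
    3-decimal correlations a pair can sit exactly on the boundary even when
    its unrounded difference exceeds it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    delta = pairs["delta"].to_numpy(dtype=float)
    absd = np.abs(delta)
    n_boundary = int(np.sum(absd == threshold))
    if n_boundary:
        logger.warning(
            "delta filter: %d pair(s) at exactly |delta| == %g were excluded "
            "(strict > comparison)",
            n_boundary,
            threshold,
        )
    keep = absd > threshold
    keep &= ~np.isnan(delta)
    return pairs[keep].reset_index(drop=True)
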