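"""Intersect large-change pair sets across diseases and export gene lists.

A pair is identified by its lexicographically sorted symbol tuple, so the
intersection is order-invariant.  By default the intersection is on pair
identity only; ``require_same_direction=True`` additionally demands that the
sign of the control-to-case correlation change agree in both diseases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import canonicalize_pairs


def intersect_pairs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    require_same_direction: bool = False,
) -> pd.DataFrame:
    """Shared pairs of two large-change sets, correlations from both carried.

    Returns a table with columns ``gene1, gene2, r_control_a, r_case_a,
    delta_a, r_control_b, r_case_b, delta_b`` sorted by (gene1, gene2).
    """
    cols = ["gene1", "gene2", "r_control", "r_case"]
    left = canonicalize_pairs(a.loc[:, [c for c in a.columns if c in cols + ["delta"]]])
    right = canonicalize_pairs(b.loc[:, [c for c in b.columns if c in cols + ["delta"]]])
    for side in (left, right):
        if "delta" not in side.columns:
            side["delta"] = side["r_case"] - side["r_control"]
    merged = left.merge(right, on=["gene1", "gene2"], suffixes=("_a", "_b"))
    if require_same_direction:
        same = np.sign(merged["delta_a"]) == np.sign(merged["delta_b"])
        merged = merged[same]
    return merged.sort_values(["gene1", "gene2"], kind="mergesort").reset_index(
        drop=True
    )


def unique_genes(pairs: pd.DataFrame) -> list[str]:
    """Sorted de-duplicated union of the gene1 and gene2 columns."""
    if pairs.empty:
        return []
    return sorted(set(pairs["gene1"]) | set(pairs["gene2"]))
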