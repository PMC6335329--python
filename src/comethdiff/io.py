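"""Readers and writers for beta matrices, phenotypes, probe annotations and pair tables.

Input side: tab-separated matrices of methylation beta values (features in
rows, samples in columns, values in [0, 1]), either as a plain TSV or in the
GEO series-matrix dialect ("!"-prefixed metadata lines around a
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` block); a
two-column sample phenotype table (case/control); and a platform annotation
table mapping probe IDs to gene symbols (semicolon-delimited multi-gene
cells, GPL13534-style).

Output side: pair tables (one row per unordered gene pair with the
correlation in each condition plus interval annotations) and labeled 8x8
transition matrices, both as TSV.

Missing values: readers accept ``NA`` / empty cells as missing.  A
:class:`BetaMatrix` carries them as NaN; analyses that need a complete
matrix fail fast with a count of offending cells (see
:func:`comethdiff.comethylation.all_pairs_correlations`).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BETA_BOUND_TOL = 1e-9

#: Canonical column order of a written pair table.
PAIR_TABLE_COLUMNS = (
    "gene1",
    "gene2",
    "r_control",
    "r_case",
    "bin_control",
    "bin_case",
    "interval_distance",
    "delta",
)

_MISSING_TOKENS = {"", "na", "nan", "null"}
_GROUP_TOKENS = {"case": "case", "control": "control"}


class FormatError(ValueError):
    """Structural problem in an input file (duplicates, missing columns...)."""


class BetaValidationError(ValueError):
    """A beta value violates the [0, 1] bound or is not numeric."""


@dataclass
class BetaMatrix:
    """Feature x sample grid of methylation beta values.

    ``values`` is a DataFrame indexed by feature ID (probe ID or gene
    symbol) with sample IDs as columns; ``level`` records whether rows are
    probes or genes.  All defined values lie in [0, 1]; missing cells are
    NaN.
    """

    values: pd.DataFrame
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        validate_beta_frame(self.values)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def require_complete(self) -> None:
        """Raise if any cell is missing (fail-fast policy)."""
        n = self.n_missing
        if n:
            raise BetaValidationError(
                f"beta matrix contains {n} missing cell(s); complete data required "
                "(use missing='pairwise' where supported, or impute upstream)"
            )


def validate_beta_frame(frame: pd.DataFrame) -> None:
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated feature ids: {dups[:5]}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicated sample ids: {dups[:5]}")
    arr = frame.to_numpy(dtype=float, copy=False)
    bad = (arr < -BETA_BOUND_TOL) | (arr > 1.0 + BETA_BOUND_TOL)
    bad &= ~np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise BetaValidationError(
            f"beta value {arr[i, j]!r} outside [0, 1] at feature "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )


def _strip_quotes(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] == '"':
        token = token[1:-1]
    return token


def _series_matrix_payload(text: str) -> str:
    """Extract the data table from a GEO series-matrix file."""
    lines = text.splitlines()
    begin = end = None
    for k, line in enumerate(lines):
        low = line.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            begin = k
        elif low.startswith("!series_matrix_table_end"):
            end = k
    if begin is not None:
        payload = lines[begin + 1 : end if end is not None else len(lines)]
    else:  # tolerate files with metadata but no sentinels
        payload = [ln for ln in lines if not ln.startswith("!")]
    return "\n".join(payload)


def read_beta_matrix(
    path: str | Path,
    dialect: str = "plain_tsv",
    level: str = "probe",
) -> BetaMatrix:
    """Read a beta-value matrix from TSV.

    ``dialect='series_matrix'`` skips "!"-prefixed metadata lines and the
    table begin/end sentinels and strips GEO's double quotes.  Cells equal
    to ``NA`` or empty are read as missing; any other non-numeric cell is a
    parse error naming its location.
    """
    if dialect not in ("plain_tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text(encoding="utf-8")
    if dialect == "series_matrix":
        text = _series_matrix_payload(text)
    raw = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    raw.index = pd.Index([_strip_quotes(str(x)) for x in raw.index], name=raw.index.name)
    raw.columns = pd.Index([_strip_quotes(str(c)) for c in raw.columns])

    numeric = pd.DataFrame(
        np.empty(raw.shape), index=raw.index, columns=raw.columns, dtype=float
    )
    for j, col in enumerate(raw.columns):
        cells = raw[col].map(lambda v: _strip_quotes(v) if isinstance(v, str) else v)
        mask_missing = cells.isna() | cells.astype(str).str.strip().str.lower().isin(
            _MISSING_TOKENS
        )
        converted = pd.to_numeric(cells.where(~mask_missing), errors="coerce")
        bad = converted.isna() & ~mask_missing
        if bad.any():
            feat = raw.index[np.flatnonzero(bad)[0]]
            raise FormatError(
                f"non-numeric cell {cells[bad].iloc[0]!r} at feature {feat!r}, "
                f"sample {col!r}"
            )
        numeric.iloc[:, j] = converted.to_numpy(dtype=float)
    matrix = BetaMatrix(numeric, level=level)
    # snap float fuzz at the bounds so downstream arithmetic stays in [0, 1]
    matrix.values.clip(lower=0.0, upper=1.0, inplace=True)
    return matrix


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="ID", na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a two-column (sample_id, group) table; group is case/control.

    Group tokens are matched case-insensitively.  Returns a DataFrame with
    columns ``sample_id`` and ``group`` (normalized to lower case).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in table.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise FormatError(
            f"phenotype table must have columns sample_id and group; got {list(table.columns)}"
        )
    out = pd.DataFrame(
        {
            "sample_id": table[cols["sample_id"]].str.strip(),
            "group": table[cols["group"]].str.strip().str.lower(),
        }
    )
    unknown = sorted(set(out["group"]) - set(_GROUP_TOKENS))
    if unknown:
        raise FormatError(
            f"unknown group token(s) {unknown}; accepted tokens: case, control"
        )
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise FormatError(f"duplicate sample id(s): {dups[:5]}")
    return out


def group_samples(phenotypes: pd.DataFrame, group: str) -> list[str]:
    """Sample IDs belonging to one phenotype group, in table order."""
    if group not in _GROUP_TOKENS:
        raise ValueError(f"group must be case or control, got {group!r}")
    return phenotypes.loc[phenotypes["group"] == group, "sample_id"].tolist()


def check_phenotypes_match(matrix: BetaMatrix, phenotypes: pd.DataFrame) -> None:
    missing = set(matrix.sample_ids) - set(phenotypes["sample_id"])
    if missing:
        raise FormatError(
            f"{len(missing)} matrix sample(s) missing from phenotype table, "
            f"e.g. {sorted(missing)[:3]}"
        )


@dataclass
class ProbeGeneMap:
    """Long-form probe -> gene mapping with one row per (probe, gene).

    ``table`` has columns ``probe_id`` and ``gene``; a probe annotated to
    several genes occupies several rows.  ``n_dropped`` counts probes whose
    gene field was empty in the source annotation.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["probe_id", "gene"]:
            raise FormatError("ProbeGeneMap table must have columns probe_id, gene")
        if self.table.duplicated().any():
            raise FormatError("duplicate (probe, gene) rows in annotation")

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"].unique())

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.table["gene"].unique()))


def read_probe_annotation(
    path: str | Path,
    probe_col: str = "ID",
    gene_col: str = "UCSC_RefGene_Name",
) -> ProbeGeneMap:
    """Read a platform annotation table mapping probes to gene symbols.

    Multi-gene cells are ";"-delimited and de-duplicated per probe
    (platform files repeat a symbol once per transcript).  Probes with an
    empty gene field are dropped and counted.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in (probe_col, gene_col):
        if col not in table.columns:
            raise FormatError(
                f"annotation missing required column {col!r}; has {list(table.columns)}"
            )
    if table[probe_col].duplicated().any():
        raise FormatError("duplicate probe ids in annotation")
    records: list[tuple[str, str]] = []
    n_dropped = 0
    for probe, cell in zip(table[probe_col], table[gene_col]):
        if not isinstance(cell, str) or not cell.strip():
            n_dropped += 1
            continue
        seen: list[str] = []
        for sym in cell.split(";"):
            sym = sym.strip()
            if sym and sym not in seen:
                seen.append(sym)
        if not seen:
            n_dropped += 1
            continue
        records.extend((probe.strip(), sym) for sym in seen)
    if n_dropped:
        logger.info("annotation: dropped %d probe(s) with empty gene field", n_dropped)
    out = pd.DataFrame(records, columns=["probe_id", "gene"])
    return ProbeGeneMap(out, n_dropped=n_dropped)


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with gene1 < gene2 lexicographically in every row."""
    out = pairs.copy()
    flip = out["gene1"] > out["gene2"]
    if flip.any():
        g1 = out.loc[flip, "gene2"].to_numpy()
        g2 = out.loc[flip, "gene1"].to_numpy()
        out.loc[flip, "gene1"] = g1
        out.loc[flip, "gene2"] = g2
    return out


def write_pair_table(pairs: pd.DataFrame, path: str | Path, scheme=None) -> None:
    """Write a pair table as TSV with the fixed column set.

    Accepts a bare correlation table (gene1, gene2, r_control, r_case) or an
    already annotated large-change set; interval columns are computed when
    absent.  Rows are canonicalized so gene1 < gene2.  Undefined values are
    written as ``NA``.
    """
    from .intervals import DEFAULT_SCHEME, annotate_pairs

    out = canonicalize_pairs(pairs)
    if "interval_distance" not in out.columns:
        out = annotate_pairs(out, scheme or DEFAULT_SCHEME)
    out = out.loc[:, list(PAIR_TABLE_COLUMNS)]
    # %.17g round-trips doubles exactly, so read(write(x)) == x
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a pair table written by :func:`write_pair_table`."""
    table = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = set(PAIR_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"pair table missing column(s): {sorted(missing)}")
    for col in ("bin_control", "bin_case", "interval_distance"):
        table[col] = table[col].astype("Int64")
    return table


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    """One gene symbol per line, for external enrichment tools."""
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
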