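"""Collapse probe-level beta values to gene-level values.

A gene's methylation value in a sample is the arithmetic mean of the beta
values of all probes annotated to that gene, mirroring how 450K array
studies summarize multi-probe genes.  Probes annotated to several genes
contribute to every listed gene by default (platform annotation semantics);
``multi_gene='drop'`` discards them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import BetaMatrix, ProbeGeneMap

logger = logging.getLogger(__name__)


@dataclass
class GeneAggregationReport:
    n_probes_in: int
    n_probes_mapped: int
    n_genes_out: int
    probes_per_gene: pd.Series  # index = gene symbol, value = probe count

    def __post_init__(self) -> None:
        assert self.n_probes_mapped <= self.n_probes_in
        assert self.n_genes_out == len(self.probes_per_gene)


def aggregate_probes_to_genes(
    probes: BetaMatrix,
    probe_map: ProbeGeneMap,
    multi_gene: str = "all",
) -> tuple[BetaMatrix, GeneAggregationReport]:
    """Average each gene's probes per sample; returns the gene matrix and a report.

    Probes absent from the map are dropped (and counted in the report).
    The mean is taken over available (non-missing) probe values per sample;
    a gene-sample cell with no available probe is missing.  Gene order in
    the output is lexicographic.
    """
    if probes.level != "probe":
        raise ValueError("input matrix must be probe-level")
    if multi_gene not in ("all", "drop"):
        raise ValueError(f"multi_gene must be 'all' or 'drop', got {multi_gene!r}")

    mapping = probe_map.table
    if multi_gene == "drop":
        counts = mapping.groupby("probe_id")["gene"].transform("size")
        mapping = mapping[counts == 1]

    mapping = mapping[mapping["probe_id"].isin(probes.feature_ids)]
    if mapping.empty:
        raise ValueError("no mappable probes: matrix and annotation do not overlap")

    values = probes.values.loc[mapping["probe_id"].to_numpy()]
    grouped = values.groupby(mapping["gene"].to_numpy())
    gene_values = grouped.mean().sort_index()  # skips NaN per cell
    gene_values.index.name = probes.values.index.name

    n_mapped = mapping["probe_id"].nunique()
    n_in = len(probes.feature_ids)
    if n_mapped < n_in:
        logger.info("aggregation: dropped %d unmapped probe(s)", n_in - n_mapped)
    report = GeneAggregationReport(
        n_probes_in=n_in,
        n_probes_mapped=n_mapped,
        n_genes_out=gene_values.shape[0],
        probes_per_gene=grouped.size().sort_index(),
    )
    return BetaMatrix(gene_values, level="gene"), report
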