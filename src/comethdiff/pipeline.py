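"""End-to-end two-disease run: correlate, classify transitions, intersect.

For each disease the pipeline produces the gene-level matrix (if probe
input), the all-pairs correlation table, transition count and percentage
matrices, and the large-change pair set; across diseases it produces the
shared-pair table, the delta-filtered table and the unique gene list.  A
manifest records parameters and the row counts of every output so
conservation identities can be audited after the fact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comethylation import all_pairs_correlations, summarize_distribution
from .cross_disease import intersect_pairs, unique_genes
from .gene_level import aggregate_probes_to_genes
from .intervals import (
    DEFAULT_SCHEME,
    IntervalScheme,
    build_transition_matrix,
    extract_large_change_pairs,
    filter_by_delta,
)
from .io import (
    BetaMatrix,
    ProbeGeneMap,
    read_beta_matrix,
    read_phenotypes,
    read_probe_annotation,
    write_gene_list,
    write_pair_table,
)

logger = logging.getLogger(__name__)


@dataclass
class DiseaseInput:
    name: str
    beta_path: str
    phenotype_path: str
    dialect: str = "plain_tsv"
    level: str = "gene"
    annotation_path: str | None = None  # required when level == "probe"


@dataclass
class RunConfig:
    disease_a: DiseaseInput
    disease_b: DiseaseInput
    out_dir: str
    min_distance: int = 3
    delta_threshold: float = 0.8
    chunk_size: int = 512
    scheme: IntervalScheme = field(default_factory=IntervalScheme)


def _analyze_disease(
    inp: DiseaseInput, cfg: RunConfig, out: Path, manifest: dict
) -> pd.DataFrame:
    matrix = read_beta_matrix(inp.beta_path, dialect=inp.dialect, level=inp.level)
    phenotypes = read_phenotypes(inp.phenotype_path)
    if inp.level == "probe":
        if not inp.annotation_path:
            raise ValueError(f"{inp.name}: probe-level input needs annotation_path")
        pmap = read_probe_annotation(inp.annotation_path)
        matrix, report = aggregate_probes_to_genes(matrix, pmap)
        manifest[f"{inp.name}.n_probes_mapped"] = report.n_probes_mapped
        manifest[f"{inp.name}.n_genes"] = report.n_genes_out
        gene_path = out / f"{inp.name}_genes.tsv"
        matrix.values.to_csv(gene_path, sep="\t", index_label="ID")

    pairs = all_pairs_correlations(matrix, phenotypes, chunk_size=cfg.chunk_size)
    write_pair_table(pairs, out / f"{inp.name}_pairs.tsv", scheme=cfg.scheme)
    manifest[f"{inp.name}.n_pairs"] = len(pairs)

    for cond in ("r_control", "r_case"):
        summary = summarize_distribution(pairs[cond].to_numpy())
        manifest[f"{inp.name}.{cond}.mean"] = round(summary.mean_r, 6)
        manifest[f"{inp.name}.{cond}.sd"] = round(summary.sd_r, 6)

    tm = build_transition_matrix(pairs, cfg.scheme)
    tm.counts_frame().to_csv(out / f"{inp.name}_transitions_counts.tsv", sep="\t")
    tm.percentages_frame().to_csv(out / f"{inp.name}_transitions_pct.tsv", sep="\t")
    manifest[f"{inp.name}.n_excluded_undefined"] = tm.n_excluded
    assert tm.n_pairs == len(pairs), "pair-count conservation violated"

    large = extract_large_change_pairs(pairs, cfg.scheme, cfg.min_distance)
    write_pair_table(large, out / f"{inp.name}_large_change.tsv", scheme=cfg.scheme)
    manifest[f"{inp.name}.n_large_change"] = len(large)
    return large


def run_full_pipeline(cfg: RunConfig) -> Path:
    """Run both diseases and the cross-disease comparison; returns the out dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "min_distance": cfg.min_distance,
        "delta_threshold": cfg.delta_threshold,
        "chunk_size": cfg.chunk_size,
    }

    large = {}
    for inp in (cfg.disease_a, cfg.disease_b):
        logger.info("pipeline: analyzing %s", inp.name)
        large[inp.name] = _analyze_disease(inp, cfg, out, manifest)

    a, b = cfg.disease_a.name, cfg.disease_b.name
    shared = intersect_pairs(large[a], large[b])
    shared.to_csv(out / "shared_pairs.tsv", sep="\t", index=False, na_rep="NA")
    manifest["n_shared_pairs"] = len(shared)

    filtered = {
        name: filter_by_delta(table, cfg.delta_threshold)
        for name, table in large.items()
    }
    for name, table in filtered.items():
        write_pair_table(table, out / f"{name}_delta_filtered.tsv", scheme=cfg.scheme)
        manifest[f"{name}.n_delta_filtered"] = len(table)
    shared_filtered = intersect_pairs(filtered[a], filtered[b])
    shared_filtered.to_csv(
        out / "shared_delta_filtered.tsv", sep="\t", index=False, na_rep="NA"
    )
    manifest["n_shared_delta_filtered"] = len(shared_filtered)

    genes = unique_genes(shared)
    write_gene_list(genes, out / "shared_unique_genes.txt")
    manifest["n_unique_genes"] = len(genes)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out
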