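# Methods

## The co-methylation coefficient

The unit of analysis is the gene-level methylation beta value: for each
gene and sample, the arithmetic mean of the beta values of all probes
annotated to the gene. No probe filtering (detection p-values, SNP or
cross-reactive probe lists), M-value transformation, or cell-composition
adjustment is applied: inputs are assumed to be normalized beta matrices,
and the analysis operates on them as given. Probes annotated to several
genes contribute to each (the annotation's own semantics); a `drop` mode
discards ambiguous probes for sensitivity analysis.

Co-methylation of genes *i* and *j* within one condition is the sample
Pearson correlation with (n−1)-denominator standard deviations,

r(i,j) = (n−1)⁻¹ Σₖ [(b_ik − b̄_i)/S_i][(b_jk − b̄_j)/S_j].

This is the ordinary sample correlation; it is implemented directly in the
two-pass form above and cross-checked against `numpy.corrcoef` in the test
suite. r is undefined when either gene is constant within the condition.
Undefined values are carried as NaN, excluded from interval counting, and
reported as an exclusion count, so the 8×8 totals always satisfy the
conservation identity counts + excluded = pairs. Without this policy a
single zero-variance gene would silently corrupt every marginal total.

### All-pairs engine

For g genes there are g(g−1)/2 pairs per condition (225,239,700 at the
cohort scale of 21,225 genes). The engine standardizes each condition's
matrix once and computes row-block products Z[I]·Zᵀ/(n−1), streaming the
upper-triangle entries into the pair table; the full g×g matrix (~3.6 GB
per condition in doubles at cohort scale) is never held. Results are exact
to ≤1e−10 across chunk sizes, and the enumeration order (row-major over
the upper triangle of the lexicographically sorted gene list) is part of
the output contract. Products accumulate in double precision; the final
values are clamped to [−1, 1] (violations beyond 1e−12 raise).

Missing data policy: the default requires a complete matrix and fails fast
with a count of offending cells, because interval counts are only
well-defined on a fixed sample set. A `missing="pairwise"` mode computes
each pair on its pairwise-complete samples via the scalar path; it is
intended for desk-scale matrices (it is O(g²·n) in Python loops).

## Interval transitions

Correlations are divided into eight fixed intervals of width 0.25. Bins
1–7 are half-open [a, b); bin 8 is closed [0.75, 1] so r = 1 is
assignable. Thus r = −0.75 falls in bin 2 and r = 0.75 in bin 8. A pair's
control→case change is summarized as the interval distance
|bin_case − bin_control| ("crossed k intervals"); the 8×8 transition
matrix counts pairs by (control bin, case bin), with row percentages
100·count/row-sum computed in full precision and printed to five decimals.
This formalization of "crossed k intervals" reproduces, from the embedded
published count tables, every derived count the cohort study reports (18;
1,893; 15; 2,468; 196,311), which is the package's acceptance check for
the semantics.

Large-change pairs are those with distance ≥ 3 (configurable 1–7). The
delta filter keeps pairs with |r_case − r_control| strictly greater than
the threshold (default 0.8); pairs landing exactly on the threshold are
excluded and logged, since correlations printed to three decimals can sit
on the boundary while their unrounded difference exceeds it.

Cross-disease intersection is a set intersection on the lexicographically
sorted symbol tuple, so pair order never matters. It intersects on pair
identity only by default; `require_same_direction=True` additionally
requires the sign of delta to agree in both diseases. The unique-gene list
is the sorted union of both symbol columns, exported one symbol per line
for external enrichment tools (enrichment itself is out of scope).

## Subsampling repeatability

To ask how many samples a co-methylation estimate needs, the experiment
draws disjoint groups of genes (default 5 groups × 100 genes, sampled
without replacement), and for each group and sample size n draws two
disjoint n-sample subsets of one condition, computes all within-group pair
correlations on each, and reports the Pearson correlation between the two
replicate vectors. Agreement is undefined (NaN, logged) when a replicate
vector is constant — guaranteed territory at n = 2, where every defined
pair correlation is ±1. Randomness uses one master seed with a
deterministic substream per (group, n), so curves are reproducible and
independent of evaluation order; the two replicate draws are disjoint
within a cell but independent across cells.

## Synthetic data

The generator draws each condition from a multivariate normal whose
correlation matrix is assembled from an identity base, constant-correlation
blocks, and explicitly injected differential pairs; each gene is then
mapped into (lo, hi) ⊂ (0, 1) by a per-gene increasing affine (min–max)
rescale. Affine maps preserve sample Pearson correlations exactly, so the
emitted beta matrix realizes the requested structure while every value
stays strictly inside (0, 1). A probability-integral transform to
beta-like bimodal marginals was deliberately not used: the pipeline's
statistics depend only on correlations, and the affine route keeps the
ground truth exact. Consequently the generator does **not** emulate 450K
marginal shapes, batch effects, or cell-composition confounding — passing
tests demonstrate correctness of the correlation/interval machinery and
its statistical behaviour, not robustness to those real-data artefacts.

Assembled targets are validated positive semi-definite (eigenvalue
tolerance 1e−8); invalid targets raise, naming the offending eigenvalue,
unless `repair_psd=True` applies eigenvalue clipping at 1e−10 with
correlation re-normalization (the truth table then records the repaired
matrix). Differential pairs default to otherwise-independent genes so they
induce no side correlations. Sampling uses a Cholesky factor with a small
jitter ladder to tolerate repaired (semidefinite) targets.

Defaults are chosen to resemble a blood-methylation case/control cohort
and are fixed: 354 cases and 335 controls (the RA cohort's arm sizes),
300 genes (a desk-scale universe; the counting machinery is scale-free),
3 probes per gene with probe noise SD 0.02, beta range (0.1, 0.9), and an
explicit integer seed giving bit-identical output.

## Problem sizes in tests and the acceptance script

The cohort-scale computation (21,225 genes) is supported by the chunked
engine but not rerun for verification; instead the counting layer is
checked exactly against the embedded published 8×8 tables, and the
statistical layer on simulations sized so each check is sharp:

* injected-pair recovery uses r −0.6 → 0.4 (distance 4) at 2,000 samples
  per condition, where the sampling SD of r (≈0.015) is small against the
  0.1 margin to the nearest bin edge; 100 seeded runs.
* the null rate uses 150 genes at equal targets and 300 samples per
  condition (≈33,500 pair draws over three seeds); a null pair needs
  |Δr| > 0.5 to cross three intervals, ≈6 SD of Δr at that n.
* repeatability monotonicity compares agreement at n = 120 vs n = 5 over
  100 seeded runs on block-correlated data; the median-agreement summary
  uses the full 5 × 100-gene design on a 520-gene universe whose blocks
  (r = 0.3–0.7) cover all genes, since real methylomes are broadly
  co-correlated and leaving most pairs at exactly zero correlation would
  understate achievable agreement.

## Known limitations

* Gene symbols are compared case-sensitively as given; no HGNC aliasing.
* Pair tables are written as TSV (the interchange contract); no columnar
  binary cache is provided.
* No significance testing of pair changes, no Spearman/robust correlation
  alternatives, and no GEO download: the series-matrix reader expects a
  local file.
* The pairwise-complete missing-data mode is quadratic in genes with
  Python-loop constants; use complete matrices at scale.
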