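# Methods

## Overview and assumptions

`mirtempo` post-processes longitudinal differential-expression results; it
does not fit DE models itself. The input contract is one table per gene
type with, per gene and time point, a log2 fold change against baseline
and a multiple-testing-adjusted p-value. The method assumes:

* the time-point axis is an ordered set of labels; spacing is not used by
  any statistic (correlations, regressions and the CCF treat the course as
  an equally-indexed sequence, so all statistics are invariant to
  relabeling of time points);
* miRNA regulation is repressive, so the biologically interesting
  pair-level signal is strongly *negative* trajectory correlation;
* database evidence (predicted or experimentally supported targeting) is a
  complementary, correlation-independent filter.

## Significance filtering

Genes pass at a time point when padj ≤ α there, independently of every
other time point. The boundary is inclusive and α defaults to 0.05 — the
conventional adjusted-p cut-off; it is configurable. Combined mode pools
the miRNA and mRNA label sets per time point; separate mode keys sets by
(time point, gene type). Combined-mode enrichment simply lets miRNA
labels fail to overlap mRNA pathways, which keeps the pooled gene list
faithful to the data without special-casing.

## Overrepresentation analysis

For each context (time point, (time point, gene type), or temporal
cluster) and each pathway, the overlap k between the significant set
(size n) and the pathway (size K) inside the universe (size N) is scored
with the one-sided upper tail P(X ≥ k) of the hypergeometric
distribution — the standard ORA convention, with the observed k included.
The tail is computed from exact integer binomial coefficients, so it is
correct to full float precision at gene-set scale; tests cross-check it
against `scipy.stats.hypergeom.sf` and against exhaustive enumeration of
all draws for universes up to 12 genes.

The universe defaults to all genes present in the input DE data after ID
mapping ("auto") and can be replaced, e.g. by an array's probe list.
Both the significant set and pathway members are intersected with the
universe before counting. Adjustment is Benjamini–Hochberg within each
context (delegated to statsmodels; an independent step-up oracle backs the
tests). Rows with k = 0 are dropped by default — they carry no signal and
p near 1 — behind a flag.

## Temporal pathway clustering

The trajectory of pathway p is the count of its members in the significant
set at each time point (raw counts by default; a flag divides by pathway
size). Rows are standardized to mean 0 and standard deviation 1 using the
*population* (n-denominator) convention — either convention satisfies the
invariant under its own definition; this one is fixed and asserted at
1e−9. Zero-variance rows (typically pathways overlapping nothing, or
everything at every time point) are dropped and listed.

Fuzzy c-means uses the classical alternating updates with Euclidean
distance: membership u_ic = 1 / Σ_c′ (d_ic/d_ic′)^(2/(m−1)), centers
v_c = Σ_i u_ic^m x_i / Σ_i u_ic^m. A row coincident with a center gets
membership 1 there. Initialization draws c rows with pairwise *distinct*
value vectors from a seeded permutation (duplicated rows must not collapse
two centers onto one point, which would degenerate every membership to
1/c). Iteration stops when the maximum center change drops below tol
(default 1e−6) or after max_iter (200); non-convergence returns a flagged
result rather than raising. The fuzzifier defaults to m = 2; as m → 1+
memberships approach hard assignments (asserted by entropy comparison at
m = 1.05 vs m = 3). The cluster count c is deliberately user-supplied —
the clustering is a supervised exploration tool, and no Dmin-style
selection heuristic is included. The per-pathway, per-cluster membership
in [0, 1] is the "fitness score" users filter on; rows sum to one.

For whole-course (nonpairwise) DE, the same machinery clusters gene-level
trajectories; each gene is hard-assigned to its maximum-membership cluster
(ties to the lower-indexed cluster, logged) and ORA runs per cluster.

## Interaction matrix and filtering

For a selected pathway, the candidate matrix crosses every input mRNA
mapping into the pathway with every miRNA significant at ≥ 1 time point
(configurable to all input miRNAs). Correlations are computed on the
log2FC trajectories by default, or on a user-supplied per-time-point mean
expression matrix; Pearson is the default, Spearman and Kendall (tau-b,
tie-corrected) optional. Fewer than 3 time points is a hard error; a
zero-variance trajectory marks the pair unavailable (it can never pass
the filter).

Database flags are exact pair lookups in local snapshots of TargetScan,
miRDB (predictive) and miRTarBase (functional); miRTarBase pairs whose
evidence contains "weak" (case-insensitive, configurable pattern) are
removed at load time. The vote is the flag sum over the user-selected
databases. A pair is kept when corr ≤ max_corr AND votes ≥ min_dbs, with
defaults −0.5 and 1. Both boundaries are inclusive: the threshold is
stated as a *maximum* correlation, so a pair exactly at −0.5 passes.
Kept pairs form a bipartite network (isolated nodes excluded; empty
networks allowed with a warning).

## Longitudinal pair statistics

Every operation first runs the time-point guard: T < 3 errors, T < 5
warns (via logging and a `TimePointWarning` so callers and tests can
assert it), T ≥ 5 is silent. Short courses make these statistics
overestimates; the guard makes that explicit rather than silently
proceeding.

* **Cross-correlation** — ccf(ℓ) = Σ_t (x_t − x̄)(y_{t+ℓ} − ȳ)/(T·s_x·s_y)
  with full-series means and population sds. Because the divisor is T and
  the sds use the same T, ccf(0) equals the Pearson correlation exactly
  (tested to 1e−12). Positive lag means the mRNA series trails the miRNA
  series. Note that for an exactly affinely-shifted copy of a *monotone
  linear* series the peak sits at lag 0, not at the shift — lag detection
  is informative only for non-degenerate shapes.
* **Scaled splines** — both series standardized, then interpolated by a
  natural cubic spline through the T points onto a uniform grid (default
  100 samples). The spline interpolates (it reproduces the data at the
  knots); the annotated correlation is computed on the unscaled data and
  rounded to 2 decimals at display only.
* **Multi-predictor regression** — OLS with intercept of a selected gene
  on any number of binding partners, reporting R², the overall F-test p,
  the coefficient table and the fitted trajectory. The predictor count is
  capped at T − 2, and exactly collinear predictors are rejected with both
  names in the message.
* **Pair odds ratio** — single-predictor OLS of mRNA on miRNA;
  OR = exp(slope), CI = exp(slope ± 1.96·SE). This treats the regression
  coefficient as a log-odds-style effect size for ranking pair strength —
  an unusual convention adopted deliberately; it is *not* a probability
  model, and the OR should be read as a monotone transform of the slope.
  A perfect fit (SE = 0) collapses the CI to the OR and flags the fit
  "exact fit". Rounding to 2 decimals happens only in `display()`.

Pairs are ordered for the selection heatmap by descending correlation,
ties broken lexicographically by (miRNA, mRNA).

## Identifier handling

The ID map covers every (label, gene type) in the input; labels missing
from the mapping table are retained with absent entrez/ensembl IDs.
Adjusted labels equal the input labels, which are unique per gene type and
keep −3p/−5p arm suffixes — so both arms of a miRNA stay distinct in
networks and exports even when entrez/ensembl annotation collapses them to
one ID. Two mRNA labels sharing one entrez ID are both kept with a logged
warning; enrichment de-duplicates by mapped ID.

## Exports

PathVisio data files carry the mapped gene ID, a BridgeDb system code
("L" entrez, "En" ensembl) and one value column per time point; the
filtered-miRNA file is a documented 3-column dialect (adjusted label,
mapped ID, system code) for MAPPbuilder-style import. Networks export as
GraphML (node attribute `type`; edge attributes `corr`, `votes`, one 0/1
flag per database) and SIF with a sidecar edge-attribute TSV. All writers
sort on stable keys and format floats with 10 significant digits, so
identical inputs give byte-identical files; every writer has a
reader-based round-trip test.

## Synthetic data

The fixture generator emulates the full input surface at toy scale
(default 30 miRNAs × 60 mRNAs × 5 time points × 10 pathways, mirroring a
5-point post-baseline injury course while running in seconds) with
recorded truth: an enriched pathway stuffed with genes significant at its
planted time point, shape-planted pathways whose significant counts
follow monotone/pulse templates, planted interactions with
mRNA = −a·miRNA + N(0, noise_sd) trajectories (exactly −1 correlation at
noise 0) and configurable database flags, decoy database pairs with
exactly orthogonal trajectories, weak-evidence miRTarBase rows, and a
shared-entrez −3p/−5p arm pair. Background genes get uniform padj in
[0.2, 0.9], so they never pass the default filter — real data's gray zone
of near-threshold genes is *not* emulated, and passing tests therefore
demonstrate correctness of the machinery, not statistical power on noisy
data. Gaussian noise on log2FC is simple and sufficient to exercise the
correlation threshold; heavier-tailed noise is not modeled.

## Problem sizes and determinism

Tests and the acceptance script run at fixture scale: the enumeration
oracle for the hypergeometric tail covers all universes up to 12 genes,
the BH property check uses hundreds of seeded random vectors, and the
pipeline fixture has 36 candidate pairs — sizes chosen so the whole suite
completes in seconds while still exercising every code path. All
randomness (fixture generation, clustering initialization, layout) flows
through explicit integer seeds; reruns are byte-identical.

## Known limitations

* Pathways and target databases are local snapshots; no live database
  access, so results depend on snapshot versions.
* The odds-ratio metric is a convention, not an inferential model (above).
* Gene-level clustering input (whole-course DE) must be prepared by the
  user; the package does not average replicate counts itself.
* Cluster-count selection and clustering-stability analysis are out of
  scope; c is user-chosen.
* Real-data behavior (probe-level noise, annotation churn, partially
  overlapping database coverage) is outside what the synthetic fixtures
  can certify.
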