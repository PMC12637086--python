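# Methods

This note documents the models, estimators and numerical choices behind
`tmedyn`, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## LTQ estimation (qc module)

The pipeline works on **log transcription quotients**: per cell c and
gene g, the natural log of the gene's fraction q_gc of the cell's
transcriptome. Counts are modeled as n_gc ~ Poisson(N_c q_gc) with
N_c the cell's total UMI count.

The estimator is deliberately simple and documented rather than a
reimplementation of any full Bayesian deconvolution tool:

* Likelihood: approximated as Gaussian in x = log q with center
  x̂ = log((n + ½)/N) and precision n + ½ (the Poisson Fisher
  information; the ½ pseudocount regularizes zeros).
* Prior: gene-wise N(μ_g, τ_g²), fitted by moments — μ_g is the
  precision-weighted mean of x̂ across cells, τ_g² the across-cell
  variance of x̂ in excess of the mean sampling variance, floored at
  0.01 so the shrinkage weight never diverges.
* LTQ = posterior mean; genes with no cross-cell signal shrink hard
  toward μ_g, deep counts are left almost untouched.

The per-gene **error bar** σ_g is the mean *sampling* error
mean_c (n_gc + ½)^(-1/2) — i.e. the noise scale of the measurement,
not the posterior sd. This is the quantity the SNR gene filter divides
by (keep genes with sd(LTQ)/σ_g > 0.25): using the posterior sd would
make the ratio prior-dependent and would not shrink with sequencing
depth.

QC defaults (≥5 cells per gene, ≥100 genes per cell, ≤12.5%
mitochondrial transcripts) follow the study design this package
reimplements. The filter order genes → cells → mitochondrial is fixed
for reproducibility; the mitochondrial cutoff is global by default with
a per-sample switch. The low-RNA filter is log total UMI <
median − 3·MAD (normal-consistent MAD; MAD = 0 keeps everything), run
*within* the cell group under analysis, because RNA content is
cell-type specific.

## Recursive typing (hierarchy module)

Each node re-runs the full per-group pipeline: low-RNA filter, SNR
gene selection, centered unscaled PCA (exact SVD; loading sign fixed so
each column's largest-magnitude entry is positive), elbow choice of the
PC count, SNN-graph Leiden clustering, density-based isolation
filtering, marker annotation, and recursion into each cluster.

Numerical/design choices:

* **Elbow rule**: the original procedure used a visual elbow; here it
  is automated as the 1-based argmax of the forward second difference
  v[i] − 2v[i+1] + v[i+2] of the variance-explained curve, clipped to
  [2, n_pcs_max]. Pure geometric decay therefore returns the lower
  bound 2.
* **Clustering**: Leiden with the modularity (RB-configuration)
  objective on a shared-nearest-neighbor graph (k = 20, Jaccard edge
  weights), seeded and bitwise reproducible. Leiden was chosen over
  Louvain as a strict quality superset with the same resolution
  semantics. The resolution schedule maps tree depth to resolution,
  default {0: 0.02, 1: 0.03, 2: 0.07, 3: 0.1} — coarse compartments
  first, finer subtype splits deeper.
* **Isolation filter**: per cell, d = mean Euclidean distance to its
  k nearest neighbors; at constant density d³ ∝ 1/n, so n·d³ is
  comparable across clusters of different sizes. The cutoff was set by
  visual inspection in the original procedure; the automated default
  is each node's 95th percentile, exposed as configuration. The
  scaling argument is asymptotic in n — finite-k edge effects remain,
  which is why the property test compares matched sample sizes.
* **Annotation**: per cluster and candidate type, the score is the
  mean over the type's markers of (cluster mean − other-clusters mean)
  / pooled within-cluster sd (a marker effect size; a small variance
  floor of 1e-4 guards degenerate genes). The best type must beat the
  runner-up by 0.5 or the cluster is "unresolved" — ties are never
  guessed. Scoring against siblings rather than z-scoring across
  clusters keeps two-cluster nodes informative.
* **Annotation locking**: once a node is confidently annotated, its
  descendants keep that call; deeper splits inside a typed population
  are phenotypic structure, not new cell types. Without this rule,
  shrinkage-induced depth gradients inside a pure type can generate
  spurious subclusters whose *relative* marker scores mis-assign them.
  Unresolved nodes recurse freely and their children are annotated
  among siblings.
* **Stopping**: one community at the node's scheduled resolution
  (recorded as `stop_reason: continuum` — the automated proxy for
  "cells formed a continuum"), node smaller than max(min_cells,
  k + 2), or max depth.

## Archetype analysis (archetypes module)

Cells of one type are modeled as x_c ≈ Σ_a w_ca A_a with barycentric
weights (w ≥ 0, Σ_a w_ca = 1) and p archetypes fit in the first p − 1
PCs.

* **Fitter**: principal-convex-hull alternating least squares.
  Archetypes are convex combinations of data points (A = B·X with
  row-stochastic B; relaxation δ lets row sums roam in [1±δ],
  default δ = 0). Weights solve the exact simplex-constrained least
  squares per cell by support enumeration (exact for the p ≤ 8 used
  here); B moves by projected gradient with backtracking, so the
  objective is monotone non-increasing. Initialization is
  furthest-sum; the best of n_restarts is kept. An unconstrained
  archetype update is *not* used: any simplex enclosing the data has
  zero residual, so the unconstrained problem is degenerate.
* **t-ratio**: volume of the minimum-volume enclosing simplex over
  the volume of the data's convex hull. The enclosing simplex is found
  on the hull vertices only (they determine it): a PCHA fit on the
  hull vertices, expanded by the smallest face-shift that contains all
  points (in barycentric terms b → (b − m)/(1 − Σm), a homothety),
  then local volume minimization (SLSQP on the vertex coordinates)
  under the containment constraints. t-ratio ≥ 1 by construction and
  = 1 when the hull is itself a simplex. Hull volumes in more than 8
  dimensions are refused (combinatorial cost); the analyses here need
  at most 3.
* **Permutation test**: each shuffle permutes every PC column
  independently (marginals preserved, correlations destroyed); the
  t-ratio is recomputed through exactly the same hull-seeded procedure
  for the observed and every shuffled dataset, which makes the
  add-one-smoothed one-sided p-value exact under the null. Fewer than
  19 shuffles triggers a warning (p floor coarser than 0.05).
* **Discretization**: the 25% of cells closest to each archetype form
  its candidate set; the 20% closest to the origin are "generalists".
  Conflict rules (documented, configurable): a cell in several
  candidate sets goes to the nearer archetype; the generalist label
  wins over archetype labels.
* **Enrichment**: per archetype, one-sided rank-sum of each feature in
  the closest-cells set vs the rest, BH-corrected within archetype.
  This is a deliberate simplification of bin-based archetype
  enrichment procedures; equivalence with them is not claimed.
* **Continuum vs clusters**: a 2D KDE over the scores is scanned for
  local maxima; each peak's axis-averaged FWHM, deconvolved of the
  KDE kernel's own FWHM in quadrature, is compared with the
  measurement-error radius propagated from the per-gene error bars
  through the loadings. "Cluster-like" requires every peak to be no
  wider than the error radius.

## Fitness scores (fitness module)

score_c = Σ_g LTQ_gc · NormZ_g over the id intersection of the gene
universes (symbol join; the intersection size is reported). LTQs enter
uncentered on the natural-log scale, matching the literal definition;
a gene-centered variant sits behind a flag because the original
description is ambiguous on centering. The archetype comparison is a
two-sided rank-sum test of the 5% closest cells vs the rest with the
direction reported; groups smaller than 3 cells are refused.

## Dynamics (dynamics module)

Prevalences divide by **all** cells sequenced at the timepoint, so
phenotype dynamics and cell-type abundance compose; an "unlabeled" row
preserves conservation (fractions sum to 1). 1D phenotype densities
are KDEs scaled so the area under each curve equals the type's
prevalence at that timepoint. Boundary conventions are strict
inequalities with documented tie sides (PC sign: 0 → positive; Tc
quadrant: strict positives; LTQ threshold −7.7: tie → high).

The three temporal patterns are named in the source study but given no
formula; the classifier here is artifact-defined with documented,
configurable tolerances: *stable colonization* = rise from t1 (second
point ≥ 2× first, or 0 → positive) then CV ≤ 0.25 over later points;
*wave-like* = interior maximum ≥ 1.5× both endpoints; *progressive
increase* = monotone non-decreasing with total rise ≥ 2×. Checked in
that order; everything else is "other". The rules are invariant to
uniform rescaling. Series whose true rise sits exactly at a tolerance
boundary can flip class under sampling noise — the macrophage series
in the default configuration (2.0× rise) is such a boundary case.

## Imaging phenotyping (hifi module)

Log1p intensities (log1p, not log, to tolerate zeros after background
subtraction) are bimodal with marker-specific positive fractions.
Each channel is divided by the location of its *highest-intensity*
(rightmost) prominent KDE mode — "highest" must mean rightmost, not
tallest, for the positive population to land at 1. For rare nested
markers the mode is searched only within the parent-positive gate
(scaled parent > 0.5), parents scaled before children (topological
order). Bandwidth and prominence are per-call configurable because
rare populations need more permissive smoothing. A channel with no
positive mode falls back to its global maximum and is flagged.

Clustering uses k = max(round(n·10⁻³), 10) neighbors and resolution 1
on the first two PCs. Cluster annotation: every necessary marker
positive (cluster median scaled > 0.5) and no marker outside the
possible set positive; zero or multiple matches → "undetermined" (with
a warning when ambiguous). The 0.5 positivity cutoff is the midpoint
of the ~0/~1 scaled populations — a package choice, configurable.
Composition comparison floors zero fractions at half the smallest
nonzero fraction (flagged) before correlating logs.

## Cross-species composition (crossspecies module)

Compositions are log-transformed (zero floor as above) and centered
within each species, removing sample-independent cross-species offsets;
PCs come from the weighted covariance Σ w_s x_s x_sᵀ / Σ w_s with
w_s = 1/(samples of that species) — 1/8 and 1/26 for the study's
cohort sizes — so both species shape the axes equally. "TPM" is the
UMI fraction × 10⁶ per pseudo-bulk sample; no gene-length correction,
as appropriate for 3'-counted UMI data (the name is kept with this
caveat).

## Preranked enrichment (enrichment module)

Genes are ranked by Σ squared loadings over the first PCs (overall
gradient strength; the top-30 slice is the conventional short list) or
by a single PC's signed loading. The enrichment score is the classic
weighted KS running sum (weight exponent 1; exponent 0 gives the
rank-only variant that is invariant to monotone score transforms).
The null permutes gene labels, matching preranked usage; p-values are
one-sided within the same-sign half of the null (keeping null p
uniform) with BH q-values across sets. Bit-compatibility with any
specific GSEA implementation is not claimed.

## Synthetic data: what it emulates, and what it does not

The generator plants: Poisson counts around per-cell log rates
(log-softmax-normalized so rates are transcriptome fractions), cell
size factors log-normal with σ = 0.3 around a mean depth of 5000 UMIs,
2% reserved `mt-` genes (plus a 1% "damaged" cell fraction with
inflated mitochondrial rates so the QC filter does real work), a
9-type composition over four timepoints following the three temporal
patterns, hierarchical marker structure (lineage blocks shared across
compartments so coarse clustering precedes subtype splits), a
4-archetype simplex inside macrophages (Dirichlet weights,
concentration 0.8 for corner-enriched occupancy), a 1D trajectory
inside Tregs whose mean position drifts over time, gated bimodal
marker channels (negative/positive log1p modes at 0.1/1.5, sd 0.1),
and NormZ tables with signature genes at N(effect, 1).

Defaults are desk-scale — 600 genes × 3000 cells — not the ~20k genes
of a real experiment; problem sizes in the tests and acceptance script
(2000 cells per simplex, 50 × 99 shuffles for the null calibration in
2D, 5000 imaging cells) were chosen so the full suite runs comfortably
on one CPU. An optional negative-binomial switch adds overdispersion
beyond Poisson (default off; the real data's dispersion is not
published). Not emulated: ambient RNA, doublets, batch effects between
samples, gene-gene correlation beyond the planted structure,
segmentation errors or spatial autocorrelation in the imaging channels.
Passing tests therefore demonstrate correctness of the algorithms
under their stated noise models, not robustness to every artifact of
real data.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; the pipeline derives one
independent sub-stream per stage (overridable per stage), so changing
the imaging seed cannot perturb the scRNA-seq stages.

## Known limitations

* Archetype *positions* recover well in the generative PC space; when
  the simplex must first be found by PCA of noisy LTQs (the 04 driver),
  per-cell weight recovery is partial at desk scale because the
  3-PC projection mixes archetype axes with residual depth gradients.
  The t-ratio test remains well-powered in that setting.
* The minimum-volume enclosing simplex is a local optimization; it is
  seeded identically for observed and shuffled data, so the
  permutation test is exact regardless, but the t-ratio value itself
  is an upper bound on the true minimal ratio.
* The LTQ estimator honors the LTQ + error-bar contract only; it is
  not a substitute for full variational inference, and its shrinkage
  can create depth-correlated gradients inside homogeneous populations
  (mitigated by the annotation-locking rule above).
* `run_pipeline` resume support skips stages whose outputs exist; it
  does not hash-validate intermediate inputs.
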