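# tmedyn — temporal dynamics of the tumor microenvironment

`tmedyn` reimplements, as a tested and reusable Python pipeline, the
computational methodology of a longitudinal single-cell study of a
progressing mouse breast tumor: how the cellular composition and the
phenotypes of the tumor microenvironment (TME) change over four weeks of
tumor growth, and how those dynamics are measured from UMI count
matrices and multiplexed immunofluorescence images.

It is written for computational biologists who want to apply (or audit)
the individual steps — each is an importable, unit-tested function — and
it ships a synthetic-data generator that plants known ground truth, so
the entire pipeline can be exercised end-to-end without any external
download.

## What the pipeline computes

1. **QC and normalization** (`tmedyn.qc`). Genes detected in <5 cells,
   cells with <100 detected genes, and cells with >12.5% mitochondrial
   transcripts are removed. Counts are converted to **log transcription
   quotients** (LTQs): a denoised natural-log estimate of each gene's
   fraction of the cell's transcriptome, with a per-gene mean sampling
   error σ<sub>g</sub>. The estimator is empirical-Bayes — a gene-wise
   Gaussian prior on log q combined with a Laplace approximation to the
   Poisson likelihood, so LTQ<sub>gc</sub> shrinks log((n<sub>gc</sub>+½)/N<sub>c</sub>)
   toward the gene's prior mean in proportion to its sampling noise.

2. **Recursive hierarchical cell typing** (`tmedyn.hierarchy`). At each
   node of the typing tree: keep genes with SNR = sd(LTQ)/σ<sub>g</sub> > 0.25,
   drop low-RNA cells (log total UMI < median − 3·MAD) and cells in
   low-density regions (n·d³ above the node's 95th percentile, d = mean
   distance to k=20 nearest neighbors), run centered unscaled PCA, pick
   the number of PCs by an automated elbow, cluster the SNN graph with
   Leiden at a depth-scheduled resolution (0.02 → 0.03 → 0.07 → 0.1),
   annotate clusters against a marker table, and recurse until a node
   is a single community (a phenotypic continuum).

3. **Simplex-archetype analysis** (`tmedyn.archetypes`). Cells of one
   type are modeled as convex mixtures of p archetypes in the first
   p−1 PCs (four archetypes span a tetrahedron). Archetypes are fit by
   principal-convex-hull alternating least squares; fit quality is the
   **t-ratio** = volume of the minimum-volume enclosing simplex over
   the volume of the data's convex hull, and significance comes from
   refitting on datasets whose PC columns are permuted independently
   (one-sided p, small t-ratio = tight simplex). Cells are discretized
   by proximity: the 25% closest cells per archetype, the 20% closest
   to the origin as generalists.

4. **CRISPR-weighted fitness** (`tmedyn.fitness`).
   score<sub>c</sub> = Σ<sub>g</sub> LTQ<sub>gc</sub> · NormZ<sub>g</sub>, where NormZ is a
   knockout screen's z-scale selective-advantage per gene; the 5% of
   cells closest to an archetype are compared with the rest by
   rank-sum test.

5. **Phenotype dynamics** (`tmedyn.dynamics`). Discretization rules
   (PC sign, positive-positive PC quadrant, an LTQ = −7.7 threshold on
   a bimodal marker gene), prevalences normalized to all cells
   sequenced per timepoint, per-timepoint 1D phenotype densities whose
   areas equal the type's prevalence, tumor volume V = π/6 · L · l²,
   and classification of prevalence series into *stable colonization*,
   *wave-like* or *progressive increase*.

6. **Multiplexed-imaging typing** (`tmedyn.hifi`). Each marker channel
   is scaled by the location of its highest-intensity mode (searched
   within a parent-marker gate for nested markers), clusters come from
   Leiden on the first two PCs with k = max(round(n·10⁻³), 10) and
   resolution 1, clusters are annotated by necessary/possible marker
   rules, and log cell-type proportions are compared across modalities.

7. **Cross-species composition** (`tmedyn.crossspecies`).
   Log-compositions centered within species, PCA weighted by inverse
   cohort size (1/8 mouse, 1/26 human), and pseudo-bulk TPM
   (UMI fraction × 10⁶) for gene-level comparisons.

8. **Synthetic data** (`tmedyn.synthetic`). Poisson UMI counts around
   cell-specific log rates with log-normal size factors, a reserved
   `mt-` gene subset, a 4-archetype simplex inside one cell type, a 1D
   trajectory inside another, per-timepoint compositions following the
   three temporal patterns, bimodal gated marker intensities, and
   NormZ tables enriched in a signature.

## Worked example

```bash
python analysis/01_simulate_tumor_timecourse.py
python analysis/02_qc_and_normalize.py
python analysis/03_hierarchical_cell_typing.py
python analysis/04_macrophage_simplex.py
```

prints, for the default desk-scale dataset (600 genes × 3000 cells over
days 11/14/18/24, seed 7):

```
QC: 3000 -> 2967 cells (33 removed at >12.5% mitochondrial reads); 600 genes kept
typing recovered 9 cell types, ARI vs planted truth = 1.000, 326 cells excluded by filters
t-ratio = 2.031, permutation p = 0.0050 (200 shuffles)
```

meaning: the recursive typing recovered all nine planted cell types
with a perfect adjusted Rand index on the typed cells, and the
macrophage continuum is significantly better described by a
4-archetype simplex than any of 200 column-shuffled null datasets.
The remaining drivers (05–08) add the fitness comparison, the temporal
pattern classification, the imaging cross-check and the cross-species
PCA; each prints a one-line summary and writes tidy tables under
`results/`.

The same chain is available as a single command with a run manifest:

```bash
tmedyn run --out results/pipeline --seed 7
```

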