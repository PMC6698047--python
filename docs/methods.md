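# Methods

## Problem and model

Bulk skin biopsies mix many cell types (keratinocytes, fibroblasts, adipose
lineages, and diverse leukocyte subsets), and the mRNA measured in such a
biopsy is, to first approximation, an abundance-weighted sum of the
constituent cell types' expression profiles. Reference-based deconvolution
inverts that mixing: given a signature matrix **S** (probes × cell types,
linear-scale characteristic intensities) and a bulk profile **m**, estimate
fractions **f** ≥ 0, Σf = 1 with **m** ≈ **S f**.

The package implements the complete workflow around this model for
microarray data: building **S** from a labeled reference compendium,
solving for **f** per sample by ν-support-vector regression, validating the
estimates, and running the compositional group statistics, with a seeded
synthetic-data generator so every stage is testable against known truth.

## Signature construction

Input is a post-normalization (log2) probe × sample matrix with one cell
type label per sample. Three steps:

1. **Differential filter.** For each cell type, every probe gets a
   two-sided unequal-variance (Welch) t-test, that type's replicates versus
   all other samples. Benjamini–Hochberg correction is applied within each
   cell type's family of probes, and probes with q < 0.3 survive. The
   permissive threshold intentionally keeps a deep candidate pool; the
   final specificity comes from the next two steps. Probes with zero
   variance in both arms are excluded (t undefined); a cell type with
   fewer than two replicates is an error.
2. **Ranking.** Candidates are ordered by one-vs-rest log2 fold change
   (difference of log2 means), ties broken lexicographically by probe id so
   the ordering is deterministic.
3. **G selection.** For each integer G in a configured range (published
   full-scale analyses of this kind use 50–150; the synthetic analyses here
   use 2–15, matched to their 20-marker blocks), the top min(G, available)
   candidates per type are pooled into a union, the probe × type matrix of
   per-type **linear**-scale mean intensities is formed, and its 2-norm
   condition number κ = σ_max/σ_min computed by SVD. The G minimizing κ
   wins; ties go to the smallest G (fewest probes for the same
   conditioning). A rank-deficient matrix gets κ = +∞ rather than an
   exception, so degenerate references (e.g. duplicated cell types) fall
   through to a warning path instead of crashing the search.

Testing and ranking run on the log2 scale, where microarray noise is
approximately additive; the stored signature holds linear-scale means,
because mixing of transcripts is additive on the linear scale. κ is
computed on the raw linear-scale submatrix (not standardized), and this
choice is recorded in the signature's provenance.

## Fraction estimation

Per sample: the mixture is restricted to the probes shared with the
signature (at least as many shared probes as cell types are required), the
mixture vector is z-scored on its own mean/SD, and the signature is z-scored
as a whole (one global mean and SD over all entries), preserving the
relative magnitudes of its columns. A linear-kernel ν-SVR (C = 1,
tol = 10⁻⁶, fixed iteration cap, deterministic) is fit for each
ν ∈ {0.25, 0.5, 0.75}; negative coefficients are clipped to zero and the
rest normalized to the simplex. The ν whose clipped solution reconstructs
the standardized mixture with minimal RMSE is reported, together with that
RMSE and the Pearson r of the reconstruction. Standardizing the mixture on
its own moments makes the estimates exactly invariant to positive scaling
of the input (covered by a property test).

An NNLS solver on the same standardized system is provided as a
deterministic baseline and as the independent oracle in tests. The z-scored
system has a free offset which the SVR absorbs in its intercept; the NNLS
route gets the same freedom through an unconstrained intercept encoded as a
+1/−1 column pair. On noise-free full-rank mixtures NNLS is then exact to
numerical precision, and the ν-SVR estimate is required to agree with it to
within 0.02 per component.

Degenerate inputs (constant mixture column, or all coefficients clipped to
zero) yield a flagged NaN fraction row rather than a fabricated
composition; per-sample failures in a matrix run are recorded and the run
continues.

## Aggregation and statistics

Fraction grouping is linear pooling (sums of member fractions, leftovers
into "others"), so row totals are conserved exactly and group means commute
with aggregation. Differences between strata are reported in percentage
points (fractions × 100 at output only).

Because fractions are bounded and skewed, inference is rank-based:
Wilcoxon signed-rank for within-subject contrasts (lesional vs
non-lesional, before vs after treatment), Wilcoxon rank-sum for independent
groups (diseased vs healthy, mild vs severe). Conventions are fixed for
determinism: zero paired differences are dropped before ranking (and
counted in the output); exact p-values for ≤ 25 untied pairs (signed-rank)
or min group size ≤ 10 without ties (rank-sum), normal approximation with
continuity (and, for rank-sum, tie) correction otherwise; all tests
two-sided; significance at p < 0.05. BH correction is applied per contrast
across the cell types of that contrast. Note BH is monotone in the input
ranks and never decreases a p-value, but it is not idempotent under
re-application; the tests assert the former properties.

The scipy implementations (`wilcoxon`, `mannwhitneyu`) and statsmodels
(`multipletests`) provide the test machinery; the test suite checks their
exact branches against independent full enumerations of sign assignments
and rank subsets.

## Synthetic data: what it emulates and what it does not

The generator is the package's stand-in for microarray compendia and biopsy
cohorts. Defaults (one place, `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| n_cell_types / n_probes | 6 / 400 | compendium size for desk-scale runs |
| markers_per_type | 20 | disjoint planted marker block per type |
| marker_log2_effect | 4.0 | 16-fold marker elevation over baseline |
| replicate_count | 4 | reference replicates per type |
| replicate_noise_sd_log2 | 0.25 | between-replicate noise, log2 scale |
| mixture_noise_sd_log2 | 0.2 | multiplicative log-normal mixture noise |
| baseline_log2_mean / sd | 7.0 / 1.0 | log-normal baseline intensities |
| gain_sd / offset_sd / dropout | 0.05 / 0.3 / 0.1 | platform-shift model |

Noise is multiplicative log-normal (additive on log2), matching microarray
error structure; the magnitudes are set so that self-deconvolution of
reference material is near-perfect while noisy mixtures remain a
non-trivial recovery problem. The platform-shift model (per-probe log2 gain
~ N(1, 0.05²), offset ~ N(0, 0.3²), 10 % probe dropout) emulates
cross-array-generation distortions: probe-specific affinity changes and
missing probes, not a full physical hybridization model.

Cohorts plant per-arm composition means on the simplex. Paired arms share a
per-subject Gaussian tilt in log-composition space (logistic-normal,
σ = 0.15) plus a per-sample term (σ = 0.10) — the simplest mechanism that
makes paired tests strictly more powerful than unpaired on the same data,
which is what paired biopsy designs exploit. Independent arms use Dirichlet
draws with precision 100. Treatment courses are arms with timepoints whose
means interpolate back toward the non-lesional composition.

Not emulated: probe-level hybridization physics, batch/site effects beyond
the study-offset used in the inter-study tests, disease-state expression
changes *within* a cell type (profiles are fixed; only composition varies),
and cross-subject heterogeneity of cell-type profiles. Passing tests
therefore demonstrate the correctness and calibration of the pipeline under
the linear mixing model, not the biological fidelity of any particular real
cohort.

## Problem sizes in the shipped analyses

The numbered `analysis/` scripts and the acceptance script run at
desk scale, chosen as the smallest sizes at which every effect of interest
is comfortably detectable: a 6-type × 400-probe reference with 4 replicates
per type; a G grid of 2–15 (the 50–150 grid of a 22-type compendium would
saturate the 20-marker candidate blocks and make the search degenerate);
paired cohorts of n = 20 per arm; 50-mixture noise benchmarks; 1000-rep
null calibrations; 20-seed replications of the end-to-end recovery.

## Known limitations

* The standardization scheme for the ν-SVR system is one of several
  defensible choices; it is recorded in provenance and covered by the
  scale-invariance test, but other deconvolution implementations differ in
  this detail and will not agree bit-for-bit.
* Estimated fractions are relative mRNA-mass fractions, not cell-count
  fractions; types with large transcriptomes are over-weighted relative to
  counts.
* The builder does not batch-correct across reference studies; a
  confounded compendium will plant batch markers in the signature.
* Rank-deficient or ill-conditioned signatures produce flagged, possibly
  non-unique solutions; κ in the provenance is the health indicator.
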