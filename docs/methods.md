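# Methods

## Assay model

The pipeline operates on quantified RT-MLPA probe signals (arbitrary
fluorescence units) for paired irradiated (IR, 5 Gy) and non-irradiated
(non-IR) aliquots of each patient sample. Three processing assumptions are
built in:

1. **Within-sample normalization.** Housekeeping expression (*Diablo*,
   *Aif*, *Gusb*, *Parn*) is irradiation-independent, so dividing every
   probe signal by the geometric mean of the housekeeping signals removes
   sample- and condition-level gain (RNA input, amplification
   efficiency). The geometric mean is computed in log space; it is
   undefined (an error) if any housekeeping signal is missing or
   non-positive, because the whole measurement is then uninterpretable.
   A zero signal on a *classification* probe, by contrast, is treated as
   probe dropout: it normalizes to zero, and a zero non-IR denominator
   marks only that probe's fold induction missing rather than failing the
   sample.
2. **Fold induction (FI)** is the ratio of normalized IR over normalized
   non-IR expression, per probe. FI stays probe-keyed until probe
   selection; a gene measured by several hemiprobes contributes each
   probe as an independent candidate.
3. **Not-evaluable policy.** A sample missing the FI of any selected
   probe cannot be classified and is reported as not evaluable. Refusal
   is preferred over imputation: the classifier's feature space is only
   ten genes, and imputing one would silently dominate the margin for
   borderline samples.

Samples with cell viability below 50% (strict inequality) are excluded
before analysis; unknown viability is kept with a warning.

## Probe selection

Per classification gene, candidates are ranked by the two-sided
Mann-Whitney p-value of the contrast the gene is designed for — cluster I
genes on wild-type vs biallelic TP53/ATM-defective (the
irradiation-response axis), cluster II–IV genes on TP53- vs ATM-defective
(the subtype axis). Monoallelic genotypes never enter these contrasts.
The test uses the exact null distribution for combined n ≤ 12 without
ties, and mid-ranks with the tie-corrected normal approximation
otherwise.

Ties in p within 1e-12 — which genuinely occur on the exact path, where
identical rank configurations give identical rationals — are broken by
the larger absolute difference of group geometric-mean FIs. FIs are
ratio-scale, so the geometric mean is the natural group summary; the
absolute difference of those means is our operationalization of "largest
change between groups". A final lexicographic probe-id tie-break makes
selection fully deterministic. No multiple-testing correction is applied:
selection is a ranking problem, not an inference problem.

## Nested classifier

* **Features:** log2(FI), standardized per feature with mean/SD learned
  on the training samples only. The log makes induction and repression
  symmetric and tames the right skew of ratio data.
* **Stage 1** (functional vs dysfunctional) uses the six cluster-I genes;
  **stage 2** (p53- vs ATM-dysfunctional) uses all ten genes and is
  fitted only on biallelic-defective samples. Stage 2 is consulted iff
  stage 1 calls the sample dysfunctional; functional calls therefore
  never carry a stage-2 margin.
* **SVM:** linear kernel, C = 10, no class weighting, all configurable.
  With ten features and tens of samples a linear maximum-margin rule is
  the appropriate model class; C = 10 is close enough to the hard-margin
  limit that a linearly separable training cohort is classified
  perfectly (C = 1 left margin violations on separable data), while
  retaining some slack against outliers. Cross-validated accuracy was
  indistinguishable between C = 1 and C = 10 on synthetic cohorts.
* **Cross-validation:** leave-one-out by default (the convention at
  n ≈ 30), with seeded k-fold available. Preprocessing statistics are
  re-learned inside every fold; held-out samples never influence them.
  Two selection modes exist: the default reuses one cohort-wide probe
  selection (fast, optimistically biased — the bias the training-cohort
  estimates carry), and `cross_validate_nested` redoes probe selection
  per fold. Folds whose training set lost an entire class (possible only
  in toy-sized cohorts) are flagged degenerate; a one-class stage then
  degrades to a constant decision rather than aborting the whole
  cross-validation.
* **Ordination:** classical (Torgerson) multidimensional scaling of
  Euclidean distances between log2-FI vectors, two dimensions.
  Reflections are canonicalized by making each axis's largest-magnitude
  coordinate positive, so the embedding is deterministic.

## Evaluation conventions

Sensitivity for "any dysfunction" counts biallelic-defective samples
called dysfunctional regardless of subtype; the TP53- and ATM-specific
sensitivities require the correct subtype call. Specificity is the
fraction of wild-type samples called functional. Exact fractions are kept
internally; display rounds to integer percent, half away from zero.
Kruskal-Wallis group comparisons use Dunn's pairwise post hoc z-tests on
pooled mid-ranks with tie-corrected variance and Bonferroni adjustment
over the pairs (the common Dunn convention). Dunn's procedure is
implemented in-package. Clone-size association uses Spearman rank
correlation between clone fraction and the dysfunctional indicator (or
the stage-1 margin).

## Synthetic cohort generator

The generator emulates the assay's biology on the log2 scale: per sample,
each gene's non-IR normalized expression is lognormal around a baseline
(sigma_baseline = 0.3 log2 units), the log2 FI is normal around a
genotype-by-gene mean with biological SD sigma_log2fi = 0.4, technical
noise (sigma_tech = 0.15) is added independently per probe and condition,
and raw signals are reconstructed by multiplying by a sample-specific
housekeeping geometric mean (mean signal 500, sigma 0.1). Default mean
log2 FIs per cluster:

| genotype | I | II | III | IV |
|---|---|---|---|---|
| WT | 1.5 | 0 | 0 | 0 |
| TP53-defective | 0.1 | 1.0 | 1.0 | −1.0 |
| ATM-defective | 0.3 | 0 | 0 | 0 |

The cluster-I means for the two defective genotypes are split
asymmetrically around 0.2: complete loss of p53 blunts p53-target
induction more severely than ATM loss, which leaves residual p53
activation through redundant kinases. This also gives the TP53-defective
profile the larger displacement from wild-type, so its dilution limit of
detection is the smaller of the two. All magnitudes are declared
configuration, not measured biology; true per-gene effect sizes for the
assay are not published.

Sibling probes of a gene carry the full genotype effect by default;
`sibling_probe_attenuation` can scale it down (to zero for testing that
probe selection finds the informative probe).

**Technical replicates** re-assay a genotype's mean profile with only
technical noise, emulating a pooled control sample run repeatedly.
**Clone mixtures** combine the defective and wild-type prototype at the
raw-signal level, `mixed = f·defective + (1−f)·WT` — the in-silico
analogue of mixing RNA before the assay. Note the FI of a mixture is a
ratio of convex combinations and hence moves monotonically (not linearly)
between the prototype FIs. The **limit of detection** is the smallest
clone fraction whose replicate detection proportion reaches a threshold
(default 0.5); a zero-noise bisection variant locates the exact stage-1
boundary crossing.

What the generator does **not** model: capillary-electrophoresis
artifacts, probe ligation/PCR efficiency differences, within-patient
subclonal heterogeneity beyond a single mixing fraction, correlated noise
across genes, and real inter-patient covariance structure. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour under
the stated noise model, not clinical performance on patient material.

## Problem sizes and numerical choices

Simulated cohorts default to 30 samples per genotype — the scale of the
assay's real training cohort — and cross-validation studies aggregate 20
seeded cohorts. Dilution scans use a 21-point grid on [0, 1] with 25–30
replicates per point, giving Monte-Carlo noise of at most ~0.1 on each
detection proportion. The Mann-Whitney exact path is limited to combined
n ≤ 12 (beyond that the normal approximation with tie correction is
accurate and much cheaper). The p-tie tolerance is 1e-12; standardization
guards against zero variance by substituting unit scale. Model
serialization covers the linear kernel (weights + preprocessing
statistics in versioned JSON); non-linear kernels can be fitted but not
serialized.

## Known limitations

* Leave-one-out accuracy on default-noise synthetic cohorts is ~98% on
  average but single cohorts can dip to ~94%; the acceptance property is
  therefore checked as a mean across seeds.
* The default (non-nested) cross-validation shares probe selection across
  folds and inherits its optimistic bias; use the nested variant for
  unbiased estimates.
* Small defective clones (below roughly half the sample under default
  noise and separation) are called functional — an intrinsic limitation
  of bulk functional read-outs that the dilution scan quantifies.
* Monoallelic genotypes are never fitted on; their predictions reflect
  whatever their expression profile resembles, and are reported in a
  separate breakdown rather than folded into sensitivity/specificity.
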