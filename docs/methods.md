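# Methods

## Scope and data model

The package analyses case-control mycobiome profiles: integer count tables
of zero-radius OTUs (zOTUs, exact ITS-1 amplicon variants) over samples,
with per-feature UNITE-style lineage strings, per-sample clinical metadata
(group, IBS subtype, optional SeHCAT bile-acid category), and optional
paired omic blocks (bacterial relative abundances, metabolite intensities,
food-frequency counts per week). All tables travel as a `FeatureTable` — a
pandas DataFrame plus a `units` tag (`counts`, `relative`, `logit`,
`log10`, `hellinger`, `intensity`, `per_week`) and a provenance trail.
Transforms refuse inputs with incompatible units, which catches the most
common pipeline-wiring mistakes (e.g. logit on raw counts).

## Profile processing

Order of operations: blacklist filter on counts → relative-abundance
normalisation → prevalence filter → transform. Two choices deserve note.

*No renormalisation after filtering.* After non-fungal zOTUs and rare
features are removed, retained columns keep their original relative values
(per-sample row sums drop below one). Renormalising would silently change
the `x` entering the logit and log10 formulas; keeping the original
denominator preserves `x` = fraction of all mapped reads.

*Logit clamp.* `ln(x/(1−x))` is undefined at 0 and 1. Entries are clamped
to `[1e-6, 1−1e-6]` before the transform; 1e-6 reuses the minimal non-zero
value that the log10 transform (`log10(x+1e-6)+6`) already defines, so both
transforms share one floor. An absent feature therefore maps to
`ln(1e-6/(1−1e-6)) ≈ −13.8155` on the logit scale — a deliberate, visible
sentinel for absence, with consequences for classifier power discussed
below.

*Prevalence boundary.* "Present in more than 10% of samples" is read
strictly: at 10 samples, presence in exactly 1 sample is insufficient. The
filter is idempotent.

## Diversity and ordination

Shannon diversity uses the natural logarithm (the common ecology default;
the base is recorded in the output name only, no rescaling is applied
anywhere downstream). Bray–Curtis distances are computed with scipy and
wrapped in a scikit-bio `DistanceMatrix`.

PCoA eigendecomposes the Gower-centred matrix `−½ J D² J`. Bray–Curtis is
not Euclidean, so negative eigenvalues occur; they are retained in the
reported spectrum, excluded from the proportion-explained denominator, and
no coordinates are produced for them. Axis signs are canonicalised (the
largest-magnitude coordinate on each axis is made positive) so repeated
runs and compiler/BLAS variations cannot flip figures.

PERMANOVA partitions the squared-distance sum into within- and
between-group components; `F = (SS_A/(a−1))/(SS_W/(n−a))`, and
`p = (1+#{F_perm ≥ F_obs})/(1+n_perm)` with label permutations driven by an
explicit seed (default 999 permutations, so the attainable floor is 0.001).
The pseudo-F is cross-checked against scikit-bio's implementation in the
test suite; the permutation loop is kept in-package so that p-values are a
pure function of the seed.

Feature-axis screening computes Spearman rho of every feature against a
chosen principal axis with BH adjustment across features. Constant features
have undefined rho and are excluded from the BH family rather than counted.
P-values use scipy's t-approximation at every sample size; no exact
small-sample enumeration is attempted.

Group tests: two groups use the two-sided Wilcoxon rank-sum
(Mann–Whitney U, exact for small tie-free samples), three or more use
Kruskal–Wallis.

## Permutation-null SVM biomarker significance

The question: does the community predict the phenotype better than chance,
and which features carry the signal? The procedure makes no parametric
assumption about the data; chance is defined empirically.

Each *iteration* draws a fresh stratified tenfold split (re-drawn if a test
fold is single-class), trains a linear SVM (C = 1, no inner tuning) per
fold with inverse-class-frequency weights (`n/(2·n_class)`), and records
the mean held-out fold AUC and the mean fold-level coefficient vector.
Features are standardised within each training fold before fitting — the
default behaviour of the common linear-SVM front-ends, and necessary here
because rare features (variance inflated by the −13.8 absence sentinel)
would otherwise dominate the margin. 100 iterations are run with true
labels and 100 with labels permuted anew each iteration.

Per feature, `z = (w̄_true − w̄_null)/SD(w_null)` with a two-sided normal
p-value and BH adjustment; features with zero null SD are flagged and
excluded from the family. The positive class is the control group, so
negative coefficients mark case-associated features. Sensitivity is the
recall of the case class, specificity the recall of the control class, both
at the default decision threshold. AUC distributions (true vs shuffled) are
compared with a two-sided rank-sum test — robust and assumption-free for
two samples of 100 iteration means.

This z-test is *calibrated*: under a global-null cohort its feature-level
rejection rate at α = 0.05 sits at ~0.05–0.06 (tested over replicate null
cohorts). The calibration has a power cost that users should understand.
The null SD of a shuffled-label SVM coefficient is approximately the
sampling SD of a spurious class-mean difference, so |z| is bounded above by
roughly the univariate t statistic of the feature. On sparse logit
profiles, where a feature with 90% prevalence carries 10% of observations
at the −13.8 sentinel, per-feature SDs run 2–5 logit units and a 1.5
natural-log fold change corresponds to a standardised effect of only
d ≈ 0.3–0.6 — below what BH-corrected discovery across ~138 features can
reliably recover at n = 144 (measured recall ≈ 0.02–0.12, though median |z|
of planted features is strictly monotone in effect size). Alternative
readings of the "single-sample z-test" that divide the null SD by √n_null
gain power only by being ~10× anti-conservative and were rejected for
failing null calibration. In short: on data of this shape the procedure
reliably answers "is there signal at all?" (AUC comparison) but individual
feature calls at moderate effect sizes are power-limited — a property of
sparse compositional data, not of the implementation.

## Co-inertia and the RV coefficient

Each processed block becomes a duality-diagram triplet: columns centred
(optionally unit-variance scaled; off by default since the source analyses
never scale) under uniform row weights `1/n`. Co-inertia is the SVD of
`XᵀDY`; squared singular values are the axis co-inertias, their sum the
total co-inertia, and the covariance of paired row scores along axis k
equals `√λ_k` (asserted in tests). The RV coefficient is the trace formula
given in the README; the SVD route and a brute-force trace evaluation are
compared to 1e-8 on random instances in the test suite.

Block transforms mirror standard practice for each data type: mycobiome
log10, bacteriome Hellinger, metabolome log10, diet left as counts/week.
Significance comes from Monte-Carlo permutation of the rows of the first
table (equivalent to permuting either side under uniform weights), default
999 rounds, `p = (1+hits)/(1+n_perm)`.

A caution on comparing raw RVs across block pairs: the null expectation of
RV depends on the effective dimensionality of the blocks (a 40-feature diet
table has a higher null RV than a 120-feature bacteriome against the same
mycobiome). Concordance claims across blocks should therefore be made via
the permutation p-values, not by ranking raw RVs — which is how the
package's own concordance test is phrased.

## Synthetic cohorts

The generator produces cohorts with the statistical structure this pipeline
assumes, so every stage can be validated end-to-end without external data.
Defaults describe a 144-sample cohort (80 cases, 64 controls), 1631 raw
zOTUs, per-sample richness log-normal with median 60 (log-sd 0.362,
matching an IQR near 46–75), read depth log-normal with median 45,000, and
a feature-popularity mixture — a "core" of 152 common zOTUs with
descending-sorted log-normal weights plus a rare tail at 1.2% relative
weight — sized once so that the >10% prevalence filter retains ~138
features (observed 138–145 across seeds). Eight dominant taxa
(*Saccharomyces*, *Candida*, *Debaryomyces*, *Penicillium* analogues)
receive a +2.5 log-abundance boost; they sit mid-core rather than at the
prevalence head, deliberately decoupling dominance from prevalence —
planting a multiplicative effect on an already-dominant taxon mostly
perturbs the compositional denominator (spilling signal onto every other
feature) rather than the taxon itself, so default effect targets are the
most *prevalent*, not the most *abundant*, features.

Per sample: richness → weighted feature draw without replacement →
log-normal abundances (feature baseline sd 1.2, per-observation noise sd
1.0) plus latent-factor contributions and planted case effects → soft-max
to relative abundance → depth multiply and round to counts. Planted
effects are natural-log folds applied multiplicatively to relative
abundance in case samples before renormalisation; `PlantedEffect.log_fold`
is in natural-log units throughout.

Paired blocks are linear-Gaussian in log space sharing a per-sample latent
factor matrix `Z` (default 2 factors, loading sd 0.8) between mycobiome,
bacteriome and metabolome; diet (Poisson counts/week) is generated
independently of `Z`, making mycobiome-diet concordance a true null by
construction. Everything is a pure function of the config seed;
equal-config runs are bit-identical.

What the generator does *not* emulate: sequencing error, chimeras or
denoising artefacts; phylogenetic correlation between features;
abundance-dependent detection beyond the rounding step (presence is drawn
from the popularity weights independently of the latent factors); batch or
library-size confounding with group. Passing tests therefore demonstrate
correctness and calibration of the statistics on realistically sparse,
heavy-tailed compositions — not robustness to every artefact of real
amplicon data.

## Problem sizes used in the validation suite

Null-calibration suites use 500 replicate tests at 30 samples for the
permutation tests and 10 replicate global-null cohorts (54 samples, 300 raw
zOTUs) for the coefficient z-test; the power-monotonicity curve uses 3
effect sizes × 50 reduced-scale cohorts; concordance and shuffled-AUC
checks run at full cohort scale (144 samples). These sizes were chosen to
give stable rates (binomial SE ≲ 0.01) while keeping the default test run
in the minutes range.

## Known limitations

- Feature-level discovery power on sparse logit profiles is bounded by the
  univariate signal (see the biomarker section); the package reports honest
  calibrated p-values rather than optimistic ones.
- PERMANOVA is the one-way design only; no strata/blocking, no db-RDA.
- Distances are taxonomy-blind (no UniFrac); co-inertia covers exactly two
  tables (no multiple co-inertia, no sparse variants).
- The classic-BIOM reader handles the TSV export only, not HDF5 BIOM.
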