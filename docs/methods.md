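# Methods

This note records the models implemented in `clonoprev`, the assumptions
behind them, the parameters that matter, and the numerical and design
choices made where more than one defensible convention exists. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## ddPCR quantification

A ddPCR reaction partitions template into droplets of volume
`V_d = 0.85e-3` ul within a `V_r = 20` ul reaction loaded with `V_i` ul of
input sample. Template molecules occupy droplets as a Poisson process, so
the mean copies per droplet is `-ln(1 - P/T)` for `P` positive of `T`
droplets, and the input-sample concentration is
`C = -ln(1 - P/T)/V_d * V_r/V_i` copies/ul. Assumptions: droplets are
uniform in volume, occupancy is independent, and a droplet is positive
iff it holds at least one target copy. `P = T` (saturation) makes the
estimate diverge and raises an error rather than clipping.

Replicate wells (4 per sample-assay in the screening design) are pooled
by summing counts *before* quantification and before the positivity call,
because one result is reported per sample-assay; the >=3-droplet
positivity rule therefore applies to the pooled counts.

Genome equivalents use a 3.3 pg haploid human genome mass (exposed as a
parameter), giving 151,515 copies for a 500 ng input — 150,000 at two
significant figures. Significant-figure rounding is half-even everywhere;
raw values are always retained.

**Limit of detection.** The detection limit of a screen of `G` genome
equivalents is defined as the VAF whose expected mutant-copy load
`lambda*` gives a 95% probability of at least 3 positive droplets under
Poisson counting: `P(Poisson(lambda*) >= 3) = 0.95`, solved by bracketed
root finding on the Poisson survival function (`lambda* ≈ 6.30`), then
`LOD = lambda*/G * 100%`. This is a modelling choice — the assay vendor's
derivation is not public — adopted because it reproduces the commonly
quoted 0.004% VAF at 150,000 copies; at 265,000 copies it gives 0.0024%.
It assumes one mutant copy yields one positive droplet, neglecting
multi-occupancy of the variant; below 0.1% VAF this error is negligible.

## Per-cell prevalence (rejection ABC)

The screening cohort is `n_samples = 253` samples x
`assays_per_sample = 5` mutation-specific assays, each interrogating
`copies_per_assay = 150,000` genome equivalents with a
`positivity_threshold = 3` copy rule. Generative model: each cell carries
a given mutation independently with per-cell per-mutation-type rate `mu`,
so a test's mutant-copy count is `Poisson(mu * G)` and the test is
positive iff the count reaches the threshold. Droplet-level detection is
assumed perfect and clonal clustering of mutant cells is not modelled;
both assumptions make the inferred `mu` an *effective* per-genome rate.

Inference is rejection ABC with:

- prior: log-uniform on `[1e-9, 1e-5]` (spans plausible somatic
  prevalences; configurable),
- summary statistic: total positive sample-assay tests,
- distance: absolute difference; tolerance default 0 (exact count),
- point estimate: posterior median; interval: equal-tailed quantiles with
  numpy's linear interpolation.

Inside an ABC batch the positive-test total for each proposed rate is
drawn as `Binomial(n_tests, P(Poisson(mu*G) >= threshold))`, which is the
exact marginal distribution of the per-test construction — a pure speed
optimization, not an approximation. The public `simulate_screen` draws
the per-test Poisson counts explicitly. Zero acceptances raise an
explicit error advising a larger tolerance or proposal count.

The calibration test runs 50 synthetic cohorts at each of three true
rates spanning the prior (1e-8, 4e-7, 4e-6) with one million proposals
per fit; at that proposal count the accepted-sample quantiles track the
exact posterior closely (verified against a fine-grid posterior during
development). Note that equal-tailed 95% credible intervals are Bayesian
objects; their frequentist coverage at a fixed true rate hovers near, and
occasionally just at, the 90% bound the tests require.

An observed total of 42 positive tests is provided as a reconstruction of
the study-scale reanalysis fixture (38 patients + 1 second-mutation
detection + 3 autopsy-cohort detections); it is an input, not a package
constant, and the resulting rate should be read as an effective rate
under this detection model.

## Signature attribution

Channels follow the COSMIC pyrimidine-reference convention; the canonical
order is substitution-class major (C>A, C>G, C>T, T>A, T>C, T>G), then 5'
flank, then 3' flank, alphabetical. A packaged index table
(`data/sbs96_channels.tsv`) pins the ordering and the reader reindexes
any catalogue to it, so row order in input files never matters. Purine
contexts are folded to the opposite strand.

Attribution is the posterior `P(s|c) ∝ exposure_s * profile_s[c]`,
normalized; it is invariant to global rescaling of the exposure vector,
and signatures with zero exposure are dropped before normalization. If no
active signature can emit the channel the mutation is reported as
unattributable rather than silently assigned.

The tobacco-carrier rule is applied per driver mutation: a patient is a
non-carrier iff *every* driver's combined SBS4+SBS92 probability is
strictly below 0.5 (ties at exactly 0.5 classify as carrier, since
non-carrier status requires "< 0.5"). Both the per-mutation values and
the patient-level aggregate are computable; the classifier uses the
per-mutation reading.

## Clone-expansion statistics

Foci are DBSCAN clusters of cell centroids with Euclidean distance,
inclusive boundary (`d <= eps`), `eps = 35` in the coordinate units of
the input table (pixels in the source imagery; unit handling is the
caller's responsibility). `min_pts` defaults to 1 — every point is core,
so the clustering equals the connected components of the
eps-neighbourhood graph and singleton foci are counted. This choice is
required for an average focus size of ~2 cells to be representable
shortly after oncogene induction; it is exposed as a parameter. A focus
is "expanded" when it holds strictly more than 5 cells (one expected
division of wild-type alveolar cells between observation points means
clusters beyond ~4 cells exceed normal turnover; the strict >5 rule is
conservative). The clustering is deterministic under input permutation;
the equivalence with brute-force graph components is property-tested for
`min_pts <= 2`.

## Normal-tissue variant filtering

Variant identity for tumour-normal matching is the
(patient, gene, normalized variant string) triple, since the screening
assays are addressed by protein change. The contamination filter removes
a normal-tissue call when the variant appears in *any* tumour region of
the same patient (union over regions). Driver filtering keeps cancer gene
census members at or above a chosen evidence tier
(strong > some > weak > none); unannotated variants rank as `none`. The
high-confidence filter additionally requires >=2 supporting duplex reads
and strong evidence; calls lacking a read count are excluded with a
warning. The three filters are idempotent and stable under re-application
in pipeline order. Prevalence summaries count positive *samples* (so
duplicate calls within a sample cannot inflate them) and report percent
rounded half-even to the nearest integer. Attached statistical
comparisons (VAF t-test, proportion chi-squared) are delegated to scipy
and reported with two-sided p-values.

## Ecological epidemiology

Age standardization implements
`ASR = sum(w_i x_i/d_i)/sum(w_i) * 100,000` with packaged ESP 2013
(sums to 100,000 over 20 bands) and WHO 2000 weight tables. The Dobson
interval anchors the normal-theory variance of the weighted rate,
`v = sum(w_i^2 x_i/d_i^2)/sum(w_i)^2`, to the exact Poisson limits
`(X_L, X_U)` of the total case count `X` (chi-square quantile identity):
`R + (X_L - X)sqrt(v/X)` to `R + (X_U - X)sqrt(v/X)`, floored at zero.
With `X = 0` the scale `v/X` is 0/0; the package returns a zero lower
bound and an upper bound using the most conservative single-case scale
`max_i(w_i/d_i)/sum(w_i)` — a documented degenerate-input convention.

**Exposure windows.** The washout counts calendar years back from and
including the diagnosis year, minimum 1 (the diagnosis year itself is
never included): the window of up to `window_years` ends at
`diagnosis_year - max(washout_years, 1)`. This single rule reproduces
both published conventions — a 2018 diagnosis with no washout and a
10-year window averages 2008–2017, and a 2017 diagnosis with a 2-year
washout averages up to 2015 (2006–2015 when the series starts in 2006,
truncation via `min_year`). Missing years inside the window raise an
error; there is no silent imputation.

Weighted Pearson correlation uses weighted means throughout
(weights = tested cases per region, the natural precision weight for a
rate estimated from tests); it reduces exactly to the ordinary Pearson r
under equal weights and is invariant to weight rescaling and
sign-preserving affine maps. Exposure groups use linear-interpolation
(type-7) quantiles at 0.2 and 0.8 with strict inequalities for the low
and high labels; values equal to a cutoff are intermediate. Robust
regression, where needed on top of these correlations, is a delegated
contract (any M-estimator implementation); it is not re-derived here.

## Synthetic-data generators

All generators take a `numpy.random.Generator` or integer seed; fixed
seed gives bit-identical output, and the ground truth is always emitted
alongside so every downstream module has a parameter-recovery test.

What they emulate — and what they do not:

- `gen_droplets`: binomial droplet occupancy at the exact inverse of the
  concentration formula; no volume jitter, rain, or misclassification,
  so round-trip accuracy reflects counting noise only.
- `gen_cohort_screen`: the per-test Poisson detection model; no
  sample-to-sample DNA-input variation or clonal clustering, so ABC
  calibration results certify the inference machinery, not robustness to
  those violations.
- `gen_signature_mutations`: exact mixture sampling from signature
  profiles; no sequencing error or profile misspecification.
- `gen_cell_field`: Gaussian clumps with rejection-separated centres and
  Poisson background; exact-recovery fixtures use spread <= eps/4 and
  separation >= 4*eps. No imaging artefacts or segmentation error.
- `gen_normal_cohort`: planted real and tumour-shared variants with known
  labels; contamination removal is exact by key construction, so the
  corresponding test verifies bookkeeping, not sensitivity to identity
  ambiguity.
- `gen_region_table`: linear PM2.5–incidence relation with Gaussian noise
  and Poisson/binomial test counts (the heteroscedastic weights); no
  spatial autocorrelation or confounding.

Passing tests on these generators therefore demonstrate the estimators'
correctness and calibration under their own assumptions, not performance
on real data with the unmodelled features above.

## Problem sizes and defaults used in the test suite

Round-trip: 100 seeded replicates of 4x20,000 droplets at 241.38
copies/ul. ABC calibration: 3 rates x 50 cohorts on the 253x5 design,
tolerance 0, 1e6 proposals per fit. Attribution consistency: 5,000
mutations, total-variation bound 0.05. Clustering equivalence: 200 random
instances up to 200 points. These sizes were chosen so Monte-Carlo error
is small relative to each test's bound while the whole suite stays
interactive (about half a minute).

## Known limitations

- The LOD and prevalence models assume ideal droplet detection; real
  assays have chemistry-specific false-positive suppression that is not
  modelled.
- The ABC rate is an effective per-genome-equivalent rate; mapping it to
  a per-cell biological rate assumes one genome per cell and no clonal
  structure in the sampled tissue.
- The per-cell frequency helper treats the k mutation types as
  independent; reciprocal "1 in N" summaries ignore posterior
  uncertainty unless taken from the results object's interval.
- Dobson intervals with zero total cases use a conservative convention
  (above) rather than an exact derivation.
- 3D clustering, image segmentation, duplex consensus calling and
  survival modelling are out of scope.
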