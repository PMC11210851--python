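# Methods

## Problem and scope

`emtprog` re-implements, as a tested pipeline, a prognostic analysis of
immunohistochemical (IHC) epithelial–mesenchymal-transition (EMT) markers
(E-cadherin, β-catenin, Fascin, Snail, Zeb-1) and stromal periostin (PN) in a
colorectal-cancer (CRC) cohort of roughly 200 patients.  Scores enter as
human-assigned tabular quantifications; image analysis, staining protocols
and any mechanistic biology are out of scope.  Because no patient-level data
are deposited anywhere we can read, the package ships a synthetic cohort
generator that emulates the published cohort's statistical structure, and
all validation is against (a) numbers whose inputs are fully printed and
(b) recovery of known simulation parameters.

## Scoring

*Weighted histoscore.* For each marker/compartment the examiner records the
percentage of tumour cells with none/weak/moderate/strong staining; the
score is `0·p0 + 1·p1 + 2·p2 + 3·p3 ∈ [0, 300]`.  The four fractions must
sum to 100 (tolerance 1e-9).  Precomputed 0–300 scores are accepted
interchangeably, since downstream stages only consume the scalar.

*Stromal periostin.* Percent positive stromal cells is binned to a grade
P ∈ {0,1,2,3} at 25/50/75; the printed integer bins (0–25, 26–50, 51–75,
76–100) generalise to half-open intervals `[0,25], (25,50], (50,75],
(75,100]` so fractional inputs are handled while integers reproduce the
printed bins exactly.  The score is P×I with intensity grade I ∈ {0..3},
range 0–9.

*Inter-rater agreement.* The source analysis reports only "interclass
correlation > 0.7" without naming a definition.  We use ICC(2,1) — two-way
random effects, single rater, absolute agreement — the standard choice for
scorer agreement, computed from the ANOVA mean squares; a consistency
variant (ICC(3,1)) is available via a flag.  The choice is recorded in the
run log.

## Dichotomization

Each continuous score is split LOW/HIGH (LOW: score ≤ cutoff) at the
threshold maximising the absolute standardized two-group log-rank statistic
over all distinct observed values — maximally selected log-rank statistics,
the method implemented by the common biomarker cut-off packages.  Every
candidate must leave at least `ceil(min_prop · n)` patients per arm
(default `min_prop = 0.10`, configurable); ties in the statistic break
toward the smallest cutoff, and tied scores are never split.  Only score
ranks matter, so the split is invariant under strictly monotone transforms.

No correction for the threshold search is applied (the source analysis
reports none), so single-marker p-values downstream are optimistic; every
run log flags this.  A subtlety verified during development: the maximiser
of the *standardized* statistic can legitimately sit one observation off an
apparent cluster gap, because the hypergeometric variance depends on group
balance — exact recovery of latent states holds only up to boundary
observations.

## Survival analysis

Kaplan-Meier curves use the product-limit estimator (events before
censorings at tied times); 5-year overall survival is `100·S(60 months)`.
Log-rank tests pool event times across groups with (k−1) degrees of
freedom.  Cox models maximise the partial likelihood with Efron tie
handling via lifelines; Wald 95% CIs and p-values are reported per
covariate.  lifelines implements Efron only, so no Breslow replication
flag is offered.

*Event definition.* The event is cancer death; non-cancer death and
alive-at-last-follow-up are censored.  This matches the published event
counts even though the text says "overall survival"; a configurable switch
(`all_death`) treats any death as the event, and an analysis driver
quantifies the sensitivity.

*Backward conditional selection.* Starting from the full model, the
covariate whose removal likelihood-ratio test (standard LR test between
nested refits; the null model's Efron partial log-likelihood is computed in
closed form) has the largest p ≥ `removal_alpha` is dropped, iterating
until all remaining covariates fall below the threshold.  The default
`removal_alpha = 0.10` follows the convention of the SPSS stepwise
procedures the original analysis used.  Ordinal clinicopathological
covariates (T 1–4, N 0–2, stage I–IV, differentiation) are coded as single
linear numeric covariates, matching a one-HR-per-covariate presentation;
the forced-entry column is computed both as one full multivariate model and
as per-covariate univariate fits, labelled explicitly, because the original
presentation is ambiguous between the two.

## Combined-marker models

FcFsPs combines stromal Fascin (Fs), cytoplasmic Fascin (Fc) and stromal
periostin (Ps); with pattern order (fs, fc, ps): good = {LLL, HLL, HHL,
HLH}, intermediate1 = {LLH, LHL}, intermediate2 = {HHH}, poor = {LHH}.
The model is intentionally not a HIGH-count rule — stromal Fascin is
protective.  FcSnPs (cytoplasmic Fascin, nuclear Snail, periostin) is a
pure count rule: 0–1 HIGH = good, 2 = intermediate, 3 = poor.  Group
contrasts are dummy-coded Cox fits against the good-prognosis reference
(the reference construction is not stated in the source; single-reference
dummy coding is assumed and documented here).  Groups with zero events are
reported as non-estimable rather than dropped.  Patients missing any
required stain are excluded from that model with logged counts.

## Associations

Cross-tabulations use pandas; independence testing uses Pearson's χ²
without continuity correction, except 2×2 tables with any expected count
below 5, which use Fisher's exact test (two-sided).  The original per-table
method choices are unverifiable, so the method used is always reported with
the p-value.  Zero-margin rows/columns are dropped with a warning.  The
significance threshold is 0.05 two-sided with no multiplicity correction,
flagged in the run log.

## Synthetic cohort generator

Latent LOW/HIGH states per marker/compartment are Bernoulli at the
configured prevalence; an optional shared "EMT activation" factor couples
the Fc/Sc/Sn/Ss/Ps states through a Gaussian copula whose thresholds keep
marginal prevalences exact (preset strength ρ = 0.3 — a free parameter, not
a published value, chosen to give realistic combined-model group sizes).
Observed scores are status-conditional: truncated normals on [0, 300] for
tumour markers (defaults: LOW location 80, HIGH 200, SD 40 — clearly
separated but overlapping, as real histoscores are), and for periostin a
status-conditional percentage (truncated normal) plus intensity grade, so
observed P×I values live on the 0–9 lattice.  A profile-emission mode
writes intensity fractions instead of histoscores to exercise the raw
scoring path (a score h maps to the exact profile `(100−h/3, 0, 0, h/3)`).

Survival is exponential with hazard `h0 · exp(Σ status·log HR)`; a Weibull
shape is exposed as an option.  Censoring combines an administrative window
(censor time ~ U(12, 104) months, emulating staggered accrual over a
104-month study), optional exponential dropout, and an independent
non-cancer death cause at 0.0017/month (≈ 17 non-cancer deaths per 202
patients over the window).  The preset transcribes all 19 marker/compartment
prevalences and univariate HRs from the published single-marker table, the
demographic proportions from the published demographics table (where a
printed percentage disagrees with its count — N2, 46/185 — the count wins),
and per-protein assay counts (148/148/148/152/192/202).  The preset
baseline hazard is calibrated so the cohort-average marginal cancer hazard
is 0.009/month, reproducing ≈ 57 cancer deaths per 202 patients under the
preset censoring.

*Non-collapsibility caveat.* The preset applies the published univariate
HRs as conditional multiplicative effects of 19 simultaneous markers.
Hazard-ratio non-collapsibility means marginal univariate HRs re-estimated
from such a cohort are attenuated relative to the conditional inputs, so
parameter-recovery experiments use focused simulators instead: a two-group
exponential cohort for single-marker HRs and a direct group-label cohort
for the combined-model HRs — exactly the designs whose truth the estimates
should match.

*What passing tests do not show.* The generator draws statuses, scores and
demographics independently of each other (apart from the EMT factor), has
no score-measurement batch effects, no informative censoring, and constant
hazards; agreement of the pipeline with simulation truth therefore
validates the estimators and plumbing, not the biological claims of any
particular cohort.

## Problem sizes and numerical choices

Recovery experiments use n = 50,000 (single markers, 2% check) and
n = 20,000 (combined models, 5% check) — at these sizes the Monte-Carlo
standard error of a log-HR is comfortably inside the check bands for all
groups except the rarest (4–6% prevalence), where the band is ≈ 1.4 SE;
calibration checks use 1,000 replicates (χ² test size at n = 300, Cox CI
coverage at n = 500).  Cutpoint scans evaluate every admissible observed
value (O(n·k) per candidate; exact, no quantile pre-binning).  Percentages
are half-up rounded to one decimal from exact integer ratios (Decimal
arithmetic, never float-rounded); HRs/CIs/p-values to three decimals.
Degenerate inputs (constant scores, zero events, constant covariates,
zero-margin tables, empty reference groups) raise typed errors rather than
returning silent defaults.

## Known limitations

* Cutpoint-selection bias is flagged but not corrected (no minimal-p-value
  correction), matching the source analysis.
* Only Efron tie handling is available for Cox fits.
* Exact independence tests are limited to 2×2 tables; larger tables always
  use χ².
* The backward "conditional" criterion is approximated by standard LR tests
  between refit nested models.
* The generator's marker inter-correlation structure (a single shared
  factor) is a modelling convenience; true inter-marker correlations are
  unreported.
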