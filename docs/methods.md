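# Methods

## Problem and scope

`mct-kit` estimates the within-patient meaningful change threshold (MCT) of
a target patient-reported outcome from a two-visit trial cohort, using the
standard anchor-based workflow with a distribution-based (half-SD)
supportive estimate, and triangulates the candidates into a single integer
recommendation. The target instrument throughout is the QLDS (0–34,
improvement negative); the anchors are the MADRS under three published
severity bandings, the two CGI suicidality global impressions, and the
EQ-VAS. The package does not model treatment efficacy, longitudinal
trajectories, or item-level psychometrics; the only distribution-based
method offered is half the SD of change (no SEM or reliable-change index).

## Severity bandings

MADRS totals are integers, so the three built-in bandings are stored as
closed integer intervals; a published exclusive bound such as "> 28–60" is
encoded `[29, 60]`, which removes any open-interval ambiguity. Construction
validates that each banding tiles 0–60 exactly and that the ordinal
severity index (0 = no depression … 3 = severe) strictly increases across
bands. Band labels are configurable text; the second band is labelled
"slight depression" in all three built-ins (the literature uses "slight"
and "mild" interchangeably for this level), and the index, not the label,
drives every computation.

## Change construction and missing data

Changes are endpoint − baseline, computed only for patients present at both
visits; category change (baseline index − endpoint index) and CGI point
change (baseline − endpoint) are improvement-positive recodings. Missing
scores are never imputed: each analysis applies pairwise complete-case
deletion over exactly the pair of variables it uses, which is why per-anchor
n's can differ within one run. Rows with partially missing QLDS item sets
are rejected outright rather than prorated — with 34 binary items there is
no published prorating rule for this instrument, and refusal is the only
behavior that cannot silently bias a total.

## Anchor qualification

Spearman correlation is computed on midranks with the t approximation
(n − 2 df) for the p-value; an exact permutation p-value is available for
n ≤ 8. The qualification rule is |ρ| ≥ 0.40: the magnitude, not the signed
value, because a health-state anchor (EQ-VAS) is expected to correlate
*negatively* with a symptom-impact target and is no less informative for
it. Anchors failing the gate are skipped with a warning; grouping can be
forced for exploration, which also warns.

## Group summaries and candidates

Groups are **exact**-change groups ("improved exactly one category"), not
cumulative ones; per-category group means only make sense under exact
grouping, and cumulative grouping remains available behind a flag. Sample
SDs use n − 1 throughout; the 95 % CI is mean ± t₀.₉₇₅,ₙ₋₁·SD/√n; the
median of an even-sized group is the midpoint of the middle two values.
SRM = mean/SD of the group's change. SES = mean divided by the baseline SD
of the **full analysis set** (configurable): the group's own baseline SD
would make effect sizes incomparable across groups of very different size.
With n = 1 or zero SD, CI and SRM are reported as undefined, never as 0.
Groups with n below 25 are flagged (not excluded): one-category groups in
the 20s have been observed to destabilize MCT estimates.

The default candidate set is: the one-category (or one-point) improvement
group mean for every qualified categorical/ordinal anchor, each MADRS
banding counted separately; the OLS projection β₀ + β₁·7 for a qualified
EQ-VAS (its published individual-level threshold being 7 points); and half
the SD of the target change. Every element can be excluded by config. The
regression always uses full-precision fitted coefficients, not rounded
ones — projecting from two-decimal coefficients can move the result by
~0.01, which matters when candidates are compared at that resolution.

Triangulation reports mean, median and range of the candidates and
recommends the integer nearest the median, rounding half away from zero and
keeping the improvement sign. Mean and median are the only pooled
statistics; no candidate weighting is attempted because candidate n's are
not comparable across sources.

## Responder CDF curves and separation

Empirical CDFs of the target change are emitted per anchor category as
right-continuous step tables (CSV), so any plotting stack reproduces the
figures; plotting is not part of the contract. Visual "separation" between
adjacent category curves is quantified by the two-sample Kolmogorov–Smirnov
distance sup|F₁ − F₂| — an operationalization this package adds; published
analyses typically assert the separation visually.

## Synthetic cohort generator

The generator emulates the structure the estimators assume, with defaults
matching a published trial-sized cohort in depression with active suicidal
ideation (n = 224): QLDS baseline 27.24 (SD 6.40) with change −12.46
(11.26); MADRS 41.1 (6.07), change −23.2 (13.03); EQ-VAS 42.0 (24.44),
change +20.7 (25.15); CGI latents centred on "markedly" with a roughly
two-level mean improvement; endpoint missingness 10 % (a realistic
four-week dropout, applied as whole-visit blanking).

Three design choices matter:

* **Correlations are targets on the rank scale.** The configured 5×5 matrix
  is the target Spearman correlation of changes (defaults: QLDS–MADRS 0.66,
  QLDS–CGI 0.43/0.44, QLDS–EQ-VAS −0.53, with plausible anchor–anchor
  values, the published sources reporting none). It is converted to the
  latent Pearson scale by the Gaussian-copula identity r = 2 sin(πρₛ/6)
  before sampling, so the realized rank correlation matches the configured
  number up to discretization effects rather than sitting ~0.02 below it.
* **Baseline–change coupling.** Each instrument's change is correlated with
  its own baseline (defaults −0.27 QLDS, −0.38 MADRS, −0.62 EQ-VAS,
  back-solved from the published endpoint SDs; −0.40 for the CGIs, whose
  endpoint SDs are unpublished). Without this regression-to-the-mean
  coupling, independent sampling inflates the endpoint spread and range
  clipping then badly attenuates both the change SDs and the correlations.
  Because baselines are independent across instruments, the cross-
  instrument residual correlations are inflated by 1/√((1−ρⱼ²)(1−ρₖ²)) so
  the configured change correlations survive the coupling; infeasible
  combinations are rejected at config time, as is any non-PSD matrix.
* **Discretization last.** Scores are rounded and clipped to instrument
  ranges (CGIs discretized through configurable cut points, by default
  half-integer boundaries). Clipping piles mass at the floors/ceilings that
  real bounded instruments also exhibit, but it attenuates realized SDs
  (QLDS change SD ≈ 9.8 against the 11.26 input at n = 5000) and shaves a
  few hundredths off rank correlations; the QLDS–MADRS Spearman realizes
  ≈ 0.655 against the 0.66 target. Checks against configured values budget
  ±0.05 for this.

What the generator does **not** emulate: treatment-arm effects (arms are
labels only; the published analyses pooled arms), intermediate visits,
item-level QLDS response processes, informative dropout, and the skewness
of real bounded-scale distributions beyond what clipping a normal induces.
Passing tests on synthetic cohorts therefore demonstrate estimator
correctness under the stated moment/correlation structure — not robustness
to real-data pathologies such as floor-heavy non-normal changes.

### Grouped ground-truth mode

`generate_grouped_cohort` fixes each patient's MADRS category change by
construction (baseline drawn in the most severe band, endpoint drawn in the
band exactly k levels lower) and draws the integer QLDS change *first*,
normal around the configured group mean (defaults 0/−8/−15/−20 for k =
0..3, SD 9, group sizes 90/150/120/90 ≈ a 450-patient cohort), then draws a
baseline inside the range that keeps the endpoint on-scale. Drawing the
change first means it is never clipped, so the realized group mean is an
unbiased realization of the configured truth — the property that makes CI
coverage of the known −8 a meaningful check. The QLDS baseline in this mode
uses a tighter SD (4) than the marginal generator, trading marginal realism
for on-scale headroom.

## Numerical and reproducibility choices

* All stochastic operations take explicit integer seeds (NumPy
  `default_rng`); the packaged demo cohort uses one fixed documented seed
  (20220710). Identical config + seed gives byte-identical outputs,
  including the report files (JSON is written with sorted keys and no
  timestamps; the run log carries seeds, versions and dropped-row counts).
* OLS is estimated by statsmodels; Spearman and KS statistics by scipy.
  Both are checked in the test suite against independent brute-force
  oracles (enumeration midranks + Pearson-on-ranks; max pooled ECDF gap).
* Degenerate inputs fail loudly: < 3 pairs or zero variance for
  correlation, zero anchor variance for regression, empty groups and empty
  candidate sets everywhere.
* Problem sizes: marginal/correlation checks use one n = 5000 cohort;
  recovery uses 50 replicates of the 450-patient grouped design (the
  50-replicate binomial check of 95 % CI coverage uses a ≥ 90 % pass line);
  oracle-equivalence checks use 1,000 random small instances per statistic.

## Known limitations

* The Spearman target matrix is honoured on the latent scale; heavy
  clipping configurations (means near a scale boundary) will realize
  noticeably weaker correlations, and the generator does not iterate to
  compensate.
* The half-SD estimate inherits the usual criticism of distribution-based
  thresholds — it reflects sample variability, not patient meaning — and is
  included as supportive only; on clipped synthetic cohorts it is further
  shrunk by the SD attenuation noted above.
* Triangulation composition is explicit and configurable precisely because
  published pooled values are generally not reconstructible from printed
  per-anchor results; users comparing against a published pooled mean must
  match the candidate set themselves.
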