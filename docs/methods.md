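# Methods notes

This note documents the models, defaults, and design choices behind
`medconn`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. MeDi scoring (`medconn.ffq`)

Eleven food categories are scored 0–5 from monthly serving frequencies and
summed to a 0–55 index. Seven favorable components (non-refined cereals,
potatoes, fruits, vegetables, legumes, fish, olive oil) score the band
index of their intake; three unfavorable components (poultry, red meat,
full-fat dairy) score `5 − band`, so higher scores mean lower intake.
Alcohol follows a fixed unimodal rule: 0 for no consumption, then 5, 4, 3,
2, 1 for 1–2, 3–4, 5–14, 15–30, 31–60 servings/month, and 0 above 60.

Numerical conventions, all covered by tests:

* **Band edges.** The five edges per non-alcohol component are
  configuration, not constants of the index; published descriptions of the
  0–55 index do not pin them. `DEFAULT_BANDS` gives documented defaults
  (wider bands for near-daily foods), and every test pins explicit edges so
  no result depends on a silent default.
* **Fractional intakes.** Bands are half-open `[edge, next_edge)`; an
  intake equal to an edge falls in the band that edge opens (alcohol at
  2.5/month scores 5, because the printed 1–2 and 3–4 integer bands are
  implemented as [1, 3) and [3, 5)).
* **Alcohol in (0, 1).** Scored 0: the printed band sequence starts at one
  serving/month, so sub-monthly drinkers fall below the lowest band.
* **Tertiles.** Group cutpoints are the empirical 1/3 and 2/3 quantiles
  (NumPy's default linear interpolation); subjects exactly at a cutpoint go
  to the lower group, which makes the labels order-invariant and keeps all
  tied subjects together. Fewer than three distinct totals is an error
  rather than an arbitrary split.

## 2. Connectivity summarization (`medconn.connectivity`)

Per subject-visit, the ROI-by-ROI Pearson matrix is Fisher z-transformed
and masked: the diagonal, pairs of ROI centers closer than 20 mm, and
negative correlations are invalid. Masked pairs are excluded from both
numerator and denominator of every mean — averaging literal zeros for the
sub-20-mm pairs would deflate means of positive values, so "set to zero"
is implemented as "excluded". The distance rule is strict (`< 20 mm`); a
pair at exactly 20.0 mm stays valid (boundary covered by a test).

Summaries over the ten named networks (Hand 30, Vis 31, Mouth 5, Aud 13,
DMN 58, Sal 18, CO 14, FP 25, DAN 11, VAN 9 ROIs; the 50 remaining ROIs
are unassigned and never summarized):

* one within-network mean per network (10 values);
* one mean per unordered network pair (45 values);
* `overall_within` / `overall_between` = unweighted means of those 10 / 45
  values (network sizes do not weight the overall summaries);
* a per-network "between" value, by default the **pooled** mean over all
  valid ROI pairs spanning that network and the other nine; the
  alternative (unweighted mean of its nine block means) is available via
  `between_mode="blocks"`, since the verbal definition of that quantity is
  ambiguous between the two.

Means are taken on the z scale by default (`domain="z"`), matching the
transform-then-average order of operations; raw-correlation averaging
(`domain="r"`) is retained for sensitivity analyses, and the choice is
recorded in output metadata. A block with no valid pair yields NaN that
propagates to the overall means — never a silent zero. Degenerate
off-diagonal |r| = 1 is nudged inside (−1, 1) before `arctanh`; the
negative-value exclusion is applied per pair per subject-visit, at the
matrix stage, not to subject-level summary values. Longitudinal change is
follow-up − baseline, field-wise.

## 3. Cognitive composites (`medconn.cognition`)

Each of four domains (FLUID, MEMORY, SPEED, VOCAB) aggregates up to six
tasks. Tasks are z-scored against reference parameters, timed/reaction-time
tasks are sign-flipped after z-scoring (algebraically identical to
z-scoring the negated values, but keeps the raw scale inspectable), and the
aligned z-scores are averaged. Conventions:

* **Reference population.** "The entire cohort" is ambiguous across
  visits; the default reference is the baseline visit's mean/SD applied to
  both visits, so change scores reflect raw longitudinal change rather
  than being re-standardized per visit. A pooled-visit reference and an
  externally supplied parameter table are both available.
* **SD estimator.** Sample SD (n−1) by default, configurable; tests pin
  the convention wherever it matters.
* **Missing data.** A composite is never computed from zero tasks; the
  count of contributing tasks is carried in the output, and a subject
  missing a visit is dropped from change scores with a log entry.

## 4. Moderation models (`medconn.models`)

The core model is OLS of a domain change score on Δconnectivity, MeDi
group (treatment contrasts vs the low group), their products, and eleven
covariates (age, sex, two race/ethnicity indicators vs non-Hispanic white,
education, NART IQ, caloric intake, scrub %, mean cortical thickness,
total brain volume, log-transformed WMH volume, mean FA). WMH is always
entered after log transform. Inference is Wald-style — normal critical
values for CIs and p-values, and a joint chi-square b′V⁻¹b over the
interaction coefficients (df = number of interaction terms; 2 for the
tertile moderator, 1 for continuous MeDi) — mirroring generalized-linear-
model output conventions; classical t-based inference is available with
`use_t=True`, and for a single interaction term the chi-square equals the
squared z-ratio exactly. Significance conventions: 0.05 for main terms,
0.10 for interaction terms; no multiple-comparison correction is applied,
and the pipeline log carries the count of tests performed instead.

Stratified slopes refit the covariate-adjusted model within each MeDi
group; age-stratified analyses refit the full moderation model within age
tertiles (same tie rule as MeDi tertiles). Complete cases only — the
design mirrors an up-front exclusion cascade, so no imputation. Rank
deficiency raises an error naming the collinear columns; strata too small
for the parameter count are flagged as missing cells, never zeros.
Descriptive group comparisons use one-way ANOVA for continuous variables
and uncorrected Pearson chi-square for categorical ones.

## 5. Synthetic cohort (`medconn.synthetic`)

The generator's defaults define the study conditions:

* **Parcellation.** 264 ROI centers placed uniformly in a
  140×170×140 mm box with a 10 mm minimum separation (rejection
  sampling); 5% of ROIs are deliberately relocated within 20 mm of a
  partner so the distance mask is exercised. Requesting planted near pairs
  with `min_pair_distance ≥ 20` is an error.
* **Time series.** Stationary zero-mean multivariate normal with block
  covariance: within-network target correlation 0.28 at baseline and
  0.265 at follow-up, between-network 0.12 and 0.108 — small negative
  drifts in both summaries, consistent with five-year change SDs of
  roughly 0.06–0.10 once per-subject-visit jitter (SD 0.05, clipped to
  preserve positive definiteness) is added to the targets. 280 volumes per
  visit (~9.5 min at TR = 2 s). No temporal autocorrelation is simulated:
  the summaries depend only on spatial structure, and temporal filtering
  is out of scope. Positive definiteness is checked at construction and a
  violation is a configuration error.
* **Planted moderation.** Memory change = −0.144 + slope(group) ×
  Δ between-network connectivity + small covariate effects + N(0, 0.6²),
  with default slopes −4.397 (low), −0.751 (moderate), +3.287 (high) — a
  sign-flipping moderation pattern of realistic magnitude. Other domains
  drift with fixed means/SDs and no interaction.
* **Tasks.** Native-unit task values are affine images of a latent domain
  ability plus a stable subject×task offset (SD 0.3); with the default
  zero visit-specific task noise, composites standardized against the
  generator's reference parameters change by exactly the planted amount —
  the refit-the-generating-model consistency checks rely on this.
* **FFQ.** A Beta(2, 2) adherence propensity drives favorable components
  up, unfavorable down, and alcohol toward the moderate band, so totals
  span the scale and populate all tertiles; caloric intake is mildly
  positively associated with adherence.
* **Roster.** Deterministic flags reproducing 562 → 254 → −25 (diet) →
  −55 (rsFC) → 174 → −49 (DTI FA) → −1 (WMH) → 124.
* **Seed discipline.** One master seed; every table, subject, visit, and
  replicate draws from `SeedSequence(seed, spawn_key=(stream, ...))` with
  fixed stream codes, so identical configs are byte-identical and any
  single subject-visit is independently reproducible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: temporal autocorrelation and filtering
artifacts, motion and physiological noise, spatially structured (rather
than exchangeable-within-block) connectivity, item-level FFQ responses
(category-level servings suffice), practice effects and measurement
non-invariance in the task battery, and covariate–connectivity
confounding beyond the planted model. Recovery results demonstrate that
the estimation machinery is correct under the assumed data-generating
process, not that the substantive effect exists in any real cohort.

## 6. Validation experiments (`models.recovery_experiment`)

Recovery and calibration replicate at the summary level: per-subject
Δconnectivity is drawn directly from its subject-level distribution
(mean −0.012, SD 0.072) and MeDi groups come from the full FFQ
simulation-and-scoring path, rather than re-running the time-series stage
per replicate. The time-series-to-summary stage is validated separately
(Monte-Carlo convergence of block correlations at 2 000 and 5 000 volumes,
tolerance 0.03–0.05, and an end-to-end pipeline run that recovers the
planted slope signs). Problem sizes used by the shipped experiments:
500 subjects × 200 replicates for slope recovery and CI coverage, and
500 × 1 000 replicates (all group slopes equal) for type-I calibration of
the joint interaction test at its 0.10 threshold.

## 7. Known limitations

* Non-alcohol band edges are conventions, not published constants; two
  studies using different edges will produce different totals (tertile
  groups are more robust).
* The pooled vs block-mean definition of per-network between-connectivity
  changes the exploratory per-network values (both are implemented; the
  overall 45-pair mean is unaffected).
* Wald (normal) inference is mildly anti-conservative at small stratum
  sizes relative to t-based inference; both are available, and coverage at
  the shipped problem sizes is within the 93–97% band tested.
* The exclusion cascade operates on roster flags; it does not model
  informative missingness.
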