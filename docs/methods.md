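# Methods

## Scope

`persnet` re-implements, as a reusable pipeline, the quantitative analysis of
personal (egocentric) social networks in people with multiple sclerosis
(pwMS) and controls: feature extraction from PERSNET-style survey exports,
covariate screening, cross-sectional feature→outcome regressions with an
MS-diagnosis moderation analysis, and a longitudinal within-subject analysis
of pandemic-era network change with a permutation-calibrated omnibus test.
Because the survey data are not public, a synthetic-cohort generator with
the same statistical structure is a first-class module: every analysis is
exercised, and the published effect sizes are used as generating truths for
parameter-recovery experiments.

## Network model and metrics

An ego network is the set of alters a respondent names, their attributes,
and the symmetric binary alter–alter tie matrix; the ego is tied to every
alter by construction of the elicitation and is excluded from the matrix.

Structural features (ego excluded from density and degrees, included for
constraint/effective size, the standard egocentric conventions):

- **size** `n` — number of alters;
- **density** `t / (n(n−1)/2)` with `t` the alter–alter tie count; undefined
  for `n < 2` (reported missing, never zero);
- **Burt constraint** `C = Σ_j (p_ij + Σ_q p_iq p_qj)²` with proportional
  investments `p` over each node's ties, reported ×100. Dyad → 100, star
  over `n` alters → `100/n`, ego plus a complete triangle → 92.59;
- **effective size** — Burt's non-redundant alter count, which reduces to
  `n − 2t/n` for binary symmetric ties; equals 1 for any complete network;
- **max/mean degree** — over the alter–alter graph. The alternative
  convention that counts the ego tie differs by exactly +1 per alter; we
  exclude the ego, consistent with density.

Compositional features: percentage of kin (kin relationship codes are
configurable; default spouse/partner/parent/child/sibling/other family),
sample SD of alter ages, normalized Blau heterogeneity
`(1 − Σ p_k²)/(1 − 1/K)` ×100 for sex (K=2) and race (K = number of
codebook race levels, 6 by default; "not sure" is treated as missing, and
the index is capped at 100), and percentages for contact frequency (weekly
or rarer), relationship duration (< 6 years), distance (> 15 miles),
drinking, smoking, sedentary lifestyle, poor diet, and perceived negative
health influence. Every percentage uses the non-missing denominator for its
attribute; an attribute missing for all alters yields a missing feature.

**Scale duality.** Descriptive tables report percentages 0–100; regression
models consume 0–1 proportions (and diversity/100), so a coefficient is the
outcome change from a network with none to all members having the
attribute. Constraint stays on its 0–100 scale everywhere.

## Cohort ingestion and covariates

Input is a three-file CSV export (participants, alters, undirected tie
pairs). Structural violations — malformed headers, contradictory tie
orientations, ties naming unknown alters, duplicate keys — raise; soft
issues (out-of-range scores, networks above the 25-alter soft cap) are
warnings with row numbers, so imperfect survey exports load reproducibly.

Covariate encodings are monotone so the screening rule can use a single
Pearson r per candidate: income bracket ordinal 1–9, education ordinal 1–6,
employment binary (employed for wages or self-employed), occupation binary
(professional/managerial), sex and race×ethnicity indicators (race and
ethnicity are dichotomized to non-Hispanic White vs other; a missing
component makes the dichotomy missing). Screening selects a covariate iff
it is present in > 70% of pwMS and has |r| ≥ 0.1 with p < .05 against **all
three** PROs (PDDS, MSRS-R, PROMIS Physical Function). Constant candidates
are flagged and excluded. Under the generator defaults this reproduces the
published covariate set: age, disease duration, employment, income.

Longitudinal linkage pairs each pandemic assessment with the most proximal
earlier baseline (latest date before it), computes elapsed time as
days/365.25 rounded to 2 decimals, excludes participants lacking either
timepoint (count logged), and treats a pandemic record dated before its
baseline as an error. Repeat prepandemic baselines are permitted and
disambiguated by assessment date; only the pandemic timepoint is unique
per participant.

## Statistical analyses

- **Group comparison** (18 features): Welch two-sample t tests with a
  Bonferroni family of m=18 (per-test threshold .05/18 ≈ .0028). Although
  a paired test is sometimes quoted for this comparison, pwMS and controls
  are independent samples with no pairing key, so the two-sample test is
  the defensible choice; paired t tests are reserved for the within-subject
  longitudinal changes.
- **Feature→PRO regressions**: OLS per (feature, outcome) on complete
  cases, pwMS models adjusting age, disease duration, employment, income;
  control models (PROMIS only) drop disease duration. 95% Wald CIs;
  Bonferroni family m=54 (per-test threshold .05/54, printed truncated as
  .00092). PDDS (ordinal 0–8) is modeled by OLS like the other outcomes,
  mirroring the single linear-regression framework; an ordinal link is out
  of scope. Rank-deficient designs raise with the collinear columns named.
- **Moderation**: joint pwMS+control OLS of PROMIS on feature, MS
  indicator, their interaction, and the control covariate set. Controls are
  the reference, so the control simple slope is the feature main effect and
  the pwMS slope is main+interaction, with CIs from the coefficient
  covariance; the feature's quartiles are reported as display anchors.
- **Longitudinal change**: paired t per feature; change (pandemic −
  baseline, regression scale) → pandemic PRO OLS adding elapsed years and
  study-cohort indicators to the covariates.
- **Omnibus**: Fisher's statistic `χ² = −2 Σ ln p` over the k=18 per-feature
  change-regression p-values per PRO, df = 2k analytically. Because the
  features are correlated, the analytic reference is not trusted: the
  outcome vector is permuted across participants B times (default 10,000),
  keeping the feature/covariate block intact — this preserves the
  inter-feature correlation under the null — the whole battery is re-fit
  per permutation, and the empirical p is `(1 + #{χ²_b ≥ χ²_obs})/(B+1)`.
  Exact p-values of 0 are impossible by construction (the +1 floor). A
  Freedman–Lane residual-permutation variant was considered and left out:
  permuting the raw outcome against the intact feature/covariate block is
  exchangeable under the null, and the calibration experiment in the test
  suite checks the resulting rejection rate against its nominal level.
  For cohorts of n ≤ 8 an exhaustive mode enumerates all n! permutations
  and matches independent per-permutation refits to exact counts.
- **Q-Q envelope**: per order statistic of −log₁₀ p, the 2.5th/97.5th
  percentiles across the same permutations; expected quantiles
  −log₁₀(i/(k+1)). Fewer than 40 permutations triggers a reliability
  warning.

### Numerical implementation

Permutation batteries use a thin-QR engine vectorized over permutation
columns (coefficients `R⁻¹QᵀY`, residual sums from the Pythagorean
identity), which agrees with `statsmodels.OLS` to ~1e-15 and makes 10,000
permutations × 18 regressions a few matrix products. Rows are canonically
sorted by participant id before permuting, so results are invariant to
input row order for a fixed seed. All randomness flows through
`numpy.random.default_rng` seeds; replicate seeds are spawned via
`SeedSequence` and kept below 2³¹.

## Synthetic cohort generator

The generator's defaults are calibrated to the published cohort moments
and are the study conditions for every calibration test; they are not
tuned per experiment.

- **Network size**: negative binomial truncated to 1–25 alters, parameters
  solved so the truncated mean/SD match the published values
  (cross-sectional pwMS 6.79/4.24, controls 6.78/3.90; longitudinal
  baselines 8.02/5.70 and 8.18/4.05).
- **Ties**: per-participant density drawn from a Beta matched to the
  published mean/SD (e.g. pwMS 0.76/0.25); ties i.i.d. within network.
- **Alter attributes**: kin flag (probability = published kin percentage),
  age Normal(48, 13) clipped to 18–95, per-network woman share
  Beta(1.8, 1.2) (between-network heterogeneity gives realistic sex
  diversity dispersion), race mostly White, contact-frequency categorical
  matched to the published "weekly or less" percentage, years known
  Gamma(2, θ) with θ set so P(< 6 y) matches, plus Bernoulli distance and
  behavior flags at the published percentages. The perceived
  negative-influence flag is logistic in the alter's behavior count
  (intercept −1.5, slope 1.1 → ≈36% prevalence), so it correlates with but
  is not identical to any single behavior — as observed, where behavior-
  specific features did not individually reach significance.
- **Participant covariates**: age Normal per arm, disease duration
  Gamma(4, 4) (pwMS only), employment/education/occupation/income
  categorical at the published frequencies, marital/cohabitant Bernoulli.
- **Outcomes**: MSRS-R and PROMIS are linear-Gaussian in the configured
  feature effects and covariate effects, with intercepts solved
  analytically so the expected outcome hits the published mean given the
  configured covariate expectations. Scores are deliberately not clipped
  to their nominal ranges: censoring at 0 would attenuate coefficient
  recovery by a censored-regression factor (~6–9% here), so a simulated
  MSRS-R can rarely dip below 0; range checks on ingestion are warnings
  for this reason. PDDS is a thresholded latent linear score with
  cutpoints placed analytically (Gaussian approximation of the latent
  marginal) at cumulative probabilities giving the published right-skewed
  distribution (mean ≈1.85, SD ≈2.1). Default effect sizes: negative
  influence → MSRS-R +2.181 (pwMS) and → PROMIS −5.707 (controls), the
  published principal associations; all other feature effects are zero.
  The default covariate effects make age, disease duration, employment and
  income — and only those — pass the screening rule.
- **Contraction operator** (longitudinal): each alter drops out with a
  probability depending on tie strength — *weak* alters (non-kin, contacted
  less than weekly) with 0.90, other non-kin with 0.225, kin with
  0.225 × (1 − 0.80) — then surviving ties are removed with a configurable
  probability (default 0). The three rates were solved analytically so the
  expected pwMS size contraction matches the published 8.02 → 6.63 and the
  kin share rises as published (46% → ~54%); a weak-only dropout cannot
  produce the observed ~17% contraction because only ~5% of alters are
  weak under the calibrated attribute marginals, hence the base rate. At
  least one alter always survives. Ages and disease durations advance by
  the planned elapsed time (uniform 1–4 years); pandemic PROs are drawn
  fresh from the outcome models on the contracted networks. The default
  longitudinal outcome model has **no** feature effects — the null that
  matches the published longitudinal finding and defines the conditions
  for the omnibus calibration experiments.

## What the generator does and does not emulate

It reproduces the marginal moments printed for the cohorts and the
assumed linear outcome structure. It does **not** model the real joint
distribution of alter attributes (independence within network, except the
behavior→influence link), assortative tie formation (ties are i.i.d. given
density, so degree distributions are binomial-conditional), item-level
missingness patterns, within-subject outcome correlation across timepoints,
or site geography beyond a categorical cohort effect. Passing recovery and
calibration tests therefore demonstrates that the pipeline estimates what
it claims under the assumed data-generating model — not that the published
coefficients are correct for the real cohort.

## Problem sizes and defaults

Default arm sizes follow the published analysis cells: 713 complete-case
pwMS and 1,250 controls cross-sectionally; 230/136 longitudinally. The
acceptance script uses 200 replicates per recovery experiment, 1,000
participants for contraction calibration, and B=999 with 100 seeded runs
for omnibus calibration (B=10,000 remains the analysis default, as in the
study); these replicate counts give Monte-Carlo SEs comfortably below the
tolerances they are checked against.

## Known limitations

- PDDS is treated as interval-scaled in OLS, as in the source analysis.
- The Blau race index defaults to codebook-K normalization; observed-K
  normalization is a documented alternative, not implemented as a switch.
- Complete-case analysis throughout; no imputation.
- The permutation scheme permutes outcomes; permuting features or
  residuals (Freedman–Lane) are alternatives the interface could host but
  does not currently expose.
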