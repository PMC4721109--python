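# Methods

## The exposure model

A respondent's lifetime is modeled as integer age-years `t = 0 … age−1`.
Each year receives:

- **Annual hours** from the exposure epoch containing `t`. Epochs are the
  half-open age bands [0,13), [13,20), [20,40), [40,65), [65,80), [80,∞);
  half-open boundaries avoid double-counting the shared endpoints. A
  respondent reports peak-window (10 am – 4 pm, hence ≤ 6 h) hours per
  weekday and weekend day within each band, combined as
  `(5·weekday + 2·weekend) × 52` hours/year. The 5:2 weighting is a
  documented convention: the instrument collects hours per day for the two
  day types but no weighting, and a plain week structure is the simplest
  consistent choice (maximum 2,184 h/year).
- **A UV index** equal to the average annual UV index of the anchor city
  nearest the residence occupied at the *start* of the age-year (mid-year
  moves resolve to the earlier residence, matching the one-location-per-year
  resolution of the model). Nearness is great-circle (Haversine) distance on
  a sphere of mean radius 6371.0 km; the radius is a documented constant,
  and exact distance ties break lexicographically by (city, state) for
  reproducibility.

The score is `CUES = Σ_t hours(t) × UVI(t)`, reported unitless (it is
proportional to W·h/m²; one UVI unit = 0.025 W/m² of erythemally-weighted
irradiance). For respondents with a skin-cancer history the diagnosis year
counts as "before" (`age_index < dx_age`), since the before-diagnosis score
means exposure accumulated up to diagnosis; a first diagnosis before age 18
is excluded. Both halves are computed with compensated summation and the
total of a case is defined as their sum, so `before + after = total` holds
bit-exactly rather than to rounding.

Deliberately out of scope: seasonal/diurnal UVI structure, posture or
body-site correction, and intermittency of exposure — the score is a
cumulative summary only.

### Reference tables

The anchor table ships with only the four cities whose average annual UV
indices are published (Anchorage 1.9, Seattle 3.3, Honolulu 9.3, San Juan
10.3); the full 58-city table is user-suppliable through the documented CSV
schema, and no values were invented to fill the gap. UVI values are stored
to the printed decimal and never rounded on load. Loading enforces the
physical bound UVI ∈ [0, 43] (hard error) and warns outside the typical US
annual range [1, 11]. The gazetteer packs approximate public coordinates for
50 US cities; geocoding is exact-match (case- and whitespace-insensitive)
and fails loudly on unknown places — no fuzzy guessing, no network.

### Bands and quartiles

The single-score comparison bands come from the study cohort medians
(205,379 without skin-cancer history; 242,074 with) rounded to the nearest
thousand: 205,000 and 242,000. Bands are half-open — band 1 `< low`,
band 2 `[low, high]`, band 3 `> high` — so every score falls in exactly one
band; a published presentation of the same rule leaves the integers between
205,000–205,001 and 242,000–242,001 unassigned, and the half-open form is
our documented resolution. Quartile labels use the averaged-inverted-cdf
("type 2", SAS-compatible) quantile rule with scores equal to a cut point
assigned downward; fully tied data land in quartile 1.

## Questionnaire model

Eligibility: age ≥ 18 and no residence marked non-US lasting a year or
more. Validation further requires the residential spells to tile [0, age]
exactly (no gaps, no overlaps), every place to geocode, and the
personal-history fields (diagnosis age/type, post-diagnosis behaviors) to
be present exactly when a history is reported. Violations are returned as a
report, never raised, so batch scoring can keep going.

The instrument has 17 items with skip logic reducing the minimal path to
10: ten always-presented items (age; Fitzpatrick type; a personal-history
compound item whose diagnosis age/type fields open only on "yes"; family
history; the six behavior items), one conditional family-history-type item,
and the six behavior items repeated (before/after diagnosis) for
respondents with a personal history. The exposure-epoch and residence
blocks are dynamic tables outside the item tally. This reconstruction
satisfies the instrument's printed 10/17 extremes but is not guaranteed to
match the original item-for-item.

Ordinal coding is 0-based in listed category order; the four protective
frequency items (sunscreen, long sleeves, hat, shade) ascend with
protection. Factor-score signs depend on this convention.

## Statistics

- **Matching.** Each case (at its age of first diagnosis) is matched to two
  controls (at their survey age) without replacement. The propensity score
  is a single-covariate logistic fit of case status on age; matching is
  greedy nearest-neighbor in a case order randomized by the seed. Because a
  one-covariate propensity is monotone in age, propensity distances can tie;
  ties break by raw age distance, then control index. Greedy (rather than
  optimal) matching is a documented choice where the procedure is otherwise
  underdetermined.
- **Conditional logistic regression** maximizes the conditional likelihood
  over matched sets (delegated to statsmodels' ConditionalLogit) and reports
  `OR = exp(coef)` with Wald 95% CIs. Covariates constant within every set
  carry no conditional information and are reported as OR 1 with an
  undefined CI; non-convergence (e.g. complete separation, detected by
  divergent coefficients or standard errors) raises instead of returning
  silently.
- **Bowker's test of symmetry** for k×k before/after tables,
  `Σ_{i<j} (n_ij − n_ji)²/(n_ij + n_ji)` on one df per discordant pair;
  reduces to McNemar for k = 2; a table with no discordant pairs is
  degenerate (p = 1 with a warning).
- **Weighted kappa** defaults to linear (Cicchetti–Allison) disagreement
  weights — the common default in the software tradition this design
  follows — with quadratic available by flag; the CI uses the asymptotic
  variance of Fleiss, Cohen & Everitt, truncated to [−1, 1].
- **ICC** is fixed to the two-way, absolute-agreement, single-measure form
  ICC(A,1), with the McGraw–Wong F-method CI. Zero between-subject variance
  returns 0 with a warning.
- **Cronbach's alpha** in raw and standardized forms.
- **One-factor scoring**: columns (hat, long sleeves, shade, sunscreen,
  Fitzpatrick, sunburns, tanning visits) are standardized; principal-axis
  factoring iterates communalities from squared-multiple-correlation
  starts. The eigenvalue-1 retention rule is applied to the *reduced*
  correlation matrix (SMC diagonal): on the raw matrix, sampling noise
  alone pushes the leading eigenvalue of 7 uncorrelated items past 1 around
  n = 1000, which would retain a spurious factor. Scores use the regression
  method; the sign is fixed so protective items load positively. When no
  eigenvalue exceeds 1 a `retained=False` result (not an exception) is
  returned and downstream models simply omit the factor covariate.
- **Rank tests** are thin delegations to scipy (rank-sum / signed-rank); an
  all-zero paired difference returns statistic 0, p = 1. No multiple-testing
  correction is applied anywhere, mirroring the analysis plan this package
  implements.

## The synthetic cohort generator

The generator emulates the study population so every pipeline stage is
testable offline; defaults are the study conditions where published and a
documented choice otherwise:

- ages: truncated normal, mean 46, SD 15, on [18, 81], floored to integers;
- skin-cancer prevalence 0.13; family history in 33% of subjects;
- Fitzpatrick frequencies (0.072, 0.385, 0.313, 0.130, 0.070, 0.031) — the
  published cohort distribution, with the pooled 23% for types 4–6 split
  plausibly;
- residences: a Poisson(2) number of moves at uniform ages over the
  packaged gazetteer cities (move_rate 0 yields exactly one lifelong
  residence);
- epoch hours: per-band normal draws (SD 1 h, clipped to [0, 6]) around
  means declining from childhood (2.5/3.5 weekday/weekend) to late life
  (1.0/1.5), calibrated so a mid-40s lifetime accumulates ≈ 36–37 thousand
  exposure hours, matching the scale of the cohort the generator emulates;
- behaviors: a latent N(0,1) protection score drives the six ordinal items
  (protective items up, tanning/sunburns down);
- case status: logistic in the cohort CUES quartile (default log-OR 0.3 per
  quartile step, i.e. a Q1-vs-Q4 odds ratio near 0.4), family history
  (log-OR 1.1) and the latent protection score (log-OR −0.5), with the
  intercept solved numerically so expected prevalence hits the target;
- diagnosis: cases draw an age at first diagnosis from a normal
  distribution with mean 51.4 and SD 13.8 — the published cohort's
  diagnosis-age moments — truncated to [18, current age]. A uniform draw
  over [18, age] was considered and rejected: it puts substantial diagnosis
  mass in the early twenties, outside the age support of the control pool,
  which degrades age matching and biases the matched quartile contrast.
  Cases then shift
  behaviors protectively (Poisson(1) ordinal steps), and scale exposure
  hours by 0.6 in epochs *starting at or after* the diagnosis age. Epochs
  straddling the diagnosis keep their hours, so the before-diagnosis score
  used as the analysis predictor is untouched by the post-diagnosis shift;
  risk is assigned from the total-CUES quartile before that shift, and the
  mild mismatch between total and before-diagnosis CUES attenuates, but
  does not reverse, the recoverable effect.

Everything is drawn from one seeded generator; identical parameters give
byte-identical cohorts, and `ground_truth` re-derives the latent values
(linear predictor, case probability, per-year doses — whose sum equals the
engine-computed CUES exactly) while rejecting cohorts it did not generate.

What the generator does **not** model: correlation between residence choice
and exposure hours (independence assumed), seasonal or within-year
structure, item non-response, and recall error in the first
administration. Passing parameter-recovery tests therefore demonstrates the
pipeline's correctness under the stated generative model, not the validity
of self-reported exposure data.

## Problem sizes and numerical conventions

Parameter-recovery checks run 200 replicates of n = 2000 cohorts for the
positive-effect arm and 100 replicates for the null-coverage arm — sizes at
which the direction of the quartile effect is decisively powered while a
full run stays in the minutes range on one core. Conservation checks use
1,000 synthetic cases. Reliability checks use duplicated responses (ICC and
kappa exactly 1) and five retest noise levels (0–4 h/day SD on epoch
hours) under which the CUES ICC degrades monotonically.

Floating-point conventions: per-year dose sums use `math.fsum`; a case's
total is defined as `before + after` (bit-exact conservation); doubling all
epoch hours doubles CUES exactly (power-of-two scaling commutes with
rounding). The principal-axis iteration stops at a 1e-8 communality change
or 200 iterations. Scores are never rounded internally; percent agreement is
rounded to integer percent for display only.

## Known limitations

- The packaged anchor table covers four cities; national-scale scoring
  needs the full user-supplied table, and with few anchors every residence
  maps to a coarse UVI.
- The skip-pattern item mapping is a reconstruction (see above).
- Greedy matching is not optimal matching; with scarce controls the age
  balance can degrade at the tail of the case order.
- The conditional-logistic CI is Wald-based; exact or profile CIs are not
  provided.
- Respondent-reported places must match the gazetteer exactly (by design);
  there is no spelling correction.
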