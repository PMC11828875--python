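# Methods

This note documents the statistical model behind `lifeyears`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Period life tables

Deaths are pooled over each multi-year analysis period; the denominator is
the period-average registry population per single year of age, so exposure
is `pop × years`. Two estimators for the death probability are provided:

- `method="central"` (pipeline default): occurrence–exposure rate
  `m_x = d_x / (pop_x × years)`, converted with
  `q_x = m_x / (1 + (1 − a_x) m_x)`. This is the standard construction when
  the registry count approximates mid-year population, as with real
  point-in-time registry snapshots.
- `method="direct"`: `q_x = d_x / (pop_x × years)`. This is exact when the
  registry count is the start-of-year at-risk cohort — which is precisely the
  convention of the package's own synthetic generator (deaths are drawn
  `Binomial(count, q_x)`), so the large-sample recovery tests use it. On real
  data the two differ by O(q_x/2) at the oldest ages.

`a_x` is the average fraction of the final year lived by those dying at age
x: flat 0.5 by default, with `a_0 = 0.1` in the analysis pipeline to reflect
the early concentration of infant deaths. With flat 0.5 the expectancy
equals the trapezoidal integral of the survival curve, which is what the
closed-form test oracles exploit.

Ages 0–94 are estimated from data ("observed"; age 0 flagged separately as
its own estimate). Ages 95–110 are replaced by a Gompertz extrapolation:
least squares of `log m_x` on age over the fit window 80–94 (ages with
q equal to 0 or 1 are excluded; at least 3 usable ages required), converted
back to probabilities, with `q_110 = 1` closing the open interval and the
terminal person-years `L_110 = a_110 · l_110`. The exact old-age and infant
parameters used by the national statistical office are not published at this
resolution, so this documented extrapolation stands in for them and both the
fit window and `a` schedule are configurable. Cells with zero population and
zero deaths (small districts at single ages) are filled by log-linear
interpolation from the nearest observed ages and flagged.

## Cause-deleted tables and YLL

The share of age-x deaths due to cause i, `f_x = d_x(i)/d_x`, is set to 0
where no deaths occur and carried forward above age 94, where cause-specific
counts are too sparse to ratio reliably. Deletion uses Chiang's proportional
elimination `q^{−i} = 1 − (1 − q)^{1−f}`, which corresponds to thinning the
force of mortality by `(1 − f)` and guarantees YLL ≥ 0; for a generating law
with `q = 1 − e^{−h}` it is *exactly* the schedule of the reduced hazard
`(1 − f) h`, which the competing-risks test exploits. A naive numerator
subtraction (`q·(1−f)`) is available behind `method="subtract"` for
sensitivity only. YLL at ages 40 and 65 are the conditional-expectancy
differences from the same pair of tables.

## Monte Carlo uncertainty

For each stratum and period, the mean and sample SD (n−1) of the annual
populations and annual crude rates at ages 0–94 define independent normal
perturbations. Latin hypercube sampling places exactly one draw per
equal-probability stratum per dimension (uniform within stratum by default;
midpoint optional), mapped through the normal inverse CDF and permuted
independently across dimensions. Draws are truncated to physical support
(populations ≥ 0, rates in [0, 1]); trials whose population draws are all
zero are rejected and logged, and more than 1% rejections aborts the run.
Each trial re-runs the full estimation path — probability conversion, tail
refit, life table, cause deletion — implemented as one vectorised batch
(batched least squares for the tail, cumulative products for survival), so
the default 10,000 trials complete in seconds. Distinct random-number sets
are drawn for the all-cause schedule and for each cause. Population draws do
not feed the rate-based schedule (rates are perturbed directly, so the
denominator cancels); they are retained for the degenerate-trial check and
for fidelity to the stated sampling procedure.

Summaries are the median and the 2.5th–97.5th percentile interval (95% UI),
with the deterministic estimate from the period means carried as the point
estimate. Period differences are computed trial-wise on *independently*
drawn trial sets (no pairing), and flagged significant when the UI excludes
zero. District-group contrasts summarise district point estimates as mean ±
1.96 × SE across districts.

The UI describes the year-to-year variability of the inputs, not the
standard error of the period mean (which would be √years narrower). The
calibration test therefore checks *predictive* coverage: across replicates,
the 95% UI built from five years of data should cover the life expectancy
implied by an independent sixth year about 95% of the time (accepted band
90–99% at 1,000 trials × 200 replicates, scaled down from the production
10,000 trials). The calibration scenario omits the generator's correlated
year effect because the perturbation model treats ages as independent
dimensions; with a shared year effect the independent-dimension UI would be
anti-conservative, a known limitation on real data where annual shocks
(e.g. influenza seasons) hit many ages at once.

## Synthetic generator

Deaths follow a Gompertz–Makeham hazard `h(x) = λ + α e^{βx}` per sex
(defaults λ=2.5e-4, α=1.2e-5, β=0.108 for males; λ=1.2e-4, α=3.5e-6, β=0.115
for females — analytic LE ≈ 78.7 and 85.5 years, the contemporary-Japan
range), with an optional additive infant bump at age 0, district
multipliers, and per-period per-cause multipliers that can target
evacuation districts. Causes are assigned by 10-year age-band mixes (cancer
peaking in midlife, circulatory disease and pneumonia rising in old age) and
ICD-10 codes are sampled uniformly from each group's 3-character ranges. The
default scale is 140,000 residents per district-year (≈2 M across 14
districts, male fraction 0.486) over the three analysis periods, with a
lognormal year effect (SD 0.02) on hazards and small lognormal wobble
(SD 0.01) in the age pyramid, which is the stationary population of the
hazard itself. District-year totals are conserved exactly by
largest-remainder rounding.

What the generator does **not** emulate: migration and evacuation-driven
registration lag (registry counts equal true exposure here), cause-of-death
miscoding, within-year seasonality, cohort effects, and correlated
multi-district shocks. Passing recovery tests therefore demonstrates the
correctness of the estimation chain under the stated model, not robustness
to those real-data features.

The published prefecture-level age-bin death counts ship as a fixture at
their printed 10-year resolution. `to_cube()` disaggregates bins to single
years with a geometric split (ratio 1.08 per year of age, largest-remainder
rounding) purely so count-cube plumbing can be exercised; quantities derived
from the split are approximate by construction and are never compared
against published expectancies.

## Effect sizes

District characteristics are consolidated by population-weighted mean except
the financial capability index, which is a simple mean of municipal values
(following the source convention for municipal financial indicators). The
two-sample contrast is the pooled-variance Student t (df = n₁+n₂−2), not
Welch, because the point-biserial identity `r = t/√(t²+df)` and the
published p-values are defined under the pooled test; `r` is oriented so
positive means the evacuation group is larger, and the reconstruction of
published effect sizes from group means/SDs reports |r| (the published table
prints signed values, the accompanying text magnitudes). Samples are
reconstructed from summary statistics as symmetric ±SD sets, which is exact
because the pooled t depends on the data only through group means and SDs.
No multiple-testing correction is applied, matching the descriptive use of
the |r| > 0.5 large-effect rule.

## Reporting conventions and problem sizes

Tests use scaled-down but structurally complete problems: 14 districts at
5,000–60,000 residents per district-year for pipeline checks, ~10⁶
person-years per sex for the analytic-recovery check, 1,000-trial Monte
Carlo for calibration (10,000 remains the production default), and a
140,000-resident-per-district scenario for the evacuation-contrast check.
The pipeline is deterministic given config and seed, with per-stage
substreams derived from the root seed by hashing, so stages can be re-run in
isolation.

## Known limitations

- The old-age extrapolation assumes log-linear rates through age 110;
  late-life mortality deceleration would bias `e_x` slightly low at the
  oldest ages.
- Independent perturbation dimensions understate uncertainty when annual
  shocks are correlated across ages (see calibration note above).
- Cause fractions above age 94 are frozen at the age-94 value.
- District point estimates in the default pipeline are deterministic;
  Monte Carlo medians per district (as used for the published district
  tables) are available but add 14× the MC cost per cause.
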