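# Methods

## Scope and model

`metalrisk` implements chronic, non-carcinogenic multipathway risk
assessment for the ten USEPA priority-pollutant metals in a residential
population. Exposure media are drinking water, surface soil, indoor and
outdoor air, and locally consumed food items; routes are ingestion,
inhalation and dermal contact, restricted by a configurable whitelist
(water → ingestion + dermal, soil → ingestion + dermal, air → inhalation,
food → ingestion).

The dose model is the standard intake equation ADI = C·IR·EF·ED/(BW·AT)
with the dermal variant ADI_D = C·SA·AF·ABS·10⁻⁶·EF·ED/(BW·AT). We adopt
the chronic-HQ convention EF = 365 day/year and AT = ED·365 days, under
which the EF·ED/AT factor is exactly 1 and all doses are independent of
exposure duration; both are configurable. Soil masses entering ingestion
and adherence terms are converted mg → kg by the explicit 10⁻⁶ factor; all
other unit conversions go through a single table (`units.py`) and unknown
or dimensionally incompatible units raise rather than silently scale.

Hazard quotients divide ingestion/dermal doses by the oral RfD. For
inhalation, when an inhalation reference concentration exists (Cd, Ni, Se,
Hg in the bundled table) the HQ is the time-averaged exposure concentration
over the RfC; otherwise the route-to-route dose over the oral RfD (lead has
inhalation contributions but no RfC). A mode flag forces RfD-only
characterization for sensitivity analysis. Totals are exact sums —
contributions below any threshold are retained — and pathway attribution is
computed on mean HQs (not as the mean of per-iteration shares, though the
sampled per-pathway terms are available for that variant).

### Indoor/outdoor air

Air exposure weights the indoor and outdoor concentrations by time
fractions (h_indoor + h_sleep)/H and h_outdoor/H with H the accounted total
(indoor + sleep + outdoor). Sleep is assigned to the indoor
micro-environment; normalizing over accounted rather than 24 hours
apportions unaccounted time proportionally instead of silently diluting
exposure. The indoor and outdoor addends are kept separate end to end so
indoor/outdoor attribution survives aggregation.

### Censored concentrations

Values below the limit of detection are left-censored. The substitution
policy (applied before any summarization, shared between environmental and
hair data) defaults to LOD/2, with LOD and zero as alternatives; the
censored flag is preserved so detection rates remain computable and the
substitution is idempotent. Geometric means use the substituted values,
which keeps logarithms finite; a hair group with zero detections reports
its means as absent.

## Exposure parameters

Survey-derived parameters (body weight 62.58 ± 10.23 kg; indoor/outdoor/
sleep hours 8.47/5.84/9.24 h with SDs 3.99/3.98/2.14; water ingestion
1.88 ± 0.62 L/day; exposure duration 35.35 ± 18.68 yr; eight food intakes
in g/day) default to lognormal distributions moment-matched on the observed
scale: σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2, so the fitted mean
equals the input mean exactly. A zero-truncated normal is available as the
alternative family; its parent parameters are solved iteratively so the
post-truncation moments match to better than 10⁻⁶. sd = 0 degenerates to a
fixed value.

Literature parameters ship as fixed defaults in an editable YAML:
inhalation rate 14.5 m³/day; skin area 5700 cm² and adherence factor
0.07 mg/cm²-day for soil contact; dermal absorption fraction 0.001
(0.01 for cadmium); a nominal whole-body water-contact term (18000 cm²,
0.01 mg/cm²-day). The **soil ingestion rate defaults to 22.8 mg/day**: it
was back-calculated from the study conditions the bundled profiles encode —
a soil lead level of 2507 mg/kg carrying 40.3 % of a total lead HQ of 16.2
for a 62.58 kg adult — and lies inside the EPA Exposure Factors Handbook
adult central range (20–50 mg/day). The frequently quoted 100 mg/day upper
bound is incompatible with those conditions (it alone would imply a soil
lead HQ of ~28.6, exceeding the total), which is why the lower,
self-consistent value is the default. Water dermal contact reuses the
soil-dermal equation structure with water-specific area/loading defaults
rather than a permeability-coefficient model.

## Monte Carlo engine

Each iteration draws one value per stochastic exposure factor (default: all
survey-derived factors; the literature constants stay fixed) and, in the
default `lognormal_from_summary` mode, one value per concentration cell
from a lognormal moment-matched to the cell's summary. `fixed_mean` holds
concentrations at their means for sensitivity runs; `empirical` bootstraps
raw sample values. Sampling is vectorized over a single name-sorted
parameter order, so determinism depends only on the seed and the model
content, not construction order; identical seed and config give
byte-identical outputs. Percentiles use linear interpolation between order
statistics.

Because every pathway HQ has the product form k·C·IR/BW (or k·C for
RfC-based inhalation) with independent factors, the analytic mean
E[HQ] = Σ k·E[C]·E[IR]·E[1/BW] is available in closed form; for lognormal
body weight E[1/BW] = (1 + cv²)/mean, about 2.7 % above 1/mean at the
default cv. The Monte Carlo mean therefore sits a few percent above the
plug-in point estimate (Jensen's inequality in 1/BW) — both are reported,
and the test suite asserts the ordering and the closed-form agreement. The
closed-form helper refuses stochastic activity hours, whose time fractions
are ratios of random variables without a product-form mean; verification
tests that compare against the closed form hold hours at their means, while
default pipeline runs sample them.

## Synthetic data and calibration

The generator emulates a three-village gradient study around a lead-zinc
mine: small-n environmental samples per medium (10 water, 5 soil, 10 + 10
air, 8 per food item), 42/42/36 survey participants and 29/30/13 hair
donors. Concentrations are lognormal with cv 0.3 (a documented synthetic
choice; the study prints SDs for only a few media), censored below
per-cell LODs. By default the LOD sits at mean/10 (effectively full
detection); cells with a stated detection-rate target place the LOD at the
matching lognormal quantile, and one food cell emulates a non-detect by a
mean below its LOD.

Survey hours cannot be drawn as independent lognormals at the surveyed
moments — their means sum to 23.55 h with ~4 h SDs, so roughly half of all
independent draws would violate the 24-hour day, and rejection or rescaling
would bias the means by 5–20 %. Hours are instead drawn as 24 h × Dirichlet
over (indoor, outdoor, sleep, slack), with component means matched exactly
and the single concentration parameter least-squares fitted to the
activity-hour SDs; the cost is that the realized sleep-hour SD (~3.6 h)
exceeds the surveyed 2.14 h. Every record satisfies the 24-hour constraint
by construction.

### Profile calibration

The bundled V1/V2/V3 profiles are calibrated against the published
summary tables rather than the (non-machine-readable) per-sample
supplementary data. Because each pathway HQ is linear in its medium
concentration, a concentration is back-calculated as
C = share × HQ_target/k, where HQ_target is the published per-metal village
mean, k the HQ per unit concentration under the default exposure parameters
(computed by running the package's own point-estimate chain on unit
concentrations, so calibration and evaluation can never drift apart), and
the shares come from documented templates. Printed concentrations are kept
as fixed anchors wherever they are consistent with the targets: V1 soil Pb
2507 and Zn 9281 mg/kg, V1 indoor air Pb/Zn/Cu and outdoor Pb/Zn, pakchoi
Pb and Zn in all villages where printed, soil Zn 92.8 mg/kg in V3, and rice
Hg 0.03 mg/kg everywhere. The remaining media absorb the residual HQ in
template proportion, so the profile-implied point estimate reproduces the
published per-metal HQ table exactly (totals 23.46/8.34/7.58 vs printed
23.4/8.3/7.5).

Share templates encode the published pathway findings where stated: lead in
V1 carries 40.3 % via soil ingestion with indoor air contributing about
twice outdoor; mercury's food share is 41.6 % once rice is pinned, with the
indoor:outdoor inhalation split following the printed 734:543 concentration
ratio; cadmium's soil medium carries ~50 % and air 44.3 %. Two published
details cannot be honored under the shipped parameters and are deliberately
not encoded: (1) the cadmium *dermal* share of 47.1 % — the dermal/ingestion
HQ ratio is bounded by SA·AF·ABS/IR_soil ≈ 0.175 for cadmium, so dermal can
never dominate ingestion under this dose model; the soil share is assigned
to the medium and the route split follows the equations; (2) the printed
mercury air levels (734/543 ng/m³) — under RfC-based characterization they
alone would contribute ~81 % of a 2.84 total HQ while food is stated at
41.6 %, an over-full budget; the mercury air cells are therefore
back-calculated (≈490 ng/m³ indoor) keeping the printed indoor:outdoor
ratio, and the printed levels remain as test anchors for time-weighted
averaging. Back-calculated cell values are synthetic stand-ins, not
reproductions; several (e.g. soil cadmium) are physically implausible as
concentrations and simply encode the published HQ under the default
parameters — the gap traces to exposure factors the study does not print.

Hair cells use the published per-village means, SDs and LODs; the
all-censored silver row has no printed mean and uses a synthetic LOD/2
mean. The published pooled zinc geometric mean (240 mg/kg) is not imposed:
with the printed arithmetic moments the implied lognormal GM is ~141 mg/kg,
an ambiguity in which mean the published table holds; both means are always
emitted.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* the analysis assumes —
lognormal media, censoring at stated LODs, surveyed factor moments, village
gradients — and the calibration guarantees internal consistency between
profiles and published HQ summaries. Passing tests therefore certify the
computational chain (equations, aggregation, attribution, sampling,
censoring handling), not the field accuracy of the underlying survey or
chemistry, and not the true values of the unprinted exposure factors: with
different IR_soil/SA/AF/ABS choices the same published HQs imply different
concentrations. Real data may also carry correlations (between intakes,
between media) that the independent-sampling default ignores; no
correlation structure was reported.

## Numerical choices and problem sizes

Point estimates are evaluated at parameter means in float64; Monte Carlo
defaults to 10,000 iterations (the published analysis's size, and the size
used by `scripts/acceptance.py`), which resolves the total-HQ mean to
~0.5 % relative standard error for the V1 profile. Verification comparisons
use 3–4 standard-error bounds; the brute-force-oracle equivalence is pinned
at 10⁻¹² relative tolerance. Percentiles interpolate linearly; sample SDs
use ddof = 1; degenerate single-draw runs report SD 0. Empty groups, zero
total HQs (distinguishing "no risk" from "no data"), missing factors and
inconsistent profiles (LOD above mean with full detection demanded) all
raise named errors rather than propagating NaNs.

## Known limitations

- Adult population only; no age stratification, no carcinogenic (slope
  factor) risk, no target-organ hazard grouping.
- No bioaccessibility or speciation adjustment; dermal water contact uses
  an adherence-style model, not permeability coefficients.
- Between-village significance testing and toxicokinetic hair-to-dose
  back-calculation are out of scope; the hair/risk concordance table is
  descriptive (the 10 mg/kg hair-lead guideline is reported as an
  annotation only).
- Monte Carlo sampling treats all inputs as independent.
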