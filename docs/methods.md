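# Methods

This note documents the models, numerical choices and limitations behind
`greenflow`, in the order the pipeline runs them.

## Screening design

A definitive screening design (DSD) for m factors is built from an
order-m conference matrix C — zero diagonal, ±1 off-diagonal,
CᵀC = (m−1)I — as the fold-over run pairs {cₖ, −cₖ} plus a centre run.
The fold-over structure makes every main-effect column orthogonal to every
other main effect and to all quadratic columns, so linear effects are
estimated free of quadratic bias in very few runs.

The four process factors are augmented with two *fake* factors: the
6-column design is generated, the fake columns are dropped, and two extra
centre replicates are appended, giving 2·6 + 1 + 2 = 15 runs with three
centre points (pure-error degrees of freedom). Conference matrices are
produced by a Paley-style construction (orders q+1 for prime q ≡ 1 mod 4;
order 6 is the one the pipeline uses) followed by a seeded simultaneous
row/column permutation and independent sign flips. These operations
preserve the zero diagonal and the defining identity, which is re-validated
on every call; the contract is the design's properties, not any particular
matrix, so any valid matrix is acceptable and the seed only fixes which
one you get.

Coded levels map linearly to physical units (−1 → low, 0 → midpoint,
+1 → high; the three design levels are mapped exactly, avoiding float
round-off at range ends). Runs execute in ascending temperature with a
stable sort, so the oil bath only heats, never waits to cool.

Default factor ranges: temperature 70–90 °C, time 5–15 min, lanolin
solution mass fraction 0.15–0.35, alkali dosage 0.116–0.123 kg/kg lanolin
(the experimental dosing band; the sensitivity analysis samples the
slightly wider 0.115–0.125 band, see below).

## Flow conversion

Merging three streams — lanolin feedstock solution (mass fraction w₀,
density ρ₁), alkali solution (w_j, ρ₂) and diluent (ρ₃) — under three
constraints (coil volume Vr swept in exactly the reaction time t₀; merged
lanolin fraction equal to the target wᵢ; delivered alkali-to-lanolin ratio
equal to λₐ) gives closed-form pump rates:

    Q₁ = (Vr/t₀) / D,  D = 1 + ρ₁w₀λₐ/(w_jρ₂) + (ρ₁w₀/wᵢ − ρ₁)/ρ₃
    Q₂ = ρ₁w₀Q₁λₐ/(w_jρ₂)
    Q₃ = (ρ₁w₀Q₁/wᵢ − ρ₁Q₁)/ρ₃

and the residence time t₁ = t₀ + V₁/Q₁ + t₃ (transfer volume V₁ = 10 mL,
equilibration t₃ = 2 min). Volume additivity on merging is assumed — a
modelling idealisation adequate for dilute aqueous streams. The identities
(merged fraction = wᵢ, ratio = λₐ, ΣQ = Vr/t₀) hold algebraically and are
asserted to 1e−9 over random inputs in the tests.

Default material properties (ρ₁ = ρ₂ = ρ₃ = 1 g/mL, w₀ = 0.5, w_j = 0.15)
describe the virtual rig only; they are round, plausible values for the
aqueous system and are explicit configuration, not measurements. Real
campaigns must supply measured values. Default reactor volume is the 1 mm
× 50 m coil, Vr = 39.27 mL.

## Carbon accounting

Emissions are attributed to natural-gas heating of the process streams
from the 25 °C reference to the reaction temperature. Per kg of processed
lanolin the heated mass is taken as the *full* diluted lanolin solution
plus the alkali solution, 1/wᵢ + λₐ/w_j kg — i.e. the dilution water is
heated too. This is the only reading consistent with the strong negative
mass-fraction dependence the sensitivity analysis exhibits (r ≈ −0.87): a
lanolin-plus-alkali-only heated mass would be nearly independent of wᵢ.

The fuel emission factor is C·η·(M_CO₂/M_C)/LHv with the standard
chemical-industry accounting constants (carbon content 15.3 t C per
10⁴ Nm³, oxidation rate 0.99, lower heating value 389.9 GJ per 10⁴ Nm³),
giving 0.14244 kg CO₂ per MJ of heat. The per-stream specific heats are
collapsed into a single effective c_spec = 2353 J/(kg·°C), back-solved so
that the optimised validation conditions (70 °C, 5 min, wᵢ = 0.25,
λₐ = 0.116) emit the reference 0.072 kg CO₂/kg. This is a declared
calibration anchor: the *structure* (linearity in T − 25, 1/wᵢ scaling,
independence from t₀) is the model's content, and the Pearson correlations
of the sensitivity analysis are exactly invariant to c_spec, so the
calibration does not touch them.

The greenness scorecard is arithmetic only: twelve per-principle scores in
[0, 10], total ≤ 120. The scores themselves are expert judgement supplied
by the user; no rubric is encoded.

## Response-surface model

The lanosterol yield is modelled as a full second-order polynomial in
coded levels, fitted by OLS; coefficient covariance is σ̂²(XᵀX)⁻¹ with
σ̂² = SSE/(n − p). Per-term inference uses drop-one (partial, type III) F
tests; the whole-model F compares against the intercept-only model. Fit
quality is reported as R², adjusted R², SD = √MSE and CV = 100·SD/ȳ.

Backward stepwise elimination at α = 0.10 repeatedly removes the eligible
term with the largest partial-F p-value above α. Hierarchy is enforced: a
linear term cannot leave while a retained quadratic or interaction
contains its factor, and the intercept never leaves. Ties break toward the
later-declared term (declaration order: intercept, linear, quadratic,
interactions in lexicographic index order), making the procedure fully
deterministic.

**Starting-set reduction.** The full 15-term quadratic is unidentifiable
on the 15-run DSD (13 distinct points; the second-order columns carry
exact linear dependencies, leaving rank 11), and which member of an alias
group survives should not be an accident of declaration order. The staged
strategy recommended in the screening-design literature is used: first
backward-eliminate among the orthogonal, high-powered main effects; then
admit only the quadratics and interactions whose parent factors survived
(strong heredity); if the set is still rank deficient, alias groups are
broken by a data-aware rule (drop the member with the weakest partial
association with the response after projecting out the unambiguous
columns). The ordinary backward pass then runs on that estimable start.
The cost of strong heredity is that an interaction both of whose parents
are truly inactive cannot be discovered; for this process that pattern has
no support.

**Power limits at campaign scale.** With the study's noise level
(SD 0.045) and 15 runs, the temperature×mass-fraction interaction
(|coefficient| 0.04, column sum of squares 8) has a noncentral-t power of
only ≈ 0.76 at α = 0.10 even for the ideal single test in the final model
(df = 10); path effects in stepwise selection reduce observed retention to
≈ 0.68 over simulated campaigns. Retention of the linear effects is
0.89–1.00 and the inert alkali term is falsely retained ≈ 13 % of the
time. A retention guarantee of 80 % for an effect of that size is simply
not available from a 15-run campaign — a useful reminder that screening
designs size effects, and confirming a borderline interaction needs
augmentation runs.

## Design-space risk

Coefficient uncertainty is propagated by Monte Carlo: 500 vectors are
drawn from N(β̂, Σ̂β) (SVD-based multivariate-normal sampling tolerates
the PSD-but-singular covariances that arise from near-saturated fits). At
each candidate point the risk is the fraction of draws whose *mean*
predicted yield leaves [0.55, 0.70]; an optional predictive mode also
draws residual noise per simulation for users who want the risk of a
single future run rather than of the process mean. One shared draw set is
used across the whole grid (common random numbers make the map smooth in
the conditions); per-point fresh draws are available behind a flag.

The default exhaustive grid steps 1 °C × 1 min × 0.01 (wᵢ) × 0.001 (λₐ)
over the design ranges — 38,808 points, evaluated as one matrix product in
well under a second. Feasibility is risk ≤ 0.2. The stored significance
level (0.05) is used only for optional confidence-interval reporting on
risk estimates; it plays no role in the feasibility rule.

**Green selection.** Among feasible points, lexicographically: minimum
alkali dosage (waste), then minimum reaction time (throughput), then
minimum temperature (emissions), then the mass-fraction level with the
greatest distance to the nearest infeasible mass fraction at that
(λₐ, t₀, T) — a robustness margin — with remaining ties going to the
larger mass fraction (less water to heat). One grid step beyond the
explored range counts as infeasible in the margin: the model is
uncertified out there, so a feasible band that touches the range edge
still yields an interior, robust optimum rather than the edge itself.
Without that convention a one-sided feasible band would select the extreme
of the sampled range, which is exactly the non-robust choice the margin
rule exists to avoid (and it measurably degrades the end-to-end yield
recovery). An empty feasible set raises an explicit "no design space"
error — the honest QbD answer when the fitted model is too uncertain,
whose remedy is more data, not a forced pick.

## Emission sensitivity

Simple random sampling: 10,000 independent uniform draws per parameter
over temperature 70–90 °C, time 5–15 min, mass fraction 0.15–0.35, alkali
0.115–0.125 kg/kg; material properties held at module defaults. Each
draw's emission is computed, and each parameter is summarised by its
sample Pearson correlation with emission, the two-sided p-value from
t = r√((n−2)/(1−r²)), and a grade: |r| ≥ 0.5 extremely sensitive,
0.2 ≤ |r| < 0.5 weakly sensitive, |r| < 0.2 insensitive (boundaries go to
the higher grade; the strict inequalities of the convention leave them
undefined). Under the emission model the expected outcome is structural:
time never enters the model (r ≈ 0), alkali enters only through the small
alkali-solution mass (r ≈ 0.01), temperature drives the linear (T − 25)
term (r ≈ 0.45) and mass fraction dominates through 1/wᵢ (r ≈ −0.87).

## Virtual rig

The rig substitutes a ground-truth response surface for the wet lab:
yield = 0.765 + 0.05·x_T + 0.045·x_t + 0.10·x_w − 0.04·x_T·x_w (coded
units) plus N(0, 0.045²) measurement noise, clipped to [0, 1]. The
coefficients are a synthetic calibration chosen so that the design-point
yields span ≈ 0.53–0.92, the (70 °C, 5 min, wᵢ = 0.25) anchor evaluates to
0.67, the effect-size ordering is mass fraction > temperature > time >
interaction, and alkali dosage has no effect; they are not fitted to any
real campaign. The cholesterol channel is modelled as essentially complete
saponification — 1 minus a small one-sided |N(0, 0.01)| deviation — with
no response surface of its own. Per-run seeds derive from the campaign
seed via seed-sequence spawning, and record timestamps come from a
simulated clock (fixed epoch + one slot per run) so a replayed campaign is
byte-identical.

What passing tests on the rig do *not* show: the rig has no drift, no
run-order carry-over, no heteroscedasticity, no kinetics (time enters the
truth as a smooth main effect, not through a rate law) and no failed
runs — so the pipeline's statistical behaviour on rig data bounds, but
does not guarantee, its behaviour on real campaigns.

## Pipeline

The orchestrator is a pure function of (configuration, seed): stage seeds
derive from the master seed by seed-sequence spawning, every artifact is a
plain CSV/JSON file, and the report is byte-identical across replays. A
timestamped log records each stage with the SHA-256 of what it wrote. Any
stage failure aborts with the stage name attached; "no design space" from
selection is surfaced, not swallowed. External records replace the rig via
a schema-validated CSV reader that rejects out-of-range yields row by row.

## Problem sizes used in the checks

The bundled checks run the pipeline at its native scale: 15-run designs,
500-draw risk maps on the 38,808-point default grid, 10,000-draw
sensitivity samples, 200-campaign stepwise-retention sweeps and
50-replicate end-to-end recovery sweeps. Nothing is scaled down relative
to the study conditions.

## Known limitations

- Volume additivity and constant densities in the flow model; no pressure
  drop, rheology or heat-transfer dynamics.
- A single effective specific heat calibrated to one anchor; absolute
  emission values inherit that calibration, correlations do not.
- Strong heredity in model reduction (see above).
- Risk is computed on the fitted model taken at face value; model-form
  error is not in the Monte Carlo.
- The greenness rubric is not encoded; only score validation/summation.
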