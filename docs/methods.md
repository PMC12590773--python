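# Methods

## Model

`otosat` treats vestibular endolymph as a well-mixed carbonate solution
at fixed temperature and pressure. Otoconial calcite is stable when the
ion-activity product of Ca²⁺ and CO₃²⁻ exceeds the effective solubility
product, quantified by the saturation index

Ω = γ_Ca [Ca²⁺] · γ_CO₃ [CO₃²⁻] / K_sp.

Carbonate comes from pH-dependent speciation of total inorganic carbon,
[CO₃²⁻] = α₂(pH)·C_T with

α₀ = h²/D, α₁ = K₁h/D, α₂ = K₁K₂/D, D = h² + K₁h + K₁K₂, h = 10^(−pH),

so Ω inherits an exponential pH sensitivity through α₂. Solving Ω = 1
for calcium defines the stability–dissolution boundary
C_crit(pH) = K_sp/(γ_Ca γ_CO₃ α₂(pH) C_T); the calcium deficit
ΔC = C_crit − [Ca²⁺] is mapped to a relative-risk score
R = 1/(1 + exp(−ΔC/σ_C)). R is probability-like and dimensionless: it
ranks states and tracks directions, it is not an absolute event
probability.

### Assumptions

- Equilibrium thermodynamics only — no nucleation or dissolution
  kinetics, no CO₂-hydration kinetics, no polymorph branch (calcite is
  the operative phase), no protein-matrix or chelation effects.
- In the default *minimal* activity mode, activities are approximated by
  concentrations (γ ≡ 1) and K_sp absorbs ionic-strength effects as an
  effective constant.
- C_T is held fixed at its calibrated value during scoring; it varies
  only where explicitly swept or inferred from blood-gas inputs.
- One compartment: utricular endolymph, with parameter windows anchored
  to vertebrate vestibular measurements (not cochlear or endolymphatic
  sac values, which are far lower in calcium).

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| pK₁, pK₂ | 6.12, 10.3 | — | carbonic-acid dissociation exponents at 37 °C |
| K_sp | 4.47×10⁻⁹ | mol²/L² | effective calcite solubility product |
| S_CO2 | 0.0306 | mmol/(L·mmHg) | plasma CO₂ solubility (blood-gas route only) |
| T | 37 | °C | working temperature (accepted 30–45) |
| I | 0.20 | mol/L | ionic strength (Davies mode only) |
| A | 0.52 | — | Davies slope at 37 °C |
| σ_C | 80 | µmol/L | logistic dispersion: inter-individual tolerance to calcium deficit |
| anchor | C_crit(7.65) = 265 | µM | calibration of C_T (≈ 7.774 mM) |

Units follow a strict convention: all internal concentrations are mol/L;
interfaces take calcium in µmol/L, C_T and HCO₃⁻ in mmol/L, pCO₂ in
mmHg, serum ionized calcium in mmol/L, and ΔC is stored in µmol/L so it
shares units with σ_C.

### Calibration convention

C_T is calibrated once, under the minimal (γ ≡ 1) convention, so that
C_crit at the anchor pH equals the anchor calcium. The Davies activity
mode is applied to scoring (Ω, C_crit) but never to the calibration
itself: if the calibration were re-run inside Davies mode the γ product
would cancel out of C_crit and ionic strength could never move the
boundary, contradicting its physical role. Consequently Davies-mode
boundaries sit strictly above the minimal one and rise with I.

### Temperature anchoring

The temperature dependence of K₁, K₂, calcite K_sp and the CO₂ Henry
constant uses the Plummer–Busenberg (1982) freshwater relations, applied
as *log-offsets relative to the base parameters' own temperature*. At
37 °C the defaults are reproduced bit-identically, and re-anchoring
(37 → 39 → 37 °C) round-trips exactly. Only the local slope of the
literature relations matters, which is well constrained; over the
clinical 35–39 °C range the boundary moves by at most ≈ 6.5%, the
smallest displacement of the four sensitivity sweeps.

## Activity coefficients

Davies mode computes γ for both divalent ions from
log₁₀ γ = −A z² (√I/(1+√I) − 0.3 I), giving γ ≈ 0.326 at I = 0.15 for
z = 2. The same γ enters Ω and C_crit so the boundary identity
Ω(Ca = C_crit) = 1 holds in either mode. The Davies form is empirical
and degrades above I ≈ 0.5 mol/L; a Pitzer ion-interaction treatment is
out of scope.

## Clinical proxy

The blood-derived Ω proxy feeds a blood-gas panel (pH, HCO₃⁻ or pCO₂,
serum ionized calcium) through the *same* pipeline: C_T from
C_T = [HCO₃⁻]/α₁ (preferred) or [CO₂(aq)]/α₀ with [CO₂(aq)] = S_CO2·pCO₂,
then standard state evaluation. There is deliberately no second
chemistry path. Because serum ionized calcium (~1.2 mmol/L) is three
orders of magnitude above endolymph free calcium, the proxy Ω for any
realistic panel is far above 1 and its R far below 0.5; the output is
meaningful only as an *ordering* — acidemia and hypocalcemia always move
the proxy toward higher relative risk — and every result carries a
mandatory caveat to that effect. The risk bands (R < 0.4 low, 0.4–0.68
intermediate, > 0.68 high) are non-clinical conveniences; 0.68 is the
model's own emphasized tail threshold, 0.4 a roughly symmetric lower
cut. The two C_T routes disagree by ~3% on a consistent panel (pK₁ =
6.12 differs from the physiological Henderson–Hasselbalch constant);
a >5% disagreement raises a data-quality caveat.

## Synthetic cohorts

The simulator emulates a population of endolymph states: pH uniform on
7.5–7.8 and free calcium on 200–350 µM, windows anchored to vertebrate
vestibular reports (≈ 250–280 µM, pH 7.6–7.7) and widened to cover
pathological deviations. Two samplers:

- `uniform`: both variables uniform — mean R ≈ 0.49, mildly
  right-skewed (the convex pH-dependence of C_crit does the skewing).
- `skewed` (default): calcium from a bounded Beta(3, 4) rescaled to the
  window — a mild low-calcium weighting (mean 264 vs 275 µM) chosen from
  large-sample population statistics so that the risk distribution stays
  right-skewed (population skewness ≈ +0.10) while the R > 0.68 tail is
  inflated relative to the uniform draw (≈ 0.22 vs 0.19).

Seeds are mandatory (`numpy.random.default_rng(seed)`); identical specs
give bit-identical rows and byte-identical CSV. Summaries are exact
sample statistics with a 30-bin histogram on [0, 1] (equal widths, last
bin right-closed). A degenerate constant sample reports skewness 0.

What the generator does *not* emulate: within-subject correlation of pH
and calcium, measurement error, temporal dynamics, or any empirical
BPPV case mix. Passing cohort tests therefore demonstrates internal
consistency of the scoring pipeline under the stated windows, not
agreement with a clinical population.

The risk grid evaluates the model on a pH–calcium lattice (default
301×301) and reports the Ω = 1 boundary *analytically* as
Ca = C_crit(pH) sampled on the pH axis — no numeric contouring — so
enlarging the plotted window cannot move boundary values at shared pH
points.

## Sensitivity sweeps

One-at-a-time sweeps perturb the calibrated baseline without
re-calibrating (they measure departure from one fixed model, not a
family of re-tuned models). Displacement is summarized as the mean and
maximum of |C_crit′ − C_crit|/C_crit over a 101-point pH grid on
7.4–7.9, in percent — a metric defined here, since "boundary shift" has
no standard quantitative form. Closed forms anchor the suite: C_crit ∝
K_sp and ∝ 1/C_T exactly (so K_sp ×{0.9, 1.1, 1.2} gives {10, 10, 20}%
and C_T ×{0.9, 1.1} gives {+11.11, −9.09}%, pH-independently), and σ_C
never enters the boundary (identically zero displacement). Under default
settings the displacement ordering is ionic strength ≳ K_sp > C_T >
temperature, and every sweep preserves the strictly decreasing boundary
topology.

## Numerical choices

- Speciation uses the closed-form α expressions; they agree with a
  50-digit brute-force equilibrium evaluation to better than 10⁻¹⁰
  relative across pH 0.5–13.5.
- The logistic uses `scipy.special.expit` (no overflow at extreme ΔC).
- Ω exactly 1 is classified as its own "boundary" label rather than
  folded into either class.
- CSV output is deterministic: fixed column order, 10 significant
  digits, RFC-4180 quoting.
- Config precedence is defaults ← file ← CLI flags; unknown keys are
  rejected with a nearest-match suggestion; commands that need
  randomness fail without a seed rather than silently defaulting.

## Known limitations

- The cohort-level tail statistics depend on the sampler's shape
  parameters, which are a modeling choice; only the qualitative
  right-skew and tail-ordering properties are contractual.
- The proxy cannot be validated against endolymph ground truth; its
  contracts are direction-only by design.
- Effective K_sp conflates ionic-strength and matrix effects at the
  default I; Davies mode and K_sp sweeps bound, but do not resolve,
  that degeneracy.
- Temperature relations are freshwater-calcite forms used for their
  local slopes only; absolute values away from the 37 °C anchor carry
  that caveat.
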