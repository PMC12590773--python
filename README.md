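# otosat

A minimal ion–chemistry model of otoconia stability, for researchers and
clinicians studying benign paroxysmal positional vertigo (BPPV).

Otoconia — the calcite (CaCO₃) biominerals of the utricular macula whose
detachment causes BPPV — sit in an endolymph whose pH and free ionized
calcium decide whether the mineral precipitates or dissolves. `otosat`
computes that balance as the calcite saturation index

    Ω = γ_Ca [Ca²⁺] · γ_CO₃ [CO₃²⁻] / K_sp,      [CO₃²⁻] = α₂(pH) · C_T,

where α₂ is the carbonate fraction of total inorganic carbon C_T from the
two carbonic-acid dissociation constants (pK₁ = 6.12, pK₂ = 10.3 at
37 °C), and K_sp = 4.47×10⁻⁹ is the effective calcite solubility product.
Ω > 1 means supersaturation (stable otoconia), Ω < 1 undersaturation
(dissolution-prone). Setting Ω = 1 gives the critical calcium boundary

    C_crit(pH) = K_sp / (γ_Ca γ_CO₃ · α₂(pH) · C_T),

and the calcium deficit ΔC = C_crit(pH) − [Ca²⁺] maps to a dimensionless,
probability-like relative-risk score through a logistic transform,

    R = 1 / (1 + exp(−ΔC / σ_C)),      σ_C = 80 µM by default,

so R = 0.5 exactly on the Ω = 1 boundary. C_T is calibrated once so that
C_crit(7.65) = 265 µM, the physiological anchor for vestibular endolymph.

The package provides:

- **Carbonate speciation** (α₀/α₁/α₂), C_T inference from blood-gas
  surrogates (HCO₃⁻ or pCO₂), Davies activity coefficients, and
  temperature-anchored constants (`otosat.chemistry`);
- **Stability scoring** — Ω, C_crit, ΔC, R, the relative critical-calcium
  index, and nine directional physiological scenario presets
  (hyperventilation, acetazolamide, loop diuretics, …)
  (`otosat.stability`);
- **A blood-derived Ω proxy** from serum ionized calcium plus blood-gas
  pH/HCO₃⁻/pCO₂ — relative-risk inference only, never an estimate of
  absolute endolymph chemistry (`otosat.proxy`);
- **Seeded synthetic cohorts** over the endolymph windows (pH 7.5–7.8,
  Ca²⁺ 200–350 µM) with risk-distribution summaries, and the analytic
  Ω = 1 boundary on the pH–calcium plane (`otosat.cohort`);
- **One-at-a-time sensitivity sweeps** of the boundary under C_T, K_sp,
  ionic-strength, temperature and σ_C perturbations
  (`otosat.sensitivity`);
- a CLI (`otosat`) wrapping all of the above with deterministic CSV
  output.

## Worked example

Score a mildly acidotic endolymph state (pH 7.50, Ca²⁺ 265 µM, C_T at
its calibrated default):

```sh
$ otosat risk --ph 7.50 --ca-umol 265
ph,ca_umol,ct_mmol,omega,c_crit_umol,delta_c_umol,r,class
7.5,265,7.773855597,0.7001278256,378.502311,113.502311,0.8051469132,dissolution-prone
```

Reading the row: at pH 7.50 the calibrated C_T is 7.774 mM and the
critical calcium rises to 378.5 µM, so a calcium level of 265 µM —
exactly the Ω = 1 boundary value at pH 7.65 — now sits 113.5 µM *below*
threshold. The saturation index drops to Ω = 0.70 (undersaturated) and
the logistic mapping turns the deficit into a relative risk R = 0.805:
a 0.15 pH acidification alone moved this state from the knife-edge
(R = 0.5) deep into the dissolution-prone regime.

A directional scenario, before and after:

```sh
$ otosat scenario --name acetazolamide --ph 7.65 --ca-umol 265
phase,scenario,ph,ca_umol,omega,r,class,d_omega_sign
before,acetazolamide,7.65,265,1,0.5,boundary,-1
after,acetazolamide,7.55,265,0.7888379203,0.7082117918,dissolution-prone,-1
```

Acetazolamide (carbonic-anhydrase inhibition → metabolic acidosis)
lowers Ω (`d_omega_sign = -1`), as do metabolic acidosis,
hypoventilation, loop diuretics and hypocalcemia; hyperventilation,
vomiting, thiazides and hypercalcemic states raise it.

A seeded 10,000-subject synthetic cohort:

```sh
$ otosat --seed 42 cohort --n 10000 --out cohort.csv --summary summary.csv
$ cat summary.csv
n,mean_r,skewness_r,frac_r_gt_0.5,frac_r_gt_0.68,frac_r_gt_0.8
10000,0.5183327123,0.08169937736,0.5184,0.2207,0.0512
```

The default mildly low-calcium-weighted sampler yields a right-skewed
risk distribution (skewness +0.08) with 22% of subjects above R = 0.68 —
a population hugging the saturation boundary. Reruns with the same seed
are byte-identical.

## Scope

The model is deliberately minimal and hypothesis-generating: no
nucleation/dissolution kinetics, no Pitzer ion-interaction model, no
protein-matrix effects, and no claim of estimating absolute endolymph
chemistry from blood values. See `docs/methods.md` for assumptions,
parameter choices and limitations.
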