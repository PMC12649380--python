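# flumefish

Analysis pipeline for open-channel flume experiments on fish swimming
performance and path-selection behaviour in high-velocity flow. It is aimed
at movement ecologists and fish-passage engineers who track individual fish
at video frame rates through a hydraulically mapped test channel and want to
quantify (a) how fast and how long the fish can swim, and (b) which
hydraulic conditions they choose to move through.

The pipeline has four stages, each usable on its own:

1. **Hydraulics** — velocimeter (ADV) time series on a rectangular grid are
   reduced to time-averaged velocities, turbulent kinetic energy
   `TKE = ½(var u + var v + var w)` and Reynolds shear stresses
   `τ_ab = −ρ·cov(a, b)`, assembled into a continuously interpolable field.
2. **Kinematics** — frame-wise positions become per-step ground, flow and
   swim velocity vectors (`V_s = V_g − V_f`), movement modes (upstream /
   cross-stream / downstream, from the angle between `V_g` and `V_f`) and
   binned speed profiles.
3. **Endurance** — fatigue times (duration above the 3.83 BL/s sustained
   threshold, right-censored at test-area traversal) are modelled with a
   breakpoint Weibull accelerated-failure-time regression

       ln T = β₀ + β₁·C_ps + (β₂ + β₃·C_ps)·x₁ + … + ε,

   where `C_ps` switches between the prolonged and sprint regimes at a
   breakpoint swim speed found by a moving-point AIC search; Harrell's
   C-index, Akaike-weight model ranking, and the dynamic endurance state
   `E(t) = 1 − ∫ dt/T(V_s)` come with it.
4. **Behaviour** — each realised step is paired with three rotated
   alternatives (a use-availability design) carrying signed hydraulic
   contrasts (Δu, Δv, ΔTKE, Δτ…), screened for collinearity and fitted with
   a binomial GAMM: per-mode penalized-spline smooths, (covariate × E)
   tensor interactions, and random intercepts for mode and fish, with
   REML-selected smoothing, fish-grouped cross-validation and
   partial-dependence effect summaries.

A synthetic-data module generates flume fields, velocimeter series, fatigue
times and preference-driven trajectories with the exact statistical
structure the estimators assume, so the whole chain is testable without
field data. See `docs/methods.md` for the models and design choices.

## Worked example

Simulate fatigue records from a two-regime endurance truth and recover the
model, including the regime breakpoint:

```python
import numpy as np, pandas as pd
from flumefish.synth import AFTTruth, gen_fatigue
from flumefish.endurance import breakpoint_search, predict_T, endurance_state

rng = np.random.default_rng(42)
truth = AFTTruth()                       # two-regime endurance truth
vs = np.concatenate([rng.uniform(3.83, 6.13, 47),
                     rng.uniform(6.13, 9.0, 138)])
bl = rng.normal(0.3916, 0.045, 185)
records = gen_fatigue(pd.DataFrame({"mean_Vs_bls": vs, "BL_m": bl}),
                      truth, rng=rng, censor_fraction=0.10)

model = breakpoint_search(records, ("Vs", "BL"))
print(f"breakpoint: {model.breakpoint:.2f} BL/s   "
      f"AIC: {model.aic:.1f}   C-index: {model.c_index_:.2f}")
print(model.summary().round(3).to_string(index=False))

T = predict_T(model, 7.0, 0.40)
print(f"predicted fatigue time at 7 BL/s, 0.40 m fish: {T:.1f} s")
E = endurance_state(np.full(90, 7.0), 18.0, model, 0.40)
print(f"endurance left after 5 s at that speed: {E[-1]:.2f}")
```

prints

```
breakpoint: 6.19 BL/s   AIC: 1430.6   C-index: 0.76
    model   variable  coefficient    se   p
Prolonged  Intercept        6.864 0.963 0.0
Prolonged         Vs       -1.104 0.130 0.0
Prolonged         BL        7.700 1.710 0.0
Prolonged Log(scale)       -0.689 0.130 0.0
   Sprint  Intercept       10.119 0.684 0.0
   Sprint         Vs       -0.521 0.065 0.0
   Sprint         BL       -7.711 1.127 0.0
   Sprint Log(scale)       -0.558 0.073 0.0
predicted fatigue time at 7 BL/s, 0.40 m fish: 29.7 s
endurance left after 5 s at that speed: 0.83
```

The search lands near the generating breakpoint (6.13 BL/s); the fitted
coefficients recover the generating values within their standard errors —
negative swim-speed slopes in both regimes (endurance falls with speed),
a positive body-length effect in the prolonged regime and a negative one in
the sprint regime. The endurance state then converts the fitted model into
a running fatigue budget: after 5 s at 7 BL/s a 0.40 m fish has 83% of its
endurance left.

The full pipeline (CSV in, CSV reports out) is driven by a YAML config:

```
flumefish simulate --seed 1 --out sim --n-fish 10
flumefish behavior --config run.yaml --out results
```

with `run.yaml` pointing at the ADV manifest, trajectory and fish-metadata
tables (`flumefish.pipeline.RunConfig` lists every key and its default).

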