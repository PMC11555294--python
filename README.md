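# ivtsurf

Current–voltage–time (IVT) surface analysis of the ventricular action
potential.

The waveform of a ventricular action potential (AP) shows only the
trajectory the membrane actually followed. What it could do if perturbed —
whether an extra stimulus triggers a full sodium-driven AP, a slow
calcium-driven one, or an abrupt all-or-none repolarization; how much
outward charge is in reserve to finish repolarizing safely — is encoded in
the total ionic current available at *other* voltages at each instant.
`ivtsurf` measures exactly that, in silico: at each time `T` during a
simulated AP it clamps the membrane across a voltage grid for a short time
`t_vc`, records the total ionic current `I_ion(T, V)` at the end of the
clamp, and stacks the resulting quasi-instantaneous IV curves into a 3-D
IVT surface. From that surface it derives

* zero-current equilibria and their stability — the resting state, the
  excitation threshold, thresholds for all-or-none repolarization (AONR)
  and for calcium- vs sodium-driven APs, and a bistable window where
  stimulus strength selects between the two;
* a four-region segmentation of repolarization (inducible self-regenerating
  repolarization / no thresholds / calcium threshold / sodium threshold);
* membrane resistance `R_m(T) = (dI/dV)^-1` at the AP's own voltage,
  including its negative window during late repolarization;
* the absolute refractory window (no sodium current available at any
  voltage);
* a charge-based repolarization-reserve metric: the volume under the
  surface over a late-repolarization region of interest, divided by its
  voltage height and scaled by the membrane capacitance, in pC.

The cell model is the O'Hara–Rudy human ventricular model (endocardial
variant), implemented in-repo from its published equations, with per-current
conductance scaling (e.g. `I_Kr` at 30% to model hERG block) and a small
analytic toy model for verification. It is intended for cellular
electrophysiologists and modellers studying repolarization stability,
pro-arrhythmic drug effects and restitution; everything is a deterministic
simulation — no external data are required.

## Worked example

```python
from ivtsurf import ORdModel, ModelParams
from ivtsurf.protocols import condition, find_threshold_current, simulate_ap, StimulusSpec
from ivtsurf.ivt_surface import measure_iv_curve
from ivtsurf.surface_analysis import find_equilibria, _local_slope

model = ORdModel(ModelParams())
rest = condition(model, bcl=800.0, n_beats=200)          # pacing to steady state
thr = find_threshold_current(rest, model, duration=0.5)  # liminal current, A/F
ap = simulate_ap(rest, model, StimulusSpec(-1.5 * thr, 0.5), duration=800.0)
print(f"diastolic V_m = {rest[0]:.1f} mV, liminal current = {thr:.1f} A/F")
print(f"APD(-60) = {ap.APD:.1f} ms; AP state at T=50 ms: "
      f"V = {ap.V_at(50.0):.1f} mV, I_ion = {ap.i_ion_at(50.0):.2f} A/F")

dia = measure_iv_curve(ap, ap.repol_time(0.99) + 20.0, t_vc=5.0)
for eq in find_equilibria(dia):
    print(f"equilibrium at {eq.V:6.1f} mV ({eq.stability}, {eq.kind})")

c180 = measure_iv_curve(ap, 180.0, t_vc=1.0, record_components=False)
slope = _local_slope(c180.V_grid, c180.I_total, c180.ap_point[0])
print(f"R_m at T=180 ms: {1.0/slope:.1f} MOhm")
```

prints (200 conditioning beats, one CPU, ~20 s):

```
diastolic V_m = -88.0 mV, liminal current = 57.0 A/F
APD(-60) = 243.6 ms; AP state at T=50 ms: V = 32.8 mV, I_ion = 0.22 A/F
equilibrium at  -87.5 mV (stable, rest)
equilibrium at  -57.7 mV (unstable, Na_threshold)
equilibrium at   35.8 mV (stable, excited)
R_m at T=180 ms: -101.2 MOhm
```

Reading: the diastolic IV curve crosses zero at the stable resting state
(−87.5 mV) and at the unstable excitation threshold (−57.7 mV); a third,
depolarized stable crossing is the excited state. At T = 180 ms the
isochronal slope at the AP's own voltage is negative — the membrane behaves
as a negative resistance (~−100 MΩ, reciprocal-slope convention), the
signature of self-regenerating late repolarization.

A command-line interface mirrors the library
(`ivtsurf run|condition|ap|surface|analyze|rm|restitution|strength-interval|reserve|fixtures`);
configs are JSON/YAML (see `ivtsurf.config.RunConfig`), surfaces are stored
as HDF5 plus long-format CSV, reports as JSON.

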