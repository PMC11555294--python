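# Methods

## The model and the representation

`ivtsurf` reconstructs the human ventricular action potential (AP) with the
O'Hara–Rudy (ORd, 2011) cell model, transcribed in full from its published
equation supplement: 41 state variables (membrane potential, eight
intracellular/subspace ion concentrations, Hodgkin–Huxley gates with their
CaMK-phosphorylated duplicates, sarcoplasmic-reticulum release fluxes and
the CaMK trap) and 16 membrane currents in A/F. The endocardial
parameterization is the default; the epi/M variant factors of the published
model are available through `ModelParams(cell_variant=...)`, and maximal
conductances can be scaled per current (e.g. `{"I_Kr": 0.3}` for 70% hERG
block). A minimal toy model (ohmic or cubic instantaneous IV, one
current-decoupled gate) provides closed forms for every analysis operation.

The central object is the quasi-instantaneous current–voltage–time (IVT)
surface. At each AP time `T` (measured from the upstroke, the instant of
maximum dV/dt) the membrane is switched to an ideal voltage clamp — V
replaced, dV/dt forced to zero, every gating and concentration ODE still
running — across a voltage grid, and the total ionic current I_ion (plus
every component current) is read at clamp time `t_vc`. Time-aligning these
isochronal IV curves gives the surface I(T, V). For small `t_vc` the AP's
own (I, V, T) states lie on the surface; the residual `delta_I` (current on
the surface at the AP's voltage minus the AP's instantaneous current) is
the gating increment accumulated during the clamp and grows with `t_vc`.

## Numerical integration

The equations are stiff (gate time constants from ~30 µs to seconds).
Production integration uses LSODA at `rtol 1e-6`, `atol 1e-8`, with dense
output retained so any snapshot can be interpolated without event
stopping. Rectangular stimulus pulses are handled by splitting the time
axis at the pulse edges, so the solver never steps across a discontinuous
right-hand side; the rare LSODA abort on near-threshold (saddle-passage)
trajectories falls back to BDF. The right-hand side is a single
scalar-arithmetic kernel compiled with numba (plain Python if numba is
absent). A fixed-step forward-Euler integrator at dt = 1 µs serves as the
cross-validation oracle in the test suite (agreement within 0.5 mV over an
AP); it is never used in production.

The GHK-type flux expressions are 0/0 at V = 0 mV (a grid point); the
kernel switches to the analytic limit for |V| below 0.1 µV.

## Protocols and their conventions

* **Conditioning**: pacing from the published initial state, default 1000
  beats, cathodal 0.5-ms pulses 50% above the liminal amplitude (≈ −86
  A/F at rest). A beat that fails to repolarize below −60 mV is tolerated
  if isolated (complex alternans regimes produce single long beats);
  three consecutive failures raise an error. Results are cached per
  (model, BCL, beats, stimulus).
* **APD**: time from maximum dV/dt to the −60 mV crossing of final
  repolarization.
* **Liminal current**: bisection to 1% on the pulse amplitude, bracket
  capped at 200 A/F. The default capture predicate is an upstroke
  crossing 0 mV; protocols probing refractory or plateau states use the
  stricter `active_response` predicate (maximum intrinsic depolarization
  rate −I_ion above 0.5 mV/ms and overshoot), because a strong pulse can
  push a depolarized membrane over 0 mV passively.
* **Clamp-and-release**: 1-ms clamp at a scanned voltage, then 100 ms of
  free running; the scalar readout is the mean dV/dt over the follow
  window. The transition to self-regenerating repolarization is placed at
  the most negative second difference of the (normalized) mean-derivative
  profile, scanning from depolarized to polarized, reported at the
  midpoint of the falling interval (the unbiased estimator on a 2-mV
  grid); profiles with no point abrupt enough return "no transition".
* **S1–S2 restitution**: one S2 after steady S1 pacing, coupling interval
  measured stimulus-to-stimulus. When steady pacing is an alternans cycle
  the S1 reference is the first cycle that starts from diastole
  (V < −80 mV) and captures, and its APD is measured on a free-running
  window (it can exceed the BCL under I_Kr block). S2 capture requires a
  regenerative response; the restitution slope is the maximum
  finite-difference slope, computed against both diastolic interval and
  coupling interval.

## Surface analyses

* **Equilibria**: zero crossings of an isochronal curve by sign change,
  refined with a local cubic fit (≤0.1 mV against a 0.01-mV dense scan on
  cubic fixtures); stable where the local slope is positive. Crossings
  closer than 1 mV are merged. An unstable crossing below the AP's
  voltage is an all-or-none-repolarization (AONR) threshold; above it, an
  excitation threshold, labelled sodium- or calcium-driven by whichever
  inward component dominates just depolarized of the crossing.
* **Region segmentation** (on the `t_vc = 5 ms` surface): region I — an
  AONR crossing or a qualifying positive IV minimum exists while the AP
  state still sits on a positive-slope limb (self-regenerating
  repolarization can be induced); region II — no thresholds, AP state on
  the negative limb; region III — calcium threshold available; region IV —
  sodium threshold available. The bistable window is the part of region
  III where sodium current is also available, so stimulus strength selects
  between a calcium- and a sodium-driven response.
* **Membrane resistance**: the isochronal slope at the AP's voltage from a
  local quadratic fit over ±4 mV. `R_m` follows the per-capacitance
  reporting convention (reciprocal slope with 1 A/F read as 1 nA, i.e. MΩ
  referenced to 1 nF); `R_m_abs = 1/(g' C_m)` gives the absolute value
  for the actual capacitance (default C_m = 200 pF). R_m is negative on
  the late negative-slope limb (≈150–255 ms at BCL 800) and its
  sign structure is invariant for `t_vc` between 2 and 10 ms.
* **Refractory window**: the maximal T interval with no sodium current
  available at any clamp voltage. Because sodium availability recovers
  exponentially (≈×3 per 4 ms), the window end under the strict default
  floor (0.05 A/F) sits ~15 ms earlier than the refractoriness seen by
  finite stimuli; `eps_mode="relative"` (floor as a fraction of the
  surface's I_Na range) aligns the end with the slope-sign transition.
* **Time constant**: single-exponential fit of the sub-threshold
  relaxation after a small 1-ms pulse, cross-checked against the
  reciprocal resting IV slope (the two agree within 10%; both give
  ≈5.4–5.7 ms for the conditioned endocardial cell at BCL 800).

## Repolarization reserve

The charge available during late repolarization is the trapezoidal double
integral of I(T, V) over a region of interest divided by the ROI's voltage
height and scaled by C_m (1 (A/F)·ms at 200 pF = 0.2 pC). The default ROI
runs from the lower limit of region III to 99% repolarization; a paired
(perturbed) condition reuses the reference ROI duration so the two
conditions integrate over the same time span. The signed integral is the
default; an outward-only option clips inward current. The paired pipeline
(`compare_conditions`) also classifies the response to an extrastimulus
inside the ROI and flags abnormal repolarization (successive-APD
difference > 5 ms, or beats failing to repolarize) under constant-CL
follow-up pacing.

## Problem sizes and tolerances

Default grids: V from −100 to +50 mV in 2-mV steps; T in 2-ms steps from
the upstroke to 99% repolarization + 50 ms; `t_vc` 1 ms for morphology and
R_m, 5 ms for threshold analyses. Diastolic measurements are taken at
99% repolarization + 20 ms, where the AP trajectory has settled into
diastole. The test suite conditions for 150 beats (the residual drift is
documented per test where it matters); `scripts/acceptance.py` uses the
full 1000 beats and completes in a few minutes on one CPU.

## Known limitations

* The Na/Ca classification of elicited APs is a continuum near the region
  III/IV border; the 50 mV/ms default cut is configurable and the bistable
  window is therefore reported from the surface's threshold structure
  rather than from stimulation scans.
* The restitution maximum slope under strong I_Kr block depends visibly on
  the capture convention and CI sampling because the S1 steady state is an
  alternans cycle; the robust result is slope > 1 (alternans predicted)
  versus ≈0.3 in control.
* Single cell only: no electrotonic loading or propagation, so
  source–sink interpretations of negative R_m remain outside the package's
  scope.
* The quiescent model is not exactly at a fixed point after conditioning
  (slow ionic drift persists at the 1e-5/ms level for minutes of model
  time), so "rest" always refers to the paced diastolic state.
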