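"""Charge-based quantification of repolarization reserve (RR).

The outward charge available during late repolarization is read off the
IVT surface: the volume under the surface over a region of interest (ROI)
spanning from the lower limit of region III (first availability of the
calcium threshold) to 99% repolarization, divided by the ROI's voltage
height and converted to pC with the membrane capacitance.  Comparing a
control and an I_Kr-reduced condition on the shortest captured restitution
beat reproduces the canonical reserve-depletion readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ivt_surface import IVTSurface, build_surface
from .models.base import CellModel
from .protocols import (
    APTrajectory,
    RestitutionCurve,
    StimulusSpec,
    condition,
    s1s2_restitution,
    simulate_ap,
)
from .surface_analysis import RegionMap, classify_ap_type, segment_regions

logger = logging.getLogger(__name__)

ALTERNANS_APD_DELTA = 5.0  # ms

__all__ = [
    "ROI",
    "ReserveResult",
    "ConditionComparison",
    "default_roi",
    "charge_reserve",
    "region_iii_over_apd",
    "compare_conditions",
]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest on the (T, V) plane."""

    T_start: float
    T_end: float
    V_low: float
    V_high: float

    def __post_init__(self) -> None:
        if not self.T_end > self.T_start:
            raise ValueError("ROI requires T_end > T_start")
        if not self.V_high > self.V_low:
            raise ValueError("ROI requires V_high > V_low")

    @property
    def duration(self) -> float:
        return self.T_end - self.T_start

    @property
    def height(self) -> float:
        return self.V_high - self.V_low


@dataclass
class ReserveResult:
    charge_pC: float
    regionIII_over_APD: float
    roi: ROI
    condition: str
    apd: float | None = None


@dataclass
class ConditionComparison:
    control: ReserveResult
    perturbed: ReserveResult
    restitution_control: RestitutionCurve
    restitution_perturbed: RestitutionCurve
    extrastim_response: dict[str, str]
    followup_apds: dict[str, np.ndarray]
    alternans: dict[str, bool]


def default_roi(
    surface: IVTSurface,
    region_map: RegionMap,
    trajectory: APTrajectory,
    duration: float | None = None,
) -> ROI:
    """ROI from the lower limit of region III to 99% repolarization.

    With ``duration`` given (the reference condition's ROI width), the ROI
    keeps that width instead, so paired conditions integrate over the same
    amount of time.  The voltage extent is the range the AP itself spans
    over the ROI (V at the end to V at the start).
    """
    if region_map.II_end >= region_map.III_end:
        raise ValueError("region III absent: no calcium-threshold window on this surface")
    t_start = region_map.II_end
    if duration is None:
        t_end = trajectory.repol_time(0.99)
        if t_end <= t_start:
            raise ValueError("99% repolarization precedes region III; degenerate trajectory")
    else:
        t_end = t_start + duration
    v_high = float(trajectory.V_at(t_start))
    v_low = float(trajectory.V_at(t_end))
    if not v_high > v_low:
        raise ValueError("AP spans no voltage range over the ROI (already at rest?)")
    return ROI(T_start=float(t_start), T_end=float(t_end), V_low=v_low, V_high=v_high)


def charge_reserve(surface: IVTSurface, roi: ROI, C_m_pF: float | None = None,
                   outward_only: bool = False) -> float:
    """Charge (pC) available under the surface over the ROI.

    Trapezoidal double integral of I(T, V) [(A/F) mV ms], divided by the
    ROI height (mV) and multiplied by C_m: (A/F) ms x F = 1e-3 nC, i.e.
    1 (A/F) ms at 200 pF is 0.2 pC.  Outward (positive) current yields
    positive charge; ``outward_only`` clips inward contributions to zero.
    """
    C_m = C_m_pF if C_m_pF is not None else surface.metadata.get("params", {}).get("C_m_pF", 200.0)
    Tg, Vg = surface.T_grid, surface.V_grid
    if roi.T_start < Tg[0] - 1e-9 or roi.T_end > Tg[-1] + 1e-9:
        raise ValueError(f"ROI time span [{roi.T_start}, {roi.T_end}] outside surface grid")
    if roi.V_low < Vg[0] - 1e-9 or roi.V_high > Vg[-1] + 1e-9:
        raise ValueError(f"ROI voltage span [{roi.V_low}, {roi.V_high}] outside surface grid")
    # resample the surface onto the ROI (grid nodes plus the ROI edges)
    tt = np.unique(np.concatenate([
        Tg[(Tg > roi.T_start) & (Tg < roi.T_end)], [roi.T_start, roi.T_end]]))
    vv = np.unique(np.concatenate([
        Vg[(Vg > roi.V_low) & (Vg < roi.V_high)], [roi.V_low, roi.V_high]]))
    grid = np.empty((tt.size, vv.size))
    for j, v in enumerate(vv):
        col = np.array([np.interp(v, Vg, row) for row in surface.I])
        grid[:, j] = np.interp(tt, Tg, col)
    if outward_only:
        grid = np.clip(grid, 0.0, None)
    vol = np.trapezoid(np.trapezoid(grid, vv, axis=1), tt)  # (A/F) mV ms
    mean_I_ms = vol / roi.height                             # (A/F) ms
    return float(mean_I_ms * C_m * 1e-12 * 1e-3 * 1e12)      # pC


def region_iii_over_apd(region_map: RegionMap, apd: float) -> float:
    width = max(region_map.III_end - region_map.II_end, 0.0)
    return float(width / apd) if apd > 0 else float("nan")


def _followup_apds(model: CellModel, conditioned, stim: StimulusSpec, ci: float,
                   n_beats: int = 6) -> np.ndarray:
    """APDs under constant-CL pacing at CL = CI after the conditioned state."""
    apds = []
    y = conditioned
    for _ in range(n_beats):
        traj = simulate_ap(y, model, stim, duration=ci)
        apds.append(np.nan if traj.APD is None else traj.APD)
        y = traj.sol(ci)
    return np.array(apds)


def compare_conditions(
    params_control,
    params_perturbed,
    model_factory,
    bcl: float = 350.0,
    n_beats: int = 1000,
    s2_intervals=None,
    t_vc: float = 1.0,
    t_vc_regions: float = 5.0,
    extrastim_T: float = 150.0,
    stim: StimulusSpec | None = None,
    T_step: float = 2.0,
    V_grid=None,
) -> ConditionComparison:
    """Full control-vs-perturbed reserve pipeline on the shortest captured
    restitution beat: S1-S2 restitution at ``bcl``, IVT surfaces of the
    shortest beats, ROI charges and region-III/APD ratios (paired ROI
    durations), extrastimulus response classification at ``extrastim_T``,
    and constant-CL follow-up pacing with an alternans flag."""
    stim = stim or StimulusSpec(amplitude=-80.0)
    if s2_intervals is None:
        s2_intervals = np.arange(240.0, 401.0, 10.0)

    results = {}
    ref_duration = None
    for label, params in (("control", params_control), ("perturbed", params_perturbed)):
        model = model_factory(params)
        rest = s1s2_restitution(model, bcl, s2_intervals, n_beats=n_beats, stim=stim)
        if rest.ci.size == 0:
            raise RuntimeError(f"{label}: no captured S2 beats")
        ci_short = float(rest.ci.min())
        conditioned = condition(model, bcl, n_beats, stim)
        # state right before the shortest-CI S2
        pre = simulate_ap(conditioned, model, stim, duration=ci_short)
        s2_traj = simulate_ap(pre.sol(ci_short), model, stim, duration=700.0)
        T_grid = np.arange(0.0, (s2_traj.APD or 400.0) + 80.0, T_step)
        surf = build_surface(s2_traj, T_grid=T_grid, t_vc=t_vc, V_grid=V_grid)
        surf5 = surf if abs(t_vc - t_vc_regions) < 1e-9 else build_surface(
            s2_traj, T_grid=T_grid, t_vc=t_vc_regions, V_grid=V_grid)
        rmap = segment_regions(surf5)
        roi = default_roi(surf, rmap, s2_traj, duration=ref_duration)
        if label == "control":
            ref_duration = roi.duration
        charge = charge_reserve(surf, roi, model.params.C_m_pF)
        ratio = region_iii_over_apd(rmap, s2_traj.APD or np.nan)
        # extrastimulus inside the ROI
        extra = simulate_ap(s2_traj.state_at(extrastim_T), model, stim, duration=500.0)
        resp = classify_ap_type(extra)
        # constant CL = CI follow-up pacing
        apds = _followup_apds(model, pre.sol(ci_short), stim, ci_short)
        # abnormal repolarization under constant-CL pacing: successive-APD
        # alternation, or beats that fail to repolarize within the cycle
        diffs = np.abs(np.diff(apds))
        alternans = bool(
            np.any(diffs[np.isfinite(diffs)] > ALTERNANS_APD_DELTA)
            or np.any(~np.isfinite(apds[1:]))
        )
        results[label] = dict(
            reserve=ReserveResult(charge_pC=charge, regionIII_over_APD=ratio, roi=roi,
                                  condition=label, apd=s2_traj.APD),
            restitution=rest, resp=resp, apds=apds, alternans=alternans,
        )

    return ConditionComparison(
        control=results["control"]["reserve"],
        perturbed=results["perturbed"]["reserve"],
        restitution_control=results["control"]["restitution"],
        restitution_perturbed=results["perturbed"]["restitution"],
        extrastim_response={k: results[k]["resp"] for k in results},
        followup_apds={k: results[k]["apds"] for k in results},
        alternans={k: results[k]["alternans"] for k in results},
    )
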