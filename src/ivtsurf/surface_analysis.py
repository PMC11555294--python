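"""Analysis of IVT surfaces: equilibria, thresholds, region segmentation,
membrane resistance, refractory window and AP-type classification.

Dynamical reading of an isochronal IV curve: each zero-current crossing is
an equilibrium of the fast (V) subsystem -- stable where the local IV slope
is positive, unstable (a threshold) where it is negative.  Pushed past an
unstable crossing the membrane regenerates away from the AP state: toward
rest (all-or-none repolarization, AONR) if the crossing lies below the
AP's voltage, toward a depolarized excited state (a sodium- or
calcium-driven AP) if above.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .ivt_surface import IVCurve, IVTSurface, measure_iv_curve
from .models.base import CellModel
from .protocols import APTrajectory, StimulusSpec, simulate_ap

logger = logging.getLogger(__name__)

ZERO_CROSSING_TOL = 1e-3   # A/F
MERGE_RADIUS = 1.0         # mV
SLOPE_FIT_HALFWIDTH = 4.0  # mV, local quadratic fit window for IV slopes
INA_ABSENT_EPS = 0.05      # A/F, "no sodium current available" floor
NA_DVDT_CUT = 50.0         # mV/ms, sodium- vs calcium-driven discrimination
CA_ACTIVE_RATE = 0.5       # mV/ms, minimum intrinsic regenerative rate
CA_OVERSHOOT = -30.0       # mV

__all__ = [
    "EquilibriumPoint",
    "SRRMinimum",
    "SRRTransition",
    "RegionMap",
    "RmProfile",
    "find_equilibria",
    "find_srr_minima",
    "detect_srr_transition",
    "segment_regions",
    "membrane_resistance",
    "ap_slope_profile",
    "tvc_sign_map",
    "slope_sign_transition",
    "refractory_window",
    "classify_ap_type",
    "membrane_time_constant",
    "rm_from_slope",
]


@dataclass
class EquilibriumPoint:
    T: float
    V: float
    stability: str                 # "stable" | "unstable"
    regenerative_direction: str | None  # "depolarizing" | "repolarizing" | None
    kind: str                      # rest | excitation | AONR | Ca_threshold | Na_threshold
    slope: float                   # secant IV slope at the crossing, (A/F)/mV


@dataclass
class SRRMinimum:
    """Positive local minimum of an isochronal IV curve below the AP state:
    overcoming it by anodal displacement puts the membrane on the
    negative-slope limb and repolarization becomes self-regenerating."""

    T: float
    V: float
    I: float


@dataclass
class SRRTransition:
    V: float
    score: float


@dataclass
class RegionMap:
    """Four-region segmentation of AP repolarization.

    Region I: self-regenerating repolarization reachable (AONR threshold or
    qualifying IV minimum).  Region II: no thresholds, AP on the
    negative-slope limb.  Region III: calcium-current threshold available.
    Region IV: sodium threshold available (resting excitability recovered).
    """

    I_end: float
    II_end: float
    III_end: float
    IV_start: float
    bistable_window: tuple[float, float] | None
    annotations: dict[float, list] = field(default_factory=dict)
    anomalies: list[str] = field(default_factory=list)


@dataclass
class RmProfile:
    """Membrane resistance along the AP.

    ``R_m`` follows the field's reporting convention for per-capacitance
    IV data: the reciprocal of the isochronal slope with current read as
    nA-per-nF (numerically, MOhm referenced to 1 nF).  ``R_m_abs`` is the
    absolute resistance 1/(g' C_m) for the actual membrane capacitance.
    Both are signed: R_m < 0 on the negative-slope limb.
    """

    T: np.ndarray
    R_m: np.ndarray                # MOhm (1 A/F == 1 nA convention); +/-inf where slope ~ 0
    R_m_abs: np.ndarray            # MOhm for the true C_m
    slope: np.ndarray              # S/F
    sign_windows: list             # (T_start, T_end, sign)
    C_m_pF: float
    t_vc: float
    tvc_sign_map: dict | None = None


# --------------------------------------------------------------------------
# curve-level primitives
# --------------------------------------------------------------------------

def _refine_crossing(V: np.ndarray, I: np.ndarray, k: int) -> float:
    """Zero of I between samples k and k+1: local cubic fit through the
    surrounding four samples, falling back to the linear secant."""
    linear = V[k] + I[k] / (I[k] - I[k + 1]) * (V[k + 1] - V[k])
    lo, hi = max(0, k - 1), min(len(V), k + 3)
    if hi - lo >= 4:
        coef = np.polyfit(V[lo:hi] - V[k], I[lo:hi], 3)
        roots = np.roots(coef) + V[k]
        real = roots[np.abs(roots.imag) < 1e-9].real
        inside = real[(real >= V[k] - 1e-9) & (real <= V[k + 1] + 1e-9)]
        if inside.size:
            return float(inside[np.argmin(np.abs(inside - linear))])
    return float(linear)


def _crossings(V: np.ndarray, I: np.ndarray):
    """Zero crossings by sign change with local polynomial refinement.

    Returns a list of (V_cross, secant_slope).  Only exact zeros are
    treated as on-grid equilibria; ZERO_CROSSING_TOL is the tolerance for
    *querying* whether a point is an equilibrium, not for detection (a
    shallow curve can stay below any tolerance across several samples).
    """
    out = []
    s = np.sign(I)
    for k in range(len(V) - 1):
        a, b = s[k], s[k + 1]
        if a == 0.0 and b == 0.0:
            continue
        if a == 0.0:
            out.append((float(V[k]), (I[k + 1] - I[k]) / (V[k + 1] - V[k])))
        elif a * b < 0:
            vz = _refine_crossing(V, I, k)
            out.append((vz, (I[k + 1] - I[k]) / (V[k + 1] - V[k])))
    if len(s) and s[-1] == 0.0:
        out.append((float(V[-1]), (I[-1] - I[-2]) / (V[-1] - V[-2])))
    # merge clusters closer than MERGE_RADIUS (tangency artifacts)
    merged = []
    for vz, sl in out:
        if merged and abs(vz - merged[-1][0]) < MERGE_RADIUS:
            v_prev, sl_prev = merged[-1]
            merged[-1] = ((vz + v_prev) / 2.0, sl if abs(sl) > abs(sl_prev) else sl_prev)
        else:
            merged.append((vz, sl))
    return merged


def _dominant_inward(curve: IVCurve, v_from: float, v_to: float) -> str | None:
    """Which of I_Na / I_CaL carries the larger inward current on [v_from, v_to]."""
    sel = (curve.V_grid >= v_from) & (curve.V_grid <= v_to)
    if not sel.any():
        return None
    mins = {}
    for name in ("I_Na", "I_CaL"):
        if name in curve.components:
            mins[name] = float(curve.components[name][sel].min())
    if not mins:
        return None
    name = min(mins, key=mins.get)
    return name if mins[name] < 0 else None


def find_equilibria(curve: IVCurve) -> list[EquilibriumPoint]:
    """Zero-current equilibria of one isochronal IV curve, with stability
    (sign of local slope) and threshold classification."""
    I = np.asarray(curve.I_total, dtype=float)
    if not np.all(np.isfinite(I)):
        raise ValueError("IV curve contains non-finite currents")
    v_ap = curve.ap_point[0] if curve.ap_point is not None else None
    pts = []
    for vz, slope in _crossings(curve.V_grid, I):
        stable = slope > 0
        if v_ap is None or abs(vz - v_ap) < MERGE_RADIUS:
            direction = None
        elif vz < v_ap:
            direction = "repolarizing"   # far side of the crossing is polarized, I > 0 there
        else:
            direction = "depolarizing"
        if stable:
            kind = "rest" if (v_ap is None or vz <= v_ap + MERGE_RADIUS) else "excited"
        elif direction == "repolarizing":
            kind = "AONR"
        else:
            dom = _dominant_inward(curve, vz, vz + 20.0)
            if dom == "I_Na":
                kind = "Na_threshold"
            elif dom == "I_CaL":
                kind = "Ca_threshold"
            else:
                kind = "excitation"
        pts.append(EquilibriumPoint(
            T=curve.T, V=vz, stability="stable" if stable else "unstable",
            regenerative_direction=direction, kind=kind, slope=float(slope),
        ))
    return pts


def find_srr_minima(curve: IVCurve) -> list[SRRMinimum]:
    """Discrete local minima with I > 0 below the AP's voltage, refined by a
    local quadratic fit; ties broken toward more polarized V."""
    I = np.asarray(curve.I_total, dtype=float)
    V = curve.V_grid
    v_ap = curve.ap_point[0] if curve.ap_point is not None else np.inf
    out = []
    for k in range(1, len(V) - 1):
        if not (I[k] <= I[k - 1] and I[k] < I[k + 1]):  # ties -> more polarized wins
            continue
        if I[k] <= ZERO_CROSSING_TOL or V[k] >= v_ap - MERGE_RADIUS:
            continue
        # quadratic refinement on the three surrounding samples
        coef = np.polyfit(V[k - 1:k + 2], I[k - 1:k + 2], 2)
        v_min = float(V[k]) if abs(coef[0]) < 1e-12 else float(-coef[1] / (2 * coef[0]))
        if abs(v_min - V[k]) > (V[k + 1] - V[k]):
            v_min = float(V[k])
        out.append(SRRMinimum(T=curve.T, V=v_min, I=float(np.polyval(coef, v_min))))
    return out


def detect_srr_transition(V_clamps, mean_dvdt, min_score: float = 0.05) -> SRRTransition | None:
    """Transition voltage of the clamp-release criterion.

    Scanning from depolarized toward polarized clamp values, the mean
    post-release dV/dt first grows roughly linearly, then drops abruptly at
    the self-regenerating-repolarization transition; the transition is
    placed at the most negative second difference of the (normalized)
    profile.  Returns None when no point is abrupt enough.
    """
    V = np.asarray(V_clamps, dtype=float)
    D = np.asarray(mean_dvdt, dtype=float)
    order = np.argsort(V)[::-1]  # depolarized first
    V, D = V[order], D[order]
    span = float(np.ptp(D))
    if len(V) < 3 or span < 1e-9:
        return None
    Dn = (D - D.min()) / span
    d2 = Dn[2:] - 2.0 * Dn[1:-1] + Dn[:-2]
    k = int(np.argmin(d2))
    score = float(-d2[k])
    if score < min_score:
        return None
    # the drop happens between the located sample and the next more
    # polarized one; report the midpoint of that interval
    c = k + 1
    v_t = 0.5 * (V[c] + V[c + 1]) if c + 1 < len(V) else float(V[c])
    return SRRTransition(V=float(v_t), score=score)


def srr_transition_from_sweep(
    trajectory: APTrajectory,
    T: float,
    V_scan=None,
    t_vc: float = 1.0,
    follow: float = 100.0,
) -> tuple[SRRTransition | None, np.ndarray, np.ndarray]:
    """Run the clamp-release V scan at AP time T and detect the transition."""
    from .protocols import clamp_release

    V_scan = np.arange(-100.0, 50.0 + 1e-9, 2.0) if V_scan is None else np.asarray(V_scan)
    snap = trajectory.state_at(T)
    means = np.array([
        clamp_release(snap, trajectory.model, vc, t_vc=t_vc, follow=follow).mean_dvdt
        for vc in V_scan
    ])
    return detect_srr_transition(V_scan, means), V_scan, means


# --------------------------------------------------------------------------
# membrane resistance
# --------------------------------------------------------------------------

def _local_slope(V: np.ndarray, I: np.ndarray, v0: float,
                 halfwidth: float = SLOPE_FIT_HALFWIDTH) -> float:
    """IV slope at v0 in (A/F)/mV by local quadratic fit over +/- halfwidth."""
    sel = np.abs(V - v0) <= halfwidth + 1e-9
    if sel.sum() < 3:
        k = int(np.argmin(np.abs(V - v0)))
        sel = np.zeros_like(sel)
        sel[max(0, k - 2):k + 3] = True
    coef = np.polyfit(V[sel], I[sel], 2)
    return float(2.0 * coef[0] * v0 + coef[1])


def rm_from_slope(slope_sf: float, C_m_pF: float | None = None) -> float:
    """Membrane resistance in MOhm from an isochronal slope in S/F.

    With ``C_m_pF`` given, the absolute resistance 1/(g' C_m); without, the
    per-capacitance reporting convention (reciprocal slope with 1 A/F read
    as 1 nA, i.e. MOhm referenced to 1 nF).  Slopes below 1e-6 S/F in
    magnitude map to signed infinity.
    """
    if abs(slope_sf) < 1e-6:
        return math.copysign(math.inf, slope_sf if slope_sf != 0 else 1.0)
    c_ref = 1e-9 if C_m_pF is None else C_m_pF * 1e-12
    return 1e-6 / (slope_sf * c_ref)


def membrane_resistance(surface: IVTSurface, C_m_pF: float | None = None) -> RmProfile:
    """R_m(T) along the AP from the isochronal IV slope at the AP's voltage."""
    C_m = C_m_pF if C_m_pF is not None else surface.metadata.get("params", {}).get("C_m_pF", 200.0)
    slope_sf = np.array([
        _local_slope(surface.V_grid, row, v_ap)
        for row, v_ap in zip(surface.I, surface.ap_V)
    ]) * 1000.0
    rm = np.array([rm_from_slope(s) for s in slope_sf])
    rm_abs = np.array([rm_from_slope(s, C_m) for s in slope_sf])
    return RmProfile(
        T=surface.T_grid, R_m=rm, R_m_abs=rm_abs, slope=slope_sf,
        sign_windows=_sign_windows(surface.T_grid, slope_sf),
        C_m_pF=float(C_m), t_vc=surface.t_vc,
    )


def _sign_windows(T: np.ndarray, x: np.ndarray):
    out = []
    if len(T) == 0:
        return out
    sgn = np.sign(x)
    start = T[0]
    cur = sgn[0]
    for k in range(1, len(T)):
        if sgn[k] != cur:
            out.append((float(start), float(T[k - 1]), int(cur)))
            start, cur = T[k], sgn[k]
    out.append((float(start), float(T[-1]), int(cur)))
    return out


def ap_slope_profile(
    trajectory: APTrajectory,
    T_grid,
    t_vc: float,
    halfwidth: float = SLOPE_FIT_HALFWIDTH,
    v_step: float = 2.0,
):
    """Isochronal IV slope at the AP state, measured directly (a narrow
    +/- halfwidth voltage window is clamped at each T instead of a full
    surface column).  Returns (T_grid, slope in S/F)."""
    T_grid = np.asarray(T_grid, dtype=float)
    slopes = np.empty(T_grid.shape)
    offsets = np.arange(-halfwidth, halfwidth + 1e-9, v_step)
    for k, T in enumerate(T_grid):
        v_ap = float(trajectory.V_at(T))
        curve = measure_iv_curve(trajectory, T, t_vc, v_ap + offsets,
                                 record_components=False)
        slopes[k] = _local_slope(curve.V_grid, curve.I_total, v_ap, halfwidth) * 1000.0
    return T_grid, slopes


def tvc_sign_map(trajectory: APTrajectory, t_vc_list, T_grid) -> dict:
    """Sign of the AP-state IV slope over (t_vc, T) -- the stability map of
    the negative-resistance window against the clamp duration."""
    out = {}
    for tvc in t_vc_list:
        _, slopes = ap_slope_profile(trajectory, T_grid, tvc)
        out[float(tvc)] = np.sign(slopes)
    return out


def _neg_to_pos_transition(T: np.ndarray, slope: np.ndarray) -> float:
    idx = np.flatnonzero((slope[:-1] < 0) & (slope[1:] >= 0))
    if idx.size == 0:
        raise ValueError("no negative-to-positive slope transition on the grid")
    k = idx[-1]  # the late-repolarization transition
    frac = slope[k] / (slope[k] - slope[k + 1])
    return float(T[k] + frac * (T[k + 1] - T[k]))


def slope_sign_transition(surface: IVTSurface) -> float:
    """AP time T at which the isochronal IV slope at the AP state turns
    from negative back to positive during late repolarization."""
    prof = membrane_resistance(surface)
    return _neg_to_pos_transition(prof.T, prof.slope)


# --------------------------------------------------------------------------
# region segmentation
# --------------------------------------------------------------------------

def segment_regions(surface: IVTSurface, na_eps: float = INA_ABSENT_EPS) -> RegionMap:
    """Segment AP repolarization into regions I-IV from the threshold
    structure of the isochronal curves (conventionally measured on a
    t_vc = 5 ms surface)."""
    ann: dict[float, list] = {}
    has_aonr, has_srr, has_ca, has_na = [], [], [], []
    na_avail, ap_slope_pos = [], []
    for T in surface.T_grid:
        curve = surface.curve_at(float(T))
        eqs = find_equilibria(curve)
        mins = find_srr_minima(curve)
        ann[float(T)] = eqs + mins
        has_aonr.append(any(e.kind == "AONR" for e in eqs))
        has_srr.append(bool(mins))
        has_ca.append(any(e.kind == "Ca_threshold" for e in eqs))
        has_na.append(any(e.kind == "Na_threshold" for e in eqs))
        v_ap = curve.ap_point[0]
        ap_slope_pos.append(_local_slope(curve.V_grid, curve.I_total, v_ap) > 0)
        if "I_Na" in curve.components:
            na_avail.append(bool(curve.components["I_Na"].min() < -na_eps))
        else:
            na_avail.append(False)
    has_aonr, has_srr = np.array(has_aonr), np.array(has_srr)
    has_ca, has_na = np.array(has_ca), np.array(has_na)
    na_avail, ap_slope_pos = np.array(na_avail), np.array(ap_slope_pos)
    T = surface.T_grid
    anomalies: list[str] = []

    def _largest_block(mask):
        best = None
        k = 0
        n_blocks = 0
        while k < len(mask):
            if mask[k]:
                j = k
                while j + 1 < len(mask) and mask[j + 1]:
                    j += 1
                n_blocks += 1
                if best is None or (j - k) > (best[1] - best[0]):
                    best = (k, j)
                k = j + 1
            else:
                k += 1
        return best, n_blocks

    # region I: SRR can still be *induced* -- a threshold or qualifying
    # minimum exists while the AP state itself sits on a positive-slope
    # limb (afterwards repolarization is already self-regenerating)
    region1 = (has_aonr | has_srr) & ap_slope_pos
    b1, n1 = _largest_block(region1)
    if n1 > 1:
        anomalies.append("region I non-contiguous; largest block kept")
    I_end = float(T[b1[1]]) if b1 else float(T[0])

    b3, n3 = _largest_block(has_ca)
    if n3 > 1:
        anomalies.append("region III non-contiguous; largest block kept")
    if b3 is None:
        III_start = III_end = float(T[-1])
    else:
        III_start, III_end = float(T[b3[0]]), float(T[b3[1]])
    II_end = III_start

    idx_na = np.flatnonzero(has_na)
    IV_start = float(T[idx_na[0]]) if idx_na.size else float(T[-1])

    bist = has_ca & na_avail
    bb, _ = _largest_block(bist)
    bistable = (float(T[bb[0]]), float(T[bb[1]])) if bb else None
    for msg in anomalies:
        logger.warning(msg)
    return RegionMap(I_end=I_end, II_end=II_end, III_end=III_end, IV_start=IV_start,
                     bistable_window=bistable, annotations=ann, anomalies=anomalies)


# --------------------------------------------------------------------------
# refractoriness and AP classification
# --------------------------------------------------------------------------

def refractory_window(surface: IVTSurface, eps: float = INA_ABSENT_EPS,
                      eps_mode: str = "absolute"):
    """Maximal T interval with no sodium current available at any clamp
    voltage (max over V of |I_Na| below the floor).

    With ``eps_mode="absolute"`` the floor is ``eps`` in A/F.  Because
    sodium availability recovers exponentially, a strict floor places the
    window end during the low tail of the recovery; ``eps_mode="relative"``
    instead uses ``eps`` as a fraction of the surface's own |I_Na| range
    (the resolution at which a rendered current surface shows "no sodium"),
    which aligns the window end with the refractoriness seen by
    finite-strength stimuli.
    """
    if "I_Na" not in surface.components:
        return (float(surface.T_grid[0]), float(surface.T_grid[-1]))
    avail = np.max(np.abs(surface.components["I_Na"]), axis=1)
    floor = eps if eps_mode == "absolute" else eps * float(avail.max())
    mask = avail < floor
    best = None
    k = 0
    while k < len(mask):
        if mask[k]:
            j = k
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            if best is None or (j - k) > (best[1] - best[0]):
                best = (k, j)
            k = j + 1
        else:
            k += 1
    if best is None:
        return None
    return (float(surface.T_grid[best[0]]), float(surface.T_grid[best[1]]))


def classify_ap_type(
    trajectory: APTrajectory,
    na_dvdt_cut: float = NA_DVDT_CUT,
    active_rate: float = CA_ACTIVE_RATE,
    overshoot: float = CA_OVERSHOOT,
) -> str:
    """Classify the post-stimulus response as ``sodium_driven``,
    ``calcium_driven`` or ``passive``.

    The intrinsic depolarization rate is read as -I_ion (the stimulus
    artifact carries no gating information), so a fast sodium upstroke
    (> 50 mV/ms by default) is distinguished from a slow calcium-driven
    regenerative response (rate above ``active_rate`` with overshoot above
    ``overshoot``) and from passive relaxation.
    """
    s = trajectory.stim
    t0 = s.onset + s.duration + 0.05
    tt = np.arange(t0, trajectory.duration, 0.25)
    Y = trajectory.sol(tt)
    V = Y[0]
    rate = np.array([-trajectory.model.i_ion(Y[:, k]) for k in range(Y.shape[1])])
    if rate.max() > na_dvdt_cut:
        return "sodium_driven"
    if V.max() > overshoot and rate.max() > active_rate:
        return "calcium_driven"
    return "passive"


def membrane_time_constant(
    model: CellModel,
    rest_state: np.ndarray,
    pulse_amplitude: float = -1.0,
    pulse_duration: float = 1.0,
    fit_window: float = 15.0,
) -> float:
    """Passive membrane time constant at rest (ms): single-exponential fit
    of the sub-threshold V_m relaxation after a small brief current pulse."""
    traj = simulate_ap(rest_state, model, StimulusSpec(pulse_amplitude, pulse_duration),
                       duration=pulse_duration + fit_window + 5.0)
    t0 = pulse_duration + 0.02
    tt = np.arange(t0, t0 + fit_window, 0.05)
    V = traj.sol(tt)[0]
    v_rest = float(traj.sol(0.0)[0])

    def _expdec(t, v_inf, amp, tau):
        return v_inf + amp * np.exp(-(t - t0) / tau)

    p0 = (v_rest, float(V[0] - v_rest), 3.0)
    try:
        popt, _ = curve_fit(_expdec, tt, V, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"time-constant fit failed: {exc}") from exc
    tau = float(popt[2])
    if not (0 < tau < 10 * fit_window):
        raise RuntimeError(f"time-constant fit implausible: tau = {tau:.3g} ms")
    return tau
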