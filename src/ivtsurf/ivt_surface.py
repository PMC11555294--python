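"""Quasi-instantaneous IV curves and their time-aligned IVT surface.

At each AP time T the membrane potential is clamped across a voltage grid
for a short time t_vc and the total ionic current (plus every component
current) is read at t = t_vc.  Stacking the curves along T yields the IVT
surface; the AP's own (I, V, T) states lie on it in the small-t_vc limit,
where the gating increment delta-I accumulated during the clamp vanishes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .models.base import CellModel
from .protocols import APTrajectory, clamp_step

logger = logging.getLogger(__name__)

DEFAULT_V_GRID = np.arange(-100.0, 50.0 + 1e-9, 2.0)
DEFAULT_T_STEP = 2.0
DEFAULT_TVC_SURFACE = 1.0   # ms, surface morphology / R_m
DEFAULT_TVC_THRESHOLD = 5.0  # ms, threshold analyses (~ 2x membrane tau)

__all__ = [
    "IVCurve",
    "IVTSurface",
    "measure_iv_curve",
    "build_surface",
    "default_T_grid",
    "project",
    "component_surface",
    "save_surface_h5",
    "load_surface_h5",
    "surface_to_csv",
]


@dataclass
class IVCurve:
    """One isochronal quasi-instantaneous IV curve.

    ``ap_point`` is the (V, I) state of the unperturbed AP at this T;
    ``delta_I`` is the current measured on the curve at the AP's own
    voltage minus the AP's instantaneous current (the gating increment
    accumulated during t_vc).
    """

    T: float
    t_vc: float
    V_grid: np.ndarray
    I_total: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    ap_point: tuple[float, float] | None = None  # (V_ap mV, I_ap A/F)
    delta_I: float | None = None

    def interp(self, v: float) -> float:
        return float(np.interp(v, self.V_grid, self.I_total))

    def component(self, name: str) -> np.ndarray:
        try:
            return self.components[name]
        except KeyError:
            raise KeyError(f"current {name!r} not recorded on this curve") from None


@dataclass
class IVTSurface:
    """Time-aligned stack of isochronal IV curves plus the embedded AP curve."""

    T_grid: np.ndarray
    V_grid: np.ndarray
    t_vc: float
    I: np.ndarray                               # (T x V) total ionic current, A/F
    components: dict[str, np.ndarray]           # each (T x V)
    ap_V: np.ndarray                            # V_ap(T) of the unperturbed AP
    ap_I: np.ndarray                            # I_ion(T) of the unperturbed AP
    metadata: dict = field(default_factory=dict)

    def curve_at(self, T: float) -> IVCurve:
        k = int(np.argmin(np.abs(self.T_grid - T)))
        if abs(self.T_grid[k] - T) > 1e-6:
            logger.debug("curve_at: snapping T=%.3f to grid %.3f", T, self.T_grid[k])
        comps = {n: m[k] for n, m in self.components.items()}
        i_ap = float(self.ap_I[k])
        v_ap = float(self.ap_V[k])
        return IVCurve(
            T=float(self.T_grid[k]), t_vc=self.t_vc, V_grid=self.V_grid,
            I_total=self.I[k], components=comps, ap_point=(v_ap, i_ap),
            delta_I=float(np.interp(v_ap, self.V_grid, self.I[k]) - i_ap),
        )

    @property
    def n_cells(self) -> int:
        return int(self.I.size)


def measure_iv_curve(
    trajectory: APTrajectory,
    T: float,
    t_vc: float,
    V_grid=None,
    record_components: bool = True,
) -> IVCurve:
    """Measure one quasi-instantaneous IV curve at AP time T.

    Every grid voltage is clamped starting from the *identical* snapshot of
    the unperturbed AP at T (dense-output interpolation); the AP's own
    (V, I) state is read from the free-running trajectory.
    """
    V_grid = DEFAULT_V_GRID if V_grid is None else np.asarray(V_grid, dtype=float)
    snap = trajectory.state_at(T)  # raises if T beyond trajectory
    model = trajectory.model
    I = np.empty(V_grid.shape)
    comps = {n: np.empty(V_grid.shape) for n in model.current_names} if record_components else {}
    for k, vc in enumerate(V_grid):
        res = clamp_step(snap, model, vc, t_vc, n_samples=2)
        I[k] = res.breakdown.I_ion
        if record_components:
            for n in model.current_names:
                comps[n][k] = res.breakdown[n]
    v_ap = float(snap[0])
    i_ap = float(model.i_ion(snap))
    return IVCurve(
        T=float(T), t_vc=float(t_vc), V_grid=V_grid, I_total=I, components=comps,
        ap_point=(v_ap, i_ap),
        delta_I=float(np.interp(v_ap, V_grid, I) - i_ap),
    )


def default_T_grid(trajectory: APTrajectory, t_step: float = DEFAULT_T_STEP,
                   margin: float = 50.0) -> np.ndarray:
    """T grid from the upstroke to 99% repolarization plus a margin.

    For a trajectory without an elicited AP (e.g. a resting toy model) the
    grid simply spans the simulated window, capped at 200 ms.
    """
    try:
        t_end = trajectory.repol_time(0.99) + margin
    except ValueError:
        t_end = 200.0
    t_end = min(t_end, trajectory.duration - trajectory.t_upstroke - 1e-6)
    return np.arange(0.0, t_end, t_step)


def build_surface(
    trajectory: APTrajectory,
    T_grid=None,
    t_vc: float = DEFAULT_TVC_SURFACE,
    V_grid=None,
    record_components: bool = True,
    max_missing_frac: float = 0.01,
) -> IVTSurface:
    """Assemble the IVT surface by measuring one IV curve per grid time.

    Deterministic and embarrassingly parallel over (T, V): each clamp
    starts from an independently interpolated snapshot, so results are
    independent of evaluation order.  Cells whose clamp integration fails
    are marked missing (NaN) and logged; more than ``max_missing_frac``
    missing cells is an error.
    """
    V_grid = DEFAULT_V_GRID if V_grid is None else np.asarray(V_grid, dtype=float)
    T_grid = default_T_grid(trajectory) if T_grid is None else np.asarray(T_grid, dtype=float)
    model = trajectory.model
    nT, nV = len(T_grid), len(V_grid)
    I = np.full((nT, nV), np.nan)
    comps = {n: np.full((nT, nV), np.nan) for n in model.current_names} if record_components else {}
    ap_V = np.empty(nT)
    ap_I = np.empty(nT)
    missing = 0
    for it, T in enumerate(T_grid):
        try:
            curve = measure_iv_curve(trajectory, T, t_vc, V_grid, record_components)
        except Exception as exc:  # pragma: no cover - defensive per-cell policy
            logger.warning("IV curve at T=%.1f ms failed: %s", T, exc)
            missing += nV
            ap_V[it] = trajectory.V_at(T)
            ap_I[it] = trajectory.i_ion_at(T)
            continue
        I[it] = curve.I_total
        for n in comps:
            comps[n][it] = curve.components[n]
        ap_V[it], ap_I[it] = curve.ap_point
    if missing > max_missing_frac * nT * nV:
        raise RuntimeError(f"{missing} of {nT * nV} surface cells missing")
    meta = {
        "model": model.name,
        "params": {
            "conductance_scales": dict(model.params.conductance_scales),
            "cell_variant": model.params.cell_variant,
            "C_m_pF": model.params.C_m_pF,
        },
        "t_vc": float(t_vc),
        "T_step": float(T_grid[1] - T_grid[0]) if nT > 1 else None,
        "rtol": 1e-6,
        "atol": 1e-8,
        "stim": {
            "amplitude": trajectory.stim.amplitude,
            "duration": trajectory.stim.duration,
        },
    }
    return IVTSurface(T_grid=T_grid, V_grid=V_grid, t_vc=float(t_vc), I=I,
                      components=comps, ap_V=ap_V, ap_I=ap_I, metadata=meta)


def project(surface: IVTSurface, delta_V: float = 10.0):
    """Project the embedded AP curve onto the three orthogonal planes.

    Returns a dict with the AP waveform ``V(T)``, the phase plot ``I(V)``,
    the current time course ``I_ion(T)``, and offset traces
    ``I(V_ap +/- delta_V, T)`` read off the surface (the response of I_ion
    to quasi-instantaneous symmetric voltage displacements).
    """
    up = np.array([np.interp(v + delta_V, surface.V_grid, row)
                   for v, row in zip(surface.ap_V, surface.I)])
    down = np.array([np.interp(v - delta_V, surface.V_grid, row)
                     for v, row in zip(surface.ap_V, surface.I)])
    return {
        "T": surface.T_grid,
        "V_of_T": surface.ap_V,
        "I_of_V": (surface.ap_V, surface.ap_I),
        "I_of_T": surface.ap_I,
        "I_offset_plus": up,
        "I_offset_minus": down,
        "delta_V": delta_V,
    }


def component_surface(surface: IVTSurface, current_name: str) -> IVTSurface:
    """Restrict the surface to a single membrane current (same grids)."""
    if current_name not in surface.components:
        raise KeyError(
            f"current {current_name!r} not recorded; have {sorted(surface.components)}"
        )
    comp = surface.components[current_name]
    # the AP-curve projection of a component surface is that current's
    # time course along the AP, read off the surface at V_ap(T)
    ap_I = np.array([np.interp(v, surface.V_grid, row)
                     for v, row in zip(surface.ap_V, comp)])
    meta = dict(surface.metadata)
    meta["component"] = current_name
    return IVTSurface(
        T_grid=surface.T_grid, V_grid=surface.V_grid, t_vc=surface.t_vc,
        I=comp, components={current_name: comp}, ap_V=surface.ap_V, ap_I=ap_I,
        metadata=meta,
    )


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_surface_h5(surface: IVTSurface, path) -> None:
    """HDF5 layout: /surface/I, /surface/components/<name>, /grids/{T,V},
    /ap_curve (T, V, I columns), /meta (JSON string)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("surface/I", data=surface.I)
        for n, m in surface.components.items():
            f.create_dataset(f"surface/components/{n}", data=m)
        f.create_dataset("grids/T", data=surface.T_grid)
        f.create_dataset("grids/V", data=surface.V_grid)
        ap = np.column_stack([surface.T_grid, surface.ap_V, surface.ap_I])
        f.create_dataset("ap_curve", data=ap)
        f.create_dataset("meta", data=json.dumps(surface.metadata, sort_keys=True))
        f.attrs["t_vc"] = surface.t_vc


def load_surface_h5(path) -> IVTSurface:
    with h5py.File(path, "r") as f:
        comps = {}
        if "surface/components" in f:
            for n in f["surface/components"]:
                comps[n] = f[f"surface/components/{n}"][...]
        ap = f["ap_curve"][...]
        return IVTSurface(
            T_grid=f["grids/T"][...],
            V_grid=f["grids/V"][...],
            t_vc=float(f.attrs["t_vc"]),
            I=f["surface/I"][...],
            components=comps,
            ap_V=ap[:, 1],
            ap_I=ap[:, 2],
            metadata=json.loads(f["meta"][()]),
        )


def surface_to_csv(surface: IVTSurface, path) -> pd.DataFrame:
    """Long-format export: T_ms, V_mV, current_name, I_AF (12 significant
    digits, byte-stable across identical builds)."""
    rows = {"total": surface.I, **surface.components}
    frames = []
    for name, mat in rows.items():
        T, V = np.meshgrid(surface.T_grid, surface.V_grid, indexing="ij")
        frames.append(pd.DataFrame({
            "T_ms": T.ravel(), "V_mV": V.ravel(),
            "current_name": name, "I_AF": mat.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return df
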