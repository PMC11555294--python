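"""End-to-end pipeline (condition -> AP -> surface -> analysis) and
synthetic test-fixture generation."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .ivt_surface import build_surface, save_surface_h5, surface_to_csv
from .protocols import StimulusSpec, condition, find_threshold_current, simulate_ap
from .surface_analysis import (
    membrane_resistance,
    membrane_time_constant,
    refractory_window,
    segment_regions,
    slope_sign_transition,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_fixtures", "random_cubics"]


def _stim_from_config(cfg: RunConfig) -> StimulusSpec:
    s = cfg.protocol.stimulus
    return StimulusSpec(amplitude=s.amplitude_AF, duration=s.duration_ms, onset=s.onset_ms)


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Condition, simulate one AP, build the IVT surface, analyze, export.

    Artifacts (HDF5 surface, long-format CSV, JSON report) are stamped with
    the config hash and tool version; conditioning is cached in-process so
    re-runs with the same config reuse it.  Returns the report dict.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "version": __version__}
    report: dict = {"stamp": stamp, "stages": {}}
    model = cfg.make_model()
    stim = _stim_from_config(cfg)

    stage = "condition"
    try:
        t0 = time.time()
        rest = condition(model, cfg.protocol.bcl_ms, cfg.protocol.n_beats, stim)
        report["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                   "diastolic_V_mV": float(rest[0])}

        stage = "simulate"
        t0 = time.time()
        traj = simulate_ap(rest, model, stim, duration=cfg.protocol.bcl_ms)
        report["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "APD_ms": traj.APD, "peak_V_mV": traj.peak_V,
            "max_dVdt_mV_per_ms": traj.max_dvdt,
        }

        stage = "surface"
        t0 = time.time()
        g = cfg.grid
        V_grid = np.arange(g.V_min_mV, g.V_max_mV + 1e-9, g.V_step_mV)
        surf = build_surface(traj, t_vc=g.t_vc_ms, V_grid=V_grid)
        save_surface_h5(surf, out / "surface.h5")
        surface_to_csv(surf, out / "surface.csv")
        report["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                   "cells": surf.n_cells}

        stage = "analyze"
        t0 = time.time()
        analysis: dict = {}
        rm = membrane_resistance(surf)
        analysis["sign_windows"] = rm.sign_windows
        try:
            analysis["slope_sign_transition_ms"] = slope_sign_transition(surf)
        except ValueError:
            analysis["slope_sign_transition_ms"] = None
        analysis["refractory_window_ms"] = refractory_window(surf)
        if cfg.model.name == "ord":
            thr = find_threshold_current(rest, model, duration=stim.duration)
            analysis["liminal_current_AF"] = thr
            analysis["tau_m_ms"] = membrane_time_constant(model, rest)
            surf5 = surf if abs(g.t_vc_ms - cfg.analysis.t_vc_thresholds_ms) < 1e-12 \
                else build_surface(traj, t_vc=cfg.analysis.t_vc_thresholds_ms, V_grid=V_grid)
            rmap = segment_regions(surf5, na_eps=cfg.analysis.na_eps_AF)
            analysis["regions_ms"] = {
                "I_end": rmap.I_end, "II_end": rmap.II_end,
                "III_end": rmap.III_end, "IV_start": rmap.IV_start,
                "bistable_window": rmap.bistable_window,
            }
        if cfg.model.scales:
            analysis["condition_label"] = "perturbed"
            analysis["scales"] = dict(cfg.model.scales)
        else:
            analysis["condition_label"] = "control"
        report["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        report["analysis"] = analysis
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    df = pd.DataFrame(dict(zip(("T_ms", "V_mV", "I_ion_AF", "I_C_AF", "I_stim_AF"),
                               traj.sample())))
    df.to_csv(out / "trajectory.csv", index=False, float_format="%.12g")
    return report


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

def random_cubics(seed: int, n: int = 200):
    """N-shaped cubic IV fixtures with recorded roots.

    Each row: scale a > 0 and three distinct roots r1 < r2 < r3 (mV), so
    I(V) = a (V-r1)(V-r2)(V-r3) has a stable/unstable/stable crossing
    triple -- the canonical excitable-membrane IV shape.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        r1 = rng.uniform(-95.0, -75.0)
        r2 = r1 + rng.uniform(5.0, 40.0)
        r3 = r2 + rng.uniform(5.0, 80.0)
        a = 10 ** rng.uniform(-5.0, -3.0)
        rows.append((a, r1, r2, r3))
    return pd.DataFrame(rows, columns=["a", "r1", "r2", "r3"])


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the cubic IV fixtures and a toy-model reference trace as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    cubics = random_cubics(seed)
    p = out / "cubic_iv_fixtures.csv"
    cubics.to_csv(p, index=False, float_format="%.12g")
    paths["cubics"] = p

    # toy ohmic relaxation closed form: V(t) = E + (V0 - E) exp(-t g),
    # g = 0.1 ms^-1, i.e. tau = 10 ms
    E, V0, tau = -85.0, -75.0, 10.0
    t = np.arange(0.0, 50.0, 0.5)
    df = pd.DataFrame({"t_ms": t, "V_mV": E + (V0 - E) * np.exp(-t / tau)})
    p = out / "toy_ohmic_relaxation.csv"
    df.to_csv(p, index=False, float_format="%.12g")
    paths["toy"] = p
    return paths
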