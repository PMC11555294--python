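"""Stiff integration machinery shared by all protocols.

The production solver is LSODA (switching BDF for the stiff phases, the
same family as Matlab's ode15s used in cardiac AP work) at rtol 1e-6 /
atol 1e-8, with dense output retained so any state snapshot can be
interpolated.  Stimulus pulses are handled by splitting the time axis at
their edges, so the solver never has to step over a discontinuous
right-hand side.

A fixed-step explicit reference integrator (forward Euler at micro-second
steps) is provided for solver cross-validation tests only.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-8
METHOD = "LSODA"


class PiecewiseSolution:
    """Dense ODE solution stitched from consecutive solver segments."""

    def __init__(self, sols, breakpoints):
        self._sols = sols
        self._breaks = breakpoints  # segment start times, ascending
        self.t0 = breakpoints[0]
        self.t1 = sols[-1].t[-1]

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(self._sols[0].y), t_arr.size))
        for k, tk in enumerate(t_arr):
            idx = bisect_right(self._breaks, tk) - 1
            idx = min(max(idx, 0), len(self._sols) - 1)
            out[:, k] = self._sols[idx].sol(min(max(tk, self.t0), self.t1))
        if np.isscalar(t) or np.asarray(t).ndim == 0:
            return out[:, 0]
        return out


@dataclass
class Segment:
    t0: float
    t1: float
    i_stim: float = 0.0


def integrate_segments(
    model,
    y0: np.ndarray,
    segments: list[Segment],
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    clamped: bool = False,
) -> PiecewiseSolution:
    """Integrate ``model`` over consecutive segments with piecewise-constant
    stimulus, returning a dense solution over the full span."""
    sols = []
    breaks = []
    y = np.asarray(y0, dtype=float).copy()
    for seg in segments:
        if seg.t1 <= seg.t0:
            continue
        if clamped:
            rhs = model.rhs_clamped
        else:
            stim = seg.i_stim

            def rhs(t, yy, _s=stim):
                return model.rhs(t, yy, _s)

        sol = solve_ivp(
            rhs,
            (seg.t0, seg.t1),
            y,
            method=METHOD,
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            # LSODA occasionally aborts on near-threshold (saddle-passage)
            # trajectories; BDF is slower but robust there
            sol = solve_ivp(rhs, (seg.t0, seg.t1), y, method="BDF",
                            rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"ODE solver failed on [{seg.t0}, {seg.t1}]: {sol.message}")
        sols.append(sol)
        breaks.append(seg.t0)
        y = sol.y[:, -1].copy()
    return PiecewiseSolution(sols, breaks)


def stimulus_segments(duration: float, onset: float, stim_duration: float, amplitude: float):
    """Split [0, duration] at the edges of one rectangular stimulus pulse."""
    segs = []
    t_on = max(onset, 0.0)
    t_off = min(onset + stim_duration, duration)
    if t_on > 0:
        segs.append(Segment(0.0, t_on, 0.0))
    if t_off > t_on:
        segs.append(Segment(t_on, t_off, amplitude))
    if duration > t_off:
        segs.append(Segment(t_off, duration, 0.0))
    return segs


def euler_reference(model, y0, duration, dt=0.001, i_stim_fn=None, sample_every=1000):
    """Fixed-step forward-Euler reference trajectory (cross-check oracle).

    Returns (t_samples, y_samples) with one sample every ``sample_every``
    steps.  Intended for tests only: accuracy comes from the tiny step, not
    from the method.
    """
    n = int(round(duration / dt))
    y = np.asarray(y0, dtype=float).copy()
    ts = [0.0]
    ys = [y.copy()]
    t = 0.0
    for k in range(n):
        stim = 0.0 if i_stim_fn is None else i_stim_fn(t)
        y = y + dt * model.rhs(t, y, stim)
        t = (k + 1) * dt
        if (k + 1) % sample_every == 0:
            ts.append(t)
            ys.append(y.copy())
    return np.array(ts), np.array(ys).T
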