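"""Minimal toy cell model with an analytically known instantaneous IV curve.

Two variants:

``ohmic``
    A single ohmic current ``I = g (V - E)`` (g in mS/uF = 1e3 S/F, E in
    mV).  Closed forms: membrane resistance ``R_m = 1/(g' C_m)`` with
    ``g' = 1000 g`` in S/F, time constant ``tau = R_m C_m = 1/g'``.

``cubic``
    ``I(V) = a (V - r1)(V - r2)(V - r3)`` with known roots, the canonical
    N-shaped instantaneous IV of excitable-membrane theory: r1 stable rest,
    r2 unstable threshold, r3 stable excited state.  The liminal sustained
    current is the local maximum of I on (r1, r2).

Both variants carry one gating variable ``w`` (first-order relaxation to a
voltage-dependent steady state, tau_w = 50 ms) that is deliberately
decoupled from the current, so the measured IV curve equals the analytic
polynomial at every clamp duration t_vc while the state machinery is still
exercised end to end.
"""

from __future__ import annotations

import numpy as np

from .base import CellModel, ModelParams

__all__ = ["ToyModel"]


class ToyModel(CellModel):
    name = "toy"
    state_names = ("v", "w")
    current_names = ("I_toy",)
    gate_names = ("w",)
    concentration_names = ()

    def __init__(
        self,
        params: ModelParams | None = None,
        kind: str = "ohmic",
        g: float = 0.1,
        E: float = -85.0,
        a: float = 1e-4,
        roots: tuple[float, float, float] = (-85.0, -55.0, 30.0),
        tau_w: float = 50.0,
    ):
        super().__init__(params)
        if kind not in ("ohmic", "cubic"):
            raise ValueError(f"unknown toy kind {kind!r}")
        self.kind = kind
        self.g = float(g)
        self.E = float(E)
        self.a = float(a)
        self.roots = tuple(sorted(float(r) for r in roots))
        self.tau_w = float(tau_w)
        self._scale = self.params.scale("I_toy")

    # analytic IV ----------------------------------------------------------
    def iv(self, v):
        """Instantaneous (and exact, at any t_vc) IV curve in A/F."""
        v = np.asarray(v, dtype=float)
        if self.kind == "ohmic":
            out = self.g * (v - self.E)
        else:
            r1, r2, r3 = self.roots
            out = self.a * (v - r1) * (v - r2) * (v - r3)
        return self._scale * out

    def resting_potential(self) -> float:
        return self.E if self.kind == "ohmic" else self.roots[0]

    def liminal_current(self) -> float:
        """Sustained-stimulus excitation threshold |amplitude| in A/F.

        Closed form for the cubic variant: the local maximum of the IV
        polynomial between the resting root and the threshold root.
        """
        if self.kind != "cubic":
            raise ValueError("the ohmic toy has no excitation threshold")
        r1, r2, r3 = self.roots
        # stationary points of the cubic
        b = -(r1 + r2 + r3)
        c = r1 * r2 + r1 * r3 + r2 * r3
        disc = np.sqrt(b * b - 3.0 * c)
        v_crit = (-b + np.array([-disc, disc])) / 3.0
        v_star = v_crit[(v_crit > r1) & (v_crit < r2)][0]
        return float(self.iv(v_star))

    def w_inf(self, v):
        return 1.0 / (1.0 + np.exp(-(v + 60.0) / 10.0))

    # kernels --------------------------------------------------------------
    def rhs(self, t, y, i_stim=0.0):
        v, w = y
        dv = -(float(self.iv(v)) + i_stim)
        dw = (self.w_inf(v) - w) / self.tau_w
        return np.array([dv, dw])

    def rhs_clamped(self, t, y):
        v, w = y
        return np.array([0.0, (self.w_inf(v) - w) / self.tau_w])

    def currents_array(self, y):
        return np.array([float(self.iv(y[0]))])

    def initial_state(self) -> np.ndarray:
        v0 = self.resting_potential()
        return np.array([v0, float(self.w_inf(v0))])
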