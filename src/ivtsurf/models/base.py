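"""Cell-model contract shared by the ventricular and toy models.

A cell model exposes a stiff ODE right-hand side ``rhs(t, y, i_stim)`` over a
flat state vector ``y`` (membrane potential first, in mV), a clamped variant
``rhs_clamped`` in which V_m is held fixed (dV/dt = 0) while every gating and
concentration equation keeps evolving, and a ``currents`` map giving each
membrane current in A/F.  Sign conventions follow standard cellular
electrophysiology: inward (depolarizing, "cathodal") currents are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "StateVector",
    "CurrentBreakdown",
    "CellModel",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters shared by all cell models.

    Parameters
    ----------
    conductance_scales
        Dimensionless multipliers applied to maximum conductances or
        permeabilities, keyed by current name (e.g. ``{"I_Kr": 0.3}`` models
        70% block of the rapid delayed rectifier).  Unspecified currents keep
        scale 1.
    cell_variant
        ``"endo"`` (default), ``"epi"`` or ``"M"``.
    C_m_pF
        Membrane capacitance in pF, used only to convert per-capacitance
        quantities (A/F, S/F) to absolute ones (pA, MOhm, pC).
    """

    conductance_scales: Mapping[str, float] = field(default_factory=dict)
    cell_variant: str = "endo"
    C_m_pF: float = 200.0

    def __post_init__(self) -> None:
        if self.cell_variant not in ("endo", "epi", "M"):
            raise ValueError(f"unknown cell variant: {self.cell_variant!r}")
        if not self.C_m_pF > 0:
            raise ValueError("C_m_pF must be positive")
        for name, scale in self.conductance_scales.items():
            if scale < 0:
                raise ValueError(f"conductance scale for {name} must be >= 0")

    def scale(self, name: str) -> float:
        return float(self.conductance_scales.get(name, 1.0))

    def cache_key(self) -> tuple:
        scales = tuple(sorted((k, float(v)) for k, v in self.conductance_scales.items()))
        return (scales, self.cell_variant, float(self.C_m_pF))

    @property
    def C_m_F(self) -> float:
        return self.C_m_pF * 1e-12


@dataclass
class StateVector:
    """Full model state at one instant.

    ``gates`` collects dimensionless activation/inactivation variables
    (each in [0, 1] up to solver tolerance), ``concentrations`` the
    intracellular/subspace ion concentrations in mM, and ``aux`` any
    remaining state (e.g. SR release fluxes), so that
    ``[V_m, *concentrations, *gates, *aux]`` reassembles the raw vector.
    """

    V_m: float
    gates: np.ndarray
    concentrations: np.ndarray
    aux: np.ndarray
    t: float = 0.0


@dataclass
class CurrentBreakdown:
    """Per-current membrane fluxes in A/F plus their total I_ion."""

    components: dict[str, float]
    I_ion: float

    def __getitem__(self, name: str) -> float:
        try:
            return self.components[name]
        except KeyError:
            raise KeyError(
                f"unknown current {name!r}; available: {sorted(self.components)}"
            ) from None


class CellModel:
    """Base class: subclasses fill in names, initial state and kernels."""

    name: str = "abstract"
    state_names: tuple[str, ...] = ()
    current_names: tuple[str, ...] = ()
    gate_names: tuple[str, ...] = ()
    concentration_names: tuple[str, ...] = ()

    def __init__(self, params: ModelParams | None = None):
        self.params = params or ModelParams()

    # -- kernels -----------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, i_stim: float = 0.0) -> np.ndarray:
        raise NotImplementedError

    def rhs_clamped(self, t: float, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def currents_array(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def initial_state(self) -> np.ndarray:
        raise NotImplementedError

    # -- public surface ----------------------------------------------------
    def derivatives(self, state: np.ndarray, i_stim: float = 0.0, t: float = 0.0) -> np.ndarray:
        """Time derivative of every state variable (per ms), with validation."""
        y = np.asarray(state, dtype=float)
        if y.shape != (self.n_states,):
            raise ValueError(f"state must have shape ({self.n_states},), got {y.shape}")
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            raise ValueError(
                f"non-finite state variable {self.state_names[bad[0]]!r} (index {bad[0]})"
            )
        return self.rhs(t, y, i_stim)

    def currents(self, state: np.ndarray) -> CurrentBreakdown:
        """Every membrane current (A/F) and their sum I_ion at this state."""
        y = np.asarray(state, dtype=float)
        vals = self.currents_array(y)
        comp = dict(zip(self.current_names, (float(v) for v in vals)))
        return CurrentBreakdown(components=comp, I_ion=float(vals.sum()))

    def i_ion(self, state: np.ndarray) -> float:
        return float(self.currents_array(np.asarray(state, dtype=float)).sum())

    def state_vector(self, y: np.ndarray, t: float = 0.0) -> StateVector:
        idx = {n: i for i, n in enumerate(self.state_names)}
        gates = np.array([y[idx[n]] for n in self.gate_names])
        concs = np.array([y[idx[n]] for n in self.concentration_names])
        rest = [
            n
            for n in self.state_names
            if n != "v" and n not in self.gate_names and n not in self.concentration_names
        ]
        aux = np.array([y[idx[n]] for n in rest])
        return StateVector(V_m=float(y[0]), gates=gates, concentrations=concs, aux=aux, t=t)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def cache_key(self) -> tuple:
        return (self.name, self.params.cache_key())
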