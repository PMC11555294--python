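"""O'Hara-Rudy (ORd, 2011) human ventricular cell model, endocardial default.

Thin object-oriented wrapper over the compiled kernel in
:mod:`ivtsurf.models._ord_kernel`.  Conductance scales (e.g. ``I_Kr`` at 0.3
to model 70% hERG block) and the endo/epi/M variant factors are folded into
a parameter vector once, at construction.
"""

from __future__ import annotations

import numpy as np

from . import _ord_kernel as K
from .base import CellModel, ModelParams

__all__ = ["ORdModel"]

# user-facing scale key -> cond-vector slot(s)
_SCALE_SLOTS = {
    "I_Na": (K.IC_GNA,),
    "I_NaL": (K.IC_GNAL,),
    "I_to": (K.IC_GTO,),
    "I_CaL": (K.IC_PCA,),
    "I_Kr": (K.IC_GKR,),
    "I_Ks": (K.IC_GKS,),
    "I_K1": (K.IC_GK1,),
    "I_NaCa": (K.IC_GNCX,),
    "I_NaK": (K.IC_PNAK,),
    "I_Kb": (K.IC_GKB,),
    "I_Nab": (K.IC_PNAB,),
    "I_Cab": (K.IC_PCAB,),
    "I_pCa": (K.IC_GPCA,),
    "J_rel": (K.IC_JRELSC,),
    "J_up": (K.IC_JUPSC,),
}


class ORdModel(CellModel):
    name = "ord"
    state_names = K.STATE_NAMES
    current_names = K.CURRENT_NAMES
    concentration_names = ("nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr")
    gate_names = (
        "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
        "a", "iF", "iS", "ap", "iFp", "iSp",
        "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
        "xrf", "xrs", "xs1", "xs2", "xk1", "CaMKt",
    )

    def __init__(self, params: ModelParams | None = None):
        super().__init__(params)
        cond = K.BASE_COND.copy()
        factors = K.VARIANT_FACTORS[self.params.cell_variant]
        for slot, fac in factors.items():
            if fac is None:  # epi I_to kinetics flag
                cond[K.IC_EPIFLAG] = 1.0
            else:
                cond[slot] *= fac
        if self.params.cell_variant == "epi":
            cond[K.IC_EPIFLAG] = 1.0
        for key, scale in self.params.conductance_scales.items():
            if key not in _SCALE_SLOTS:
                raise KeyError(
                    f"unknown current name {key!r} in conductance_scales; "
                    f"known: {sorted(_SCALE_SLOTS)}"
                )
            for slot in _SCALE_SLOTS[key]:
                cond[slot] *= scale
        self._cond = cond

    # kernels --------------------------------------------------------------
    def rhs(self, t, y, i_stim=0.0):
        dy, _ = K.ord_rhs_currents(t, y, i_stim, self._cond, False)
        return dy

    def rhs_clamped(self, t, y):
        dy, _ = K.ord_rhs_currents(t, y, 0.0, self._cond, True)
        return dy

    def currents_array(self, y):
        _, cur = K.ord_rhs_currents(0.0, y, 0.0, self._cond, False)
        return cur

    def initial_state(self) -> np.ndarray:
        return K.Y0.copy()
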