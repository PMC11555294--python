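from .base import CellModel, CurrentBreakdown, ModelParams, StateVector
from .ord import ORdModel
from .toy import ToyModel

__all__ = [
    "CellModel",
    "CurrentBreakdown",
    "ModelParams",
    "StateVector",
    "ORdModel",
    "ToyModel",
    "make_model",
]


def make_model(name: str = "ord", params: ModelParams | None = None, **kwargs) -> CellModel:
    """Factory used by configs: ``name`` is ``"ord"`` or ``"toy"``."""
    if name == "ord":
        return ORdModel(params)
    if name == "toy":
        return ToyModel(params, **kwargs)
    raise ValueError(f"unknown model {name!r}")
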