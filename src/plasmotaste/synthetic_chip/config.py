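"""YAML configuration for the simulator: response model, noise, seeds, geometry."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .layout import ChipLayout, default_layout
from .response import ResponseModel


@dataclass(frozen=True)
class SimulatorConfig:
    response_model: ResponseModel = field(default_factory=ResponseModel)
    layout: ChipLayout = field(default_factory=default_layout)
    chip_seed: int = 0
    catalog_seed: int = 42
    session_seed: int = 7
    #: sd (nm) of the per-reading wavelength noise used by the fast
    #: (frame-free) session source; calibrated to match the spread the
    #: full render->readout->spline pipeline produces at the default
    #: intensity noise.
    lambda_noise_sd: float = 0.02


def load_config(path: str | Path) -> SimulatorConfig:
    """Load a simulator config from a YAML file; omitted keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    model = ResponseModel(**raw.get("response_model", {}))
    layout_kwargs = raw.get("layout", {})
    layout = default_layout(**layout_kwargs)
    return SimulatorConfig(
        response_model=model,
        layout=layout,
        chip_seed=int(raw.get("chip_seed", 0)),
        catalog_seed=int(raw.get("catalog_seed", 42)),
        session_seed=int(raw.get("session_seed", 7)),
        lambda_noise_sd=float(raw.get("lambda_noise_sd", 0.02)),
    )
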