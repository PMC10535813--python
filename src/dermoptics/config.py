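"""YAML/JSON configuration loading for the optics and model stack."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .pigment_model import ModelConfig
from .spectral_optics import ChromophoreLibrary, ScatteringParams, TissueParams

__all__ = ["PipelineConfig", "load_config", "default_config_dict"]


class PipelineConfig:
    """Bundle of tissue, scattering, LUT-grid and model settings."""

    def __init__(self, tissue=None, scattering=None, grid_sizes=(64, 64),
                 oxygenation_fraction=0.75, model=None):
        self.tissue = tissue or TissueParams()
        self.scattering = scattering or ScatteringParams()
        self.grid_sizes = tuple(grid_sizes)
        self.oxygenation_fraction = oxygenation_fraction
        self.model = model or ModelConfig()

    def chromophore_library(self) -> ChromophoreLibrary:
        return ChromophoreLibrary.default(self.oxygenation_fraction)


def default_config_dict() -> dict:
    cfg = PipelineConfig()
    return {
        "tissue": asdict(cfg.tissue),
        "scattering": asdict(cfg.scattering),
        "grid_sizes": list(cfg.grid_sizes),
        "oxygenation_fraction": cfg.oxygenation_fraction,
        "model": asdict(cfg.model),
    }


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML or JSON config; missing keys take package defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    with open(path) as f:
        raw = json.load(f) if path.suffix == ".json" else yaml.safe_load(f)
    raw = raw or {}
    tissue = raw.get("tissue", {})
    if "melanin_vf_range" in tissue:
        tissue["melanin_vf_range"] = tuple(tissue["melanin_vf_range"])
    if "hemoglobin_vf_range" in tissue:
        tissue["hemoglobin_vf_range"] = tuple(tissue["hemoglobin_vf_range"])
    return PipelineConfig(
        tissue=TissueParams(**tissue),
        scattering=ScatteringParams(**raw.get("scattering", {})),
        grid_sizes=tuple(raw.get("grid_sizes", (64, 64))),
        oxygenation_fraction=raw.get("oxygenation_fraction", 0.75),
        model=ModelConfig(**raw.get("model", {})),
    )
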