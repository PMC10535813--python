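"""Numerically controlled pigment modification.

Skin tone is shifted by adding a constant to every pixel of the melanin
and/or hemoglobin map (normalized units: a delta of -1/+1 spans the full
physiological range), and pigmented-region contrast is changed by scaling
the maps multiplicatively.  Both operations clip to [0, 1] — maps saturate
at the range ends rather than renormalizing, which is what produces the
characteristic flattening at strong negative shifts.  Modified maps are
re-rendered patch-by-patch and blended back into a full sRGB image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .color_pipeline import linear_to_srgb
from .patchwork import PatchGrid
from .pigment_model import decompose_image
from .renderer import PigmentMaps, render
from .spectral_optics import ReflectanceLUT, TissueParams

logger = logging.getLogger(__name__)

__all__ = [
    "ModificationSpec",
    "shift_maps",
    "scale_maps",
    "apply_modification",
    "generate_modified_image",
]


@dataclass(frozen=True)
class ModificationSpec:
    """One pigment modification: additive shift or multiplicative scaling.

    Additive deltas are in normalized map units, conventionally [-1, 1];
    multiplicative factors are positive, conventionally 0.8-1.4 for melanin
    and 0.6-1.4 for hemoglobin.  ``region_mask`` optionally restricts a
    scaling to a region (off by default; whole-map scaling is the standard
    procedure).
    """

    mode: str = "additive"
    delta_melanin: float = 0.0
    delta_hemoglobin: float = 0.0
    factor_melanin: float = 1.0
    factor_hemoglobin: float = 1.0
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError("mode must be 'additive' or 'multiplicative'")
        if self.mode == "multiplicative" and (
            self.factor_melanin <= 0 or self.factor_hemoglobin <= 0
        ):
            raise ValueError("scaling factors must be positive")

    @classmethod
    def identity(cls) -> "ModificationSpec":
        return cls()


def _clip_report(arr: np.ndarray, label: str) -> np.ndarray:
    clipped = np.mean((arr < 0) | (arr > 1))
    if clipped:
        logger.info("%s map: %.2f%% of pixels saturated", label, 100 * clipped)
    return np.clip(arr, 0.0, 1.0)


def shift_maps(maps: PigmentMaps, spec: ModificationSpec) -> PigmentMaps:
    """Additive skin-tone shift; shading is untouched."""
    if spec.mode != "additive":
        raise ValueError("shift_maps requires an additive spec")
    mel = _clip_report(maps.melanin + spec.delta_melanin, "melanin")
    hem = _clip_report(maps.hemoglobin + spec.delta_hemoglobin, "hemoglobin")
    return PigmentMaps(mel, hem, maps.shading.copy())


def scale_maps(maps: PigmentMaps, spec: ModificationSpec) -> PigmentMaps:
    """Multiplicative scaling, whole-map or within ``spec.region_mask``."""
    if spec.mode != "multiplicative":
        raise ValueError("scale_maps requires a multiplicative spec")
    if spec.region_mask is None:
        mel = maps.melanin * spec.factor_melanin
        hem = maps.hemoglobin * spec.factor_hemoglobin
    else:
        m = np.asarray(spec.region_mask, bool)
        mel = np.where(m, maps.melanin * spec.factor_melanin, maps.melanin)
        hem = np.where(m, maps.hemoglobin * spec.factor_hemoglobin, maps.hemoglobin)
    return PigmentMaps(
        _clip_report(mel, "melanin"),
        _clip_report(hem, "hemoglobin"),
        maps.shading.copy(),
    )


def apply_modification(maps: PigmentMaps, spec: ModificationSpec) -> PigmentMaps:
    if spec.mode == "additive":
        return shift_maps(maps, spec)
    return scale_maps(maps, spec)


def generate_modified_image(
    img: np.ndarray,
    mask: np.ndarray,
    model,
    spec: ModificationSpec,
    lut: ReflectanceLUT,
    grid: PatchGrid | None = None,
    tissue: TissueParams | None = None,
) -> np.ndarray:
    """Decompose, modify the maps, re-render and gamma-encode.

    With an identity spec the output is exactly the model's plain
    reconstruction of the input.  Non-skin pixels are black.
    """
    maps = decompose_image(img, mask, model, grid=grid)
    modified = apply_modification(maps, spec)
    linear = render(modified, lut, tissue)
    linear *= np.asarray(mask, bool)[..., None]
    return linear_to_srgb(np.clip(linear, 0.0, 1.0))
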