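"""Pixelwise reconstruction of linear-RGB images from pigment maps.

A pixel's color is the reflectance-LUT entry at its (melanin, hemoglobin)
volume fractions, scaled by its shading value.  The lookup is bilinear, so
the rendered image is piecewise-differentiable in every map value and
gradients propagate back to the maps during self-supervised training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .spectral_optics import ReflectanceLUT, TissueParams

__all__ = ["PigmentMaps", "maps_to_volume_fractions", "render", "mse", "psnr"]


@dataclass
class PigmentMaps:
    """Per-pixel melanin, hemoglobin and shading fields in normalized [0, 1].

    Normalized pigment value v maps affinely onto the physiological
    volume-fraction range: ``vf = lo + v * (hi - lo)``.
    """

    melanin: np.ndarray
    hemoglobin: np.ndarray
    shading: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.melanin, float)
        h = np.asarray(self.hemoglobin, float)
        s = np.asarray(self.shading, float)
        if not (m.shape == h.shape == s.shape):
            raise ValueError("pigment maps must share one shape")
        for name, a in (("melanin", m), ("hemoglobin", h), ("shading", s)):
            if a.min() < -1e-9 or a.max() > 1 + 1e-9:
                warnings.warn(f"{name} map clipped to [0, 1]", stacklevel=2)
        self.melanin = np.clip(m, 0.0, 1.0)
        self.hemoglobin = np.clip(h, 0.0, 1.0)
        self.shading = np.clip(s, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.melanin.shape

    def copy(self) -> "PigmentMaps":
        return PigmentMaps(
            self.melanin.copy(), self.hemoglobin.copy(), self.shading.copy()
        )


def maps_to_volume_fractions(maps: PigmentMaps, t: TissueParams):
    """Affine rescale of normalized maps into volume fractions.

    0 maps to the lower physiological bound, 1 to the upper.
    """
    m_lo, m_hi = t.melanin_vf_range
    h_lo, h_hi = t.hemoglobin_vf_range
    vm = m_lo + maps.melanin * (m_hi - m_lo)
    vh = h_lo + maps.hemoglobin * (h_hi - h_lo)
    return vm, vh


def render(maps: PigmentMaps, lut: ReflectanceLUT,
           tissue: TissueParams | None = None) -> np.ndarray:
    """Render pigment maps to a linear-RGB image via the reflectance LUT.

    Returns an (H, W, 3) array in [0, 1]: bilinear LUT lookup at each
    pixel's volume fractions, times its shading value.
    """
    t = tissue or TissueParams()
    vm, vh = maps_to_volume_fractions(maps, t)
    rgb = lut.lookup(vm, vh)
    return rgb * maps.shading[..., None]


def _masked(img_a, img_b, mask):
    a = np.asarray(img_a, float)
    b = np.asarray(img_b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is None:
        mask = np.ones(a.shape[:2], bool)
    mask = np.asarray(mask, bool)
    if mask.shape != a.shape[: mask.ndim]:
        raise ValueError("mask shape must match image leading dimensions")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return a[mask], b[mask]


def mse(img_a, img_b, mask=None) -> float:
    """Mean squared error over masked pixels (all channels)."""
    a, b = _masked(img_a, img_b, mask)
    return float(np.mean((a - b) ** 2))


def psnr(img_a, img_b, mask=None, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB over masked pixels.

    ``peak`` defaults to 1.0 for normalized intensities.  Identical inputs
    return ``inf``.
    """
    err = mse(img_a, img_b, mask)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / err))
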