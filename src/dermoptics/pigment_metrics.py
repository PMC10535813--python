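"""Skin tone and pigmentation quantification.

Skin tone is summarized by the individual typology angle,

    ITA = arctan((L* - 50) / b*) * 180 / pi   [degrees],

computed from the CIELAB coordinates of the average masked skin color.
Pigmentation is quantified on white-balanced linear RGB (perfect reflector
= 1, so intensities are reflectances) through optical density
OD = -log10(I / I0):

* melanin index        M.I  = OD_R           (red-band absorption,
                                              melanin-dominated);
* erythema index 1     E.I1 = OD_G - OD_R    (Diffey's method);
* erythema index 2     E.I2 = I_B * I_R / I_G (Jacovels' method, which
                                              suppresses melanin's
                                              influence).

Region-versus-surround contrast is the difference of mean index values
between a pigmented region and its surrounding normal skin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .color_pipeline import linear_to_srgb, rgb_to_lab

__all__ = [
    "PigmentIndices",
    "RegionPair",
    "ita",
    "ita_from_lab",
    "optical_density",
    "melanin_index",
    "erythema_diffey",
    "erythema_jacovels",
    "region_contrast",
    "ITA_CATEGORIES",
]

#: Conventional ITA skin-tone bands (degrees, lower bound -> label), exposed
#: for reference only; no computation in this package uses them.
ITA_CATEGORIES = [
    (55.0, "very light"),
    (41.0, "light"),
    (28.0, "intermediate"),
    (10.0, "tan"),
    (-30.0, "brown"),
    (-90.0, "dark"),
]


@dataclass(frozen=True)
class RegionPair:
    """Disjoint masks for a pigmented region and its surrounding skin."""

    region_mask: np.ndarray
    surround_mask: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.region_mask, bool)
        s = np.asarray(self.surround_mask, bool)
        if r.shape != s.shape:
            raise ValueError("masks must share a shape")
        if not r.any() or not s.any():
            raise ValueError("both masks must be nonempty")
        if (r & s).any():
            raise ValueError("region and surround masks must be disjoint")
        object.__setattr__(self, "region_mask", r)
        object.__setattr__(self, "surround_mask", s)


@dataclass(frozen=True)
class PigmentIndices:
    """Region-aggregated pigment indices."""

    ita_deg: float
    mi: float
    ei1: float
    ei2: float


def ita_from_lab(L, b) -> float | np.ndarray:
    """ITA in degrees from CIELAB lightness and b*; L = 50 is the reference.

    Uses the two-argument arctangent so b* = 0 is well defined.
    """
    out = np.degrees(np.arctan2(np.asarray(L, float) - 50.0, np.asarray(b, float)))
    return float(out) if np.ndim(L) == 0 and np.ndim(b) == 0 else out


def ita(img: np.ndarray, mask: np.ndarray | None = None) -> float:
    """ITA of the average masked color of an sRGB image."""
    img = np.asarray(img, float)
    if mask is None:
        mask = np.ones(img.shape[:2], bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    mean_rgb = img[mask].mean(axis=0)
    L, _, b = rgb_to_lab(mean_rgb)
    return ita_from_lab(L, b)


def optical_density(intensity, i0: float = 1.0, od_max: float = 4.0):
    """OD = -log10(I / I0); zero intensities are capped at ``od_max``."""
    if i0 <= 0:
        raise ValueError("reference intensity i0 must be positive")
    x = np.asarray(intensity, float)
    if np.any(x < 0):
        raise ValueError("intensity must be nonnegative")
    zero = x == 0
    if np.any(zero):
        warnings.warn(f"zero intensity capped at OD {od_max:g}", stacklevel=2)
    with np.errstate(divide="ignore"):
        od = -np.log10(np.where(zero, 1.0, x) / i0)
    od = np.where(zero, od_max, np.minimum(od, od_max))
    return float(od) if np.ndim(intensity) == 0 else od


def _channel_stats(img, mask, per_pixel):
    img = np.asarray(img, float)
    if mask is None:
        mask = np.ones(img.shape[:2], bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return img, mask


def melanin_index(img: np.ndarray, mask: np.ndarray | None = None,
                  per_pixel: bool = False):
    """Melanin index: optical density of the red channel.

    ``img`` is white-balanced linear RGB (I0 = 1).  Returns the mask mean,
    or the per-pixel OD map when ``per_pixel`` is true.
    """
    img, mask = _channel_stats(img, mask, per_pixel)
    od_r = optical_density(img[..., 0])
    if per_pixel:
        return np.where(mask, od_r, np.nan)
    return float(od_r[mask].mean())


def erythema_diffey(img: np.ndarray, mask: np.ndarray | None = None,
                    per_pixel: bool = False):
    """Diffey's erythema index: OD_G - OD_R on linear RGB."""
    img, mask = _channel_stats(img, mask, per_pixel)
    ei = optical_density(img[..., 1]) - optical_density(img[..., 0])
    if per_pixel:
        return np.where(mask, ei, np.nan)
    return float(ei[mask].mean())


def erythema_jacovels(img: np.ndarray, mask: np.ndarray | None = None,
                      per_pixel: bool = False):
    """Jacovels' erythema index: I_B * I_R / I_G on linear RGB.

    Pixels with zero green intensity are excluded (with a warning).
    """
    img, mask = _channel_stats(img, mask, per_pixel)
    green = img[..., 1]
    valid = green > 0
    if np.any(mask & ~valid):
        warnings.warn("pixels with zero green intensity excluded", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ei = np.where(valid, img[..., 2] * img[..., 0] / np.where(valid, green, 1.0),
                      np.nan)
    if per_pixel:
        return np.where(mask & valid, ei, np.nan)
    sel = mask & valid
    if not sel.any():
        raise ValueError("no valid pixels for Jacovels' index")
    return float(ei[sel].mean())


def region_contrast(index_map: np.ndarray, pair: RegionPair) -> float:
    """Mean index over the pigmented region minus mean over the surround."""
    idx = np.asarray(index_map, float)
    vals_r = idx[pair.region_mask]
    vals_s = idx[pair.surround_mask]
    vals_r = vals_r[np.isfinite(vals_r)]
    vals_s = vals_s[np.isfinite(vals_s)]
    if vals_r.size == 0 or vals_s.size == 0:
        raise ValueError("region or surround has no finite index values")
    return float(vals_r.mean() - vals_s.mean())


def indices_report(linear_img: np.ndarray, mask: np.ndarray | None = None
                   ) -> PigmentIndices:
    """All four indices of a white-balanced linear-RGB image at once."""
    srgb = linear_to_srgb(np.clip(np.asarray(linear_img, float), 0, 1))
    return PigmentIndices(
        ita_deg=ita(srgb, mask),
        mi=melanin_index(linear_img, mask),
        ei1=erythema_diffey(linear_img, mask),
        ei2=erythema_jacovels(linear_img, mask),
    )
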