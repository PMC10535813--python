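"""Spectral reflectance -> camera RGB -> linear sRGB -> display sRGB.

Image formation follows the physical chain: per channel m,

    I_m = integral L(lambda) R(lambda) M_shading C_m(lambda) d lambda,

followed by white balance (normalization by the sensor's response to the
bare illuminant, so a perfect reflector maps to unit RGB), a camera-RGB ->
XYZ -> linear-sRGB matrix pair, and finally the standard sRGB transfer
function.  The camera->XYZ matrix is fitted at configuration time by least
squares against the CIE 1931 standard observer and the combined matrix is
row-normalized so camera white maps exactly to linear-sRGB white.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab

from .spectra import SpectralCurve, default_wavelengths, load_packaged_curve

logger = logging.getLogger(__name__)

__all__ = [
    "RenderConfig",
    "spectral_to_camera_rgb",
    "white_balance_factors",
    "camera_to_linear_rgb",
    "linear_to_srgb",
    "srgb_to_linear",
    "rgb_to_lab",
    "cie_1931_observer",
    "XYZ_TO_SRGB",
    "SRGB_TO_XYZ",
]

# Standard sRGB (D65) matrices.
XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)
SRGB_TO_XYZ = np.linalg.inv(XYZ_TO_SRGB)


def _lobe(lam, amp, mu, s1, s2):
    # Piecewise Gaussian with separate left/right widths.
    s = np.where(lam < mu, s1, s2)
    return amp * np.exp(-0.5 * ((lam - mu) / s) ** 2)


def cie_1931_observer(lambda_nm) -> np.ndarray:
    """CIE 1931 2-degree color matching functions (analytic multi-lobe fit).

    Returns an array of shape ``lam.shape + (3,)`` with (xbar, ybar, zbar).
    """
    lam = np.asarray(lambda_nm, dtype=float)
    x = (
        _lobe(lam, 1.056, 599.8, 37.9, 31.0)
        + _lobe(lam, 0.362, 442.0, 16.0, 26.7)
        - _lobe(lam, 0.065, 501.1, 20.4, 26.2)
    )
    y = _lobe(lam, 0.821, 568.8, 46.9, 40.5) + _lobe(lam, 0.286, 530.9, 16.3, 31.1)
    z = _lobe(lam, 1.217, 437.0, 11.8, 36.0) + _lobe(lam, 0.681, 459.0, 26.0, 13.8)
    return np.stack([x, y, z], axis=-1)


@dataclass(frozen=True)
class RenderConfig:
    """Illuminant, sensor and color-transform configuration.

    ``cam_rgb_to_xyz`` maps white-balanced camera RGB to XYZ; ``xyz_to_rgb``
    maps XYZ to linear sRGB; ``wb_factors`` holds the per-channel white
    balance gains (the reciprocal sensor response to the bare illuminant).
    """

    illuminant_spd: SpectralCurve
    camera_qe: tuple[SpectralCurve, SpectralCurve, SpectralCurve]
    cam_rgb_to_xyz: np.ndarray
    xyz_to_rgb: np.ndarray
    wb_factors: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.cam_rgb_to_xyz, self.xyz_to_rgb):
            m = np.asarray(m, float)
            if m.shape != (3, 3) or not np.all(np.isfinite(m)):
                raise ValueError("color matrices must be finite 3x3")
            if abs(np.linalg.det(m)) < 1e-12:
                raise ValueError("color matrix is singular")
        wb = np.asarray(self.wb_factors, float)
        if wb.shape != (3,) or np.any(wb <= 0):
            raise ValueError("wb_factors must be a positive triple")
        object.__setattr__(self, "cam_rgb_to_xyz", np.asarray(self.cam_rgb_to_xyz, float))
        object.__setattr__(self, "xyz_to_rgb", np.asarray(self.xyz_to_rgb, float))
        object.__setattr__(self, "wb_factors", wb)

    @property
    def cam_to_linear_rgb_matrix(self) -> np.ndarray:
        """Combined white-preserving matrix from balanced camera RGB to linear sRGB."""
        m = self.xyz_to_rgb @ self.cam_rgb_to_xyz
        white = m @ np.ones(3)
        if np.any(np.abs(white) < 1e-12):
            raise ValueError("camera white maps to a zero channel")
        return m / white[:, None]

    @classmethod
    def default(cls, illuminant: SpectralCurve | None = None,
                camera_qe=None) -> "RenderConfig":
        """Config with the packaged daylight SPD and idealized sensor.

        The camera->XYZ matrix is fitted by least squares of the three QE
        curves against the CIE 1931 observer on the default wavelength grid,
        and white-balance gains are derived from a perfect-reflector render.
        """
        spd = illuminant or load_packaged_curve("illuminant_d65.txt")
        qe = camera_qe or tuple(
            load_packaged_curve(f"qe_{c}.txt") for c in ("red", "green", "blue")
        )
        lam = default_wavelengths()
        responses = np.stack([c.resample(lam).values for c in qe], axis=1)  # (L, 3)
        targets = cie_1931_observer(lam)  # (L, 3)
        fit, *_ = np.linalg.lstsq(responses, targets, rcond=None)
        cam_to_xyz = fit.T
        cfg = cls(spd, tuple(qe), cam_to_xyz, XYZ_TO_SRGB, np.ones(3))
        wb = white_balance_factors(cfg)
        return cls(spd, tuple(qe), cam_to_xyz, XYZ_TO_SRGB, wb)


def spectral_to_camera_rgb(reflectance: SpectralCurve, shading: float,
                           cfg: RenderConfig) -> np.ndarray:
    """Camera RGB of a reflectance spectrum under the configured conditions.

    Trapezoidal integration of L(lambda) R(lambda) M_shading C_m(lambda) on
    the default wavelength grid; linear in shading.  Integrals are normalized
    by the band width so values stay O(1).
    """
    if shading < 0:
        raise ValueError("shading must be nonnegative")
    lam = default_wavelengths()
    refl = reflectance.resample(lam).values
    spd = cfg.illuminant_spd.resample(lam).values
    out = np.empty(3)
    norm = lam[-1] - lam[0]
    for m, qe in enumerate(cfg.camera_qe):
        integrand = spd * refl * qe.resample(lam).values
        out[m] = np.trapezoid(integrand, lam) / norm
    return out * float(shading)


def white_balance_factors(cfg: RenderConfig) -> np.ndarray:
    """Reciprocal of the sensor response to the bare illuminant.

    Applying these gains to the render of a perfect reflector (R = 1,
    shading = 1) yields exactly (1, 1, 1).
    """
    lam = default_wavelengths()
    white = spectral_to_camera_rgb(
        SpectralCurve(lam, np.ones_like(lam)), 1.0, cfg
    )
    if np.any(white <= 0):
        raise ValueError("sensor has zero response to the illuminant in a channel")
    return 1.0 / white


def camera_to_linear_rgb(cam_rgb: np.ndarray, cfg: RenderConfig,
                         clip: bool = True) -> np.ndarray:
    """White balance + matrix chain from camera RGB to linear sRGB.

    Works on a triple or an (..., 3) array.  Out-of-gamut values are clipped
    to [0, 1]; the clipped fraction is logged at debug level.
    """
    cam = np.asarray(cam_rgb, dtype=float)
    balanced = cam * cfg.wb_factors
    rgb = balanced @ cfg.cam_to_linear_rgb_matrix.T
    if clip:
        out_of_gamut = np.mean((rgb < 0) | (rgb > 1))
        if out_of_gamut:
            logger.debug("clipped %.3f%% of values to [0, 1]", 100 * out_of_gamut)
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


_SRGB_A = 0.055
_LIN_THRESH = 0.0031308
_SRGB_THRESH = 0.04045


def linear_to_srgb(linear):
    """Standard sRGB transfer function (gamma encoding) on [0, 1] values."""
    x = np.asarray(linear, dtype=float)
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("linear values must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    out = np.where(
        x <= _LIN_THRESH,
        12.92 * x,
        (1 + _SRGB_A) * np.power(np.maximum(x, _LIN_THRESH), 1 / 2.4) - _SRGB_A,
    )
    return float(out) if np.ndim(linear) == 0 else out


def srgb_to_linear(srgb):
    """Inverse sRGB transfer function (inverse gamma) on [0, 1] values."""
    x = np.asarray(srgb, dtype=float)
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("sRGB values must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    out = np.where(
        x <= _SRGB_THRESH,
        x / 12.92,
        np.power((x + _SRGB_A) / (1 + _SRGB_A), 2.4),
    )
    return float(out) if np.ndim(srgb) == 0 else out


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB (gamma-encoded, [0, 1]) to CIE L*a*b* under D65.

    Accepts a triple or an (..., 3) image; L is in [0, 100].
    """
    arr = np.asarray(rgb, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, None, :]
    elif arr.ndim == 2:
        arr = arr[None, :, :]
    lab = rgb2lab(arr)
    return lab[0, 0] if squeeze else np.squeeze(lab, axis=0) if rgb.ndim == 2 else lab
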