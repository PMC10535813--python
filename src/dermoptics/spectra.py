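"""Sampled spectral curves on the visible working band.

All spectral quantities in this package (chromophore extinction, illuminant
power, sensor quantum efficiency, reflectance) live on a common band of
450-750 nm and are represented as :class:`SpectralCurve` objects: a strictly
increasing wavelength axis with one nonnegative value per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Working band limits in nm.
LAMBDA_MIN = 450.0
LAMBDA_MAX = 750.0

#: Default sampling step in nm.
LAMBDA_STEP = 5.0


def default_wavelengths(step_nm: float = LAMBDA_STEP) -> np.ndarray:
    """Uniform wavelength axis over the working band (inclusive ends)."""
    n = int(round((LAMBDA_MAX - LAMBDA_MIN) / step_nm)) + 1
    return np.linspace(LAMBDA_MIN, LAMBDA_MAX, n)


@dataclass(frozen=True)
class SpectralCurve:
    """A sampled function of wavelength.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm, within [450, 750].
    values
        Nonnegative, finite samples, same length as ``wavelengths_nm``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("a spectral curve needs at least two samples")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v >= 0)):
            raise ValueError("values must be finite and nonnegative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    def __call__(self, lambda_nm) -> np.ndarray | float:
        """Linear interpolation at ``lambda_nm`` (scalar or array).

        Raises a ``ValueError`` for wavelengths outside the curve support.
        """
        lam = np.asarray(lambda_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside curve support [{lo:g}, {hi:g}] nm"
            )
        out = np.interp(lam, self.wavelengths_nm, self.values)
        return float(out) if np.isscalar(lambda_nm) else out

    def resample(self, wavelengths_nm: np.ndarray) -> "SpectralCurve":
        """Resample onto a new axis; warns when extrapolating at the ends."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if lam[0] < lo or lam[-1] > hi:
            warnings.warn(
                "resampling extrapolates beyond curve support; "
                "end values are held constant",
                stacklevel=2,
            )
        vals = np.interp(lam, self.wavelengths_nm, self.values)
        return SpectralCurve(lam, vals)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpectralCurve":
        """Load a two-column text file (wavelength_nm, value; '#' comments)."""
        arr = np.loadtxt(path, comments="#")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns")
        return cls(arr[:, 0], arr[:, 1])


def data_path(name: str) -> Path:
    """Path of a spectral data file shipped with the package."""
    return Path(__file__).parent / "data" / name


def load_packaged_curve(name: str) -> SpectralCurve:
    return SpectralCurve.from_file(data_path(name))
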