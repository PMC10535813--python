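"""Two-layer Kubelka-Munk skin reflectance model.

The skin is modelled as a thin, melanin-bearing epidermis over a
semi-infinite, hemoglobin-bearing dermis:

* absorption is linear in chromophore volume fractions,
  ``mu_a(lambda) = vm * eps_mel(lambda) + vh * eps_hb(lambda)``;
* reduced scattering mixes a Rayleigh (lambda^-4) and a Mie (lambda^-b)
  power law;
* the epidermis transmits by Beer-Lambert attenuation over its thickness,
  and the dermis reflects with the semi-infinite Kubelka-Munk solution
  ``R_inf = 1 + K/S - sqrt((K/S)^2 + 2 K/S)`` using the ``K = 2 mu_a``
  two-flux convention and ``S = mu_s'``;
* total diffuse reflectance is ``T_epidermis^2 * R_dermis``.

Volume fractions cover the physiological ranges 1.3-43 % (melanin) and
2-7 % (hemoglobin).  :func:`build_reflectance_lut` bakes the full spectral
pipeline (including illuminant, sensor and color transforms) into a dense
(vm, vh) -> linear-RGB table that the differentiable renderer interpolates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    LAMBDA_MAX,
    LAMBDA_MIN,
    SpectralCurve,
    default_wavelengths,
    load_packaged_curve,
)

__all__ = [
    "ChromophoreLibrary",
    "ScatteringParams",
    "TissueParams",
    "ReflectanceLUT",
    "absorption_coefficient",
    "reduced_scattering",
    "epidermis_transmittance",
    "dermis_reflectance",
    "skin_reflectance",
    "build_reflectance_lut",
]


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Effective extinction spectra of the two dominant skin chromophores.

    Extinctions are in 1/mm per unit volume fraction; concentration is folded
    into the curves, so absorption is simply ``volume_fraction * extinction``.
    The hemoglobin curve is a fixed oxy/deoxy mix.
    """

    melanin_extinction: SpectralCurve
    hemoglobin_extinction: SpectralCurve
    oxygenation_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.oxygenation_fraction <= 1.0:
            raise ValueError("oxygenation_fraction must lie in [0, 1]")
        for curve in (self.melanin_extinction, self.hemoglobin_extinction):
            if np.any(curve.values <= 0):
                raise ValueError("extinction must be positive across the band")

    @classmethod
    def default(cls, oxygenation_fraction: float = 0.75) -> "ChromophoreLibrary":
        """Library built from the packaged spectra at the given oxygenation."""
        mel = load_packaged_curve("melanin_extinction.txt")
        oxy = load_packaged_curve("hemoglobin_oxy.txt")
        deoxy = load_packaged_curve("hemoglobin_deoxy.txt")
        f = float(oxygenation_fraction)
        hb = SpectralCurve(
            oxy.wavelengths_nm,
            f * oxy.values + (1.0 - f) * deoxy.resample(oxy.wavelengths_nm).values,
        )
        return cls(mel, hb, f)


@dataclass(frozen=True)
class ScatteringParams:
    """Reduced-scattering power-law parameters (Rayleigh + Mie mix)."""

    amplitude_a: float = 3.0  # mu_s' at lambda0, 1/mm
    power_b: float = 1.3  # Mie scattering power
    f_rayleigh: float = 0.4  # fraction of Rayleigh events
    lambda0_nm: float = 500.0  # reference wavelength

    def __post_init__(self) -> None:
        if self.amplitude_a <= 0 or self.power_b <= 0 or self.lambda0_nm <= 0:
            raise ValueError("amplitude, power and lambda0 must be positive")
        if not 0.0 <= self.f_rayleigh <= 1.0:
            raise ValueError("f_rayleigh must lie in [0, 1]")


@dataclass(frozen=True)
class TissueParams:
    """Layer geometry and physiological volume-fraction ranges.

    Besides melanin, the epidermis carries a pigment-independent baseline
    absorber concentrated at short wavelengths (carotenoids and other minor
    chromophores), modelled as ``k * exp(-(lambda - 450) / decay)``.  It
    gives minimally pigmented skin its residual warm tint and leaves the
    melanin/hemoglobin dependence untouched.
    """

    melanin_vf_range: tuple[float, float] = (0.013, 0.43)
    hemoglobin_vf_range: tuple[float, float] = (0.02, 0.07)
    epidermis_thickness_mm: float = 0.06
    baseline_absorption_mm: float = 0.0  # flat pigment-independent mu_a, both layers
    baseline_blue_mm: float = 6.0  # epidermal short-wavelength baseline peak (1/mm)
    baseline_blue_decay_nm: float = 30.0
    dermis_semi_infinite: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.melanin_vf_range, self.hemoglobin_vf_range):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("volume-fraction ranges must satisfy 0 <= lo < hi <= 1")
        if self.epidermis_thickness_mm <= 0:
            raise ValueError("epidermis thickness must be positive")
        if self.baseline_absorption_mm < 0 or self.baseline_blue_mm < 0:
            raise ValueError("baseline absorption must be nonnegative")
        if self.baseline_blue_decay_nm <= 0:
            raise ValueError("baseline decay must be positive")

    def epidermal_baseline(self, lambda_nm):
        """Pigment-independent epidermal absorption (1/mm) at ``lambda_nm``."""
        lam = np.asarray(lambda_nm, dtype=float)
        return self.baseline_absorption_mm + self.baseline_blue_mm * np.exp(
            -(lam - LAMBDA_MIN) / self.baseline_blue_decay_nm
        )


def _check_band(lambda_nm) -> np.ndarray:
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam < LAMBDA_MIN) or np.any(lam > LAMBDA_MAX):
        raise ValueError(f"wavelength outside [{LAMBDA_MIN:g}, {LAMBDA_MAX:g}] nm")
    return lam


def absorption_coefficient(lambda_nm, vm, vh, lib: ChromophoreLibrary):
    """Absorption coefficient (1/mm): ``vm*eps_mel + vh*eps_hb``.

    Linear in each volume fraction; broadcasts over wavelength and fractions.
    """
    lam = _check_band(lambda_nm)
    vm = np.asarray(vm, dtype=float)
    vh = np.asarray(vh, dtype=float)
    if np.any(vm < 0) or np.any(vh < 0):
        raise ValueError("volume fractions must be nonnegative")
    out = vm * lib.melanin_extinction(lam) + vh * lib.hemoglobin_extinction(lam)
    return float(out) if np.ndim(out) == 0 else out


def reduced_scattering(lambda_nm, p: ScatteringParams):
    """Reduced scattering coefficient (1/mm), Rayleigh/Mie power-law mix."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    x = lam / p.lambda0_nm
    out = p.amplitude_a * (
        p.f_rayleigh * x**-4.0 + (1.0 - p.f_rayleigh) * x ** (-p.power_b)
    )
    return float(out) if np.ndim(out) == 0 else out


def _clip_vf(v, rng: tuple[float, float], label: str):
    v = np.asarray(v, dtype=float)
    if np.any(v < rng[0]) or np.any(v > rng[1]):
        warnings.warn(
            f"{label} volume fraction clipped to [{rng[0]:g}, {rng[1]:g}]",
            stacklevel=3,
        )
        v = np.clip(v, rng[0], rng[1])
    return v


def epidermis_transmittance(lambda_nm, vm, t: TissueParams, lib: ChromophoreLibrary,
                            clip: bool = True):
    """One-pass Beer-Lambert transmission through the epidermis.

    Melanin plus the configured pigment-independent baseline absorb.
    """
    lam = _check_band(lambda_nm)
    if clip:
        vm = _clip_vf(vm, t.melanin_vf_range, "melanin")
    else:
        vm = np.asarray(vm, dtype=float)
    mu_a = vm * lib.melanin_extinction(lam) + t.epidermal_baseline(lam)
    out = np.exp(-mu_a * t.epidermis_thickness_mm)
    return float(out) if np.ndim(out) == 0 else out


def km_reflectance_semi_infinite(k_over_s):
    """Semi-infinite Kubelka-Munk reflectance ``R_inf`` for given K/S >= 0."""
    r = np.asarray(k_over_s, dtype=float)
    if np.any(r < 0):
        raise ValueError("K/S must be nonnegative")
    out = 1.0 + r - np.sqrt(r * r + 2.0 * r)
    return float(out) if np.ndim(out) == 0 else out


def dermis_reflectance(lambda_nm, vh, t: TissueParams, s: ScatteringParams,
                       lib: ChromophoreLibrary, clip: bool = True):
    """Semi-infinite Kubelka-Munk dermis reflectance.

    K follows the two-flux convention K = 2*mu_a; S is the reduced
    scattering coefficient.
    """
    lam = _check_band(lambda_nm)
    if clip:
        vh = _clip_vf(vh, t.hemoglobin_vf_range, "hemoglobin")
    else:
        vh = np.asarray(vh, dtype=float)
    mu_a = vh * lib.hemoglobin_extinction(lam) + t.baseline_absorption_mm
    mu_s = reduced_scattering(lam, s)
    if np.any(np.asarray(mu_s) <= 0):
        raise ValueError("Kubelka-Munk model undefined for zero scattering")
    return km_reflectance_semi_infinite(2.0 * mu_a / mu_s)


def skin_reflectance(lambda_nm, vm, vh, t: TissueParams, s: ScatteringParams,
                     lib: ChromophoreLibrary, clip: bool = True):
    """Total diffuse skin reflectance ``T_epidermis^2 * R_dermis`` in [0, 1]."""
    te = epidermis_transmittance(lambda_nm, vm, t, lib, clip=clip)
    rd = dermis_reflectance(lambda_nm, vh, t, s, lib, clip=clip)
    return te * te * rd


def reflectance_spectrum(vm: float, vh: float, t: TissueParams,
                         s: ScatteringParams, lib: ChromophoreLibrary,
                         wavelengths_nm: np.ndarray | None = None) -> SpectralCurve:
    """Reflectance sampled on a wavelength axis (default 5-nm grid)."""
    lam = default_wavelengths() if wavelengths_nm is None else np.asarray(wavelengths_nm)
    return SpectralCurve(lam, skin_reflectance(lam, vm, vh, t, s, lib))


@dataclass(frozen=True)
class ReflectanceLUT:
    """Dense (vm, vh) -> white-balanced linear-RGB reflectance table.

    ``rgb_table[i, j]`` holds the full spectral pipeline (reflectance model,
    illuminant, sensor integration, white balance and color matrices; no
    shading, no gamma) evaluated at ``(vm_grid[i], vh_grid[j])``.  Lookups
    bilinearly interpolate; queries outside the grid are clamped to it.
    """

    vm_grid: np.ndarray
    vh_grid: np.ndarray
    rgb_table: np.ndarray  # (len(vm_grid), len(vh_grid), 3)

    def __post_init__(self) -> None:
        vm = np.asarray(self.vm_grid, float)
        vh = np.asarray(self.vh_grid, float)
        tab = np.asarray(self.rgb_table, float)
        if vm.size < 2 or vh.size < 2:
            raise ValueError("LUT grids need at least two nodes per axis")
        if not (np.all(np.diff(vm) > 0) and np.all(np.diff(vh) > 0)):
            raise ValueError("LUT grids must be strictly increasing")
        if tab.shape != (vm.size, vh.size, 3):
            raise ValueError("rgb_table shape must be (len(vm), len(vh), 3)")
        if tab.min() < 0 or tab.max() > 1:
            raise ValueError("rgb_table entries must lie in [0, 1]")
        object.__setattr__(self, "vm_grid", vm)
        object.__setattr__(self, "vh_grid", vh)
        object.__setattr__(self, "rgb_table", tab)

    def _locate(self, v: np.ndarray, grid: np.ndarray):
        v = np.clip(v, grid[0], grid[-1])
        idx = np.clip(np.searchsorted(grid, v, side="right") - 1, 0, grid.size - 2)
        frac = (v - grid[idx]) / (grid[idx + 1] - grid[idx])
        return idx, frac

    def lookup(self, vm, vh) -> np.ndarray:
        """Bilinear interpolation; returns RGB with shape ``vm.shape + (3,)``."""
        rgb, _, _ = self.lookup_with_grad(vm, vh)
        return rgb

    def lookup_with_grad(self, vm, vh):
        """Interpolated RGB plus its partial derivatives w.r.t. vm and vh."""
        vm = np.asarray(vm, float)
        vh = np.asarray(vh, float)
        i, fi = self._locate(vm, self.vm_grid)
        j, fj = self._locate(vh, self.vh_grid)
        t = self.rgb_table
        c00, c01 = t[i, j], t[i, j + 1]
        c10, c11 = t[i + 1, j], t[i + 1, j + 1]
        fi = fi[..., None]
        fj = fj[..., None]
        low = c00 * (1 - fj) + c01 * fj
        high = c10 * (1 - fj) + c11 * fj
        rgb = low * (1 - fi) + high * fi
        dvm = (high - low) / (self.vm_grid[i + 1] - self.vm_grid[i])[..., None]
        d_low = (c01 - c00) / (self.vh_grid[j + 1] - self.vh_grid[j])[..., None]
        d_high = (c11 - c10) / (self.vh_grid[j + 1] - self.vh_grid[j])[..., None]
        dvh = d_low * (1 - fi) + d_high * fi
        return rgb, dvm, dvh


def build_reflectance_lut(t: TissueParams, s: ScatteringParams,
                          lib: ChromophoreLibrary, render_cfg,
                          grid_sizes: tuple[int, int] = (64, 64)) -> ReflectanceLUT:
    """Precompute the (vm, vh) -> white-balanced linear-RGB table.

    Every node runs the full spectral pipeline: two-layer reflectance,
    illuminant/sensor integration, white balance and the camera-to-sRGB
    matrix (clipped to [0, 1]).  Nodes span the declared physiological
    volume-fraction ranges on uniform grids.
    """
    from .color_pipeline import camera_to_linear_rgb, spectral_to_camera_rgb

    n_m, n_h = grid_sizes
    if n_m < 2 or n_h < 2:
        raise ValueError("grid_sizes must be at least 2 per axis")
    vm_grid = np.linspace(*t.melanin_vf_range, n_m)
    vh_grid = np.linspace(*t.hemoglobin_vf_range, n_h)
    lam = default_wavelengths()
    # Spectral separability: R(lambda) = Tepi(lambda; vm)^2 * Rderm(lambda; vh),
    # so the (n_m*n_h) spectra factor into an outer product of two small sets.
    te2 = np.stack(
        [epidermis_transmittance(lam, vm, t, lib) ** 2 for vm in vm_grid]
    )  # (n_m, L)
    rd = np.stack([dermis_reflectance(lam, vh, t, s, lib) for vh in vh_grid])
    table = np.empty((n_m, n_h, 3))
    for i in range(n_m):
        for j in range(n_h):
            refl = SpectralCurve(lam, te2[i] * rd[j])
            cam = spectral_to_camera_rgb(refl, 1.0, render_cfg)
            table[i, j] = camera_to_linear_rgb(cam, render_cfg)
    return ReflectanceLUT(vm_grid, vh_grid, np.clip(table, 0.0, 1.0))
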