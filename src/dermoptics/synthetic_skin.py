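"""Synthetic cross-polarized skin image generator with ground truth.

Stands in for clinical data: each subject is a set of smooth random pigment
fields (Gaussian-filtered white noise around a per-subject base level),
optional localized hyperpigmented blobs with raised-cosine profiles, and a
low-frequency multiplicative shading field, rendered to sRGB through the
same forward model the decomposition network inverts.  Every draw is
deterministic under the subject seed, and generated volume fractions stay
inside the physiological ranges by construction.

Default base-level distributions are chosen so rendered subjects span the
light-to-tan skin tone range (mean ITA values concentrated around 20-40
degrees) with melanin carrying more map weight than hemoglobin, mirroring
the population structure the modification experiments assume.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .color_pipeline import linear_to_srgb
from .pigment_metrics import RegionPair
from .renderer import PigmentMaps, render
from .spectral_optics import ReflectanceLUT, TissueParams

__all__ = [
    "SubjectSpec",
    "generate_pigment_fields",
    "add_pigmented_region",
    "generate_subject",
    "make_subjects",
    "sample_subject_spec",
    "generate_dataset",
]


@dataclass(frozen=True)
class SubjectSpec:
    """Parameters of one synthetic subject.

    Pigment values are normalized map units in [0, 1]; ``field_smoothness``
    is the spatial correlation length in pixels (distance at which the field
    autocorrelation falls to 1/e).  Blob radii are in pixels and blob gains
    in normalized map units.  ``seed`` fixes every random draw.
    """

    base_melanin: float = 0.08
    base_hemoglobin: float = 0.40
    field_smoothness: float = 8.0
    noise_amplitude: float = 0.05
    n_blobs: int = 1
    blob_radius_px: tuple[float, float] = (20.0, 28.0)
    blob_gain: tuple[float, float] = (0.10, 0.25)
    blob_pigment: str = "melanin"
    shading_range: tuple[float, float] = (0.6, 1.0)
    shading_smoothness: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.base_melanin <= 1 and 0 <= self.base_hemoglobin <= 1):
            raise ValueError("base levels must lie in [0, 1]")
        if self.blob_pigment not in ("melanin", "hemoglobin", "both"):
            raise ValueError("blob_pigment must be melanin, hemoglobin or both")
        for lo, hi in (self.blob_radius_px, self.blob_gain, self.shading_range):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")


def _smooth_field(rng, shape, correlation_length):
    # Gaussian-filtered white noise; filter sigma = L/2 gives autocorrelation
    # exp(-r^2 / (4 sigma^2)), i.e. 1/e at r = L.  Renormalized to unit std.
    sigma = max(correlation_length / 2.0, 1e-6)
    g = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    std = g.std()
    return g / std if std > 0 else g


def generate_pigment_fields(spec: SubjectSpec, shape: tuple[int, int]) -> PigmentMaps:
    """Smooth random melanin/hemoglobin/shading fields for one subject.

    Pigment fields fluctuate around the base levels with ``noise_amplitude``
    standard deviation and are clipped to [0, 1]; shading is a slower field
    confined to ``shading_range``.
    """
    rng = np.random.default_rng(spec.seed)
    mel = spec.base_melanin + spec.noise_amplitude * _smooth_field(
        rng, shape, spec.field_smoothness
    )
    hem = spec.base_hemoglobin + spec.noise_amplitude * _smooth_field(
        rng, shape, spec.field_smoothness
    )
    lo, hi = spec.shading_range
    sh = _smooth_field(rng, shape, spec.shading_smoothness)
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    sha = mid + half * np.tanh(sh / 1.5)
    return PigmentMaps(
        np.clip(mel, 0.0, 1.0), np.clip(hem, 0.0, 1.0), np.clip(sha, lo, hi)
    )


def _raised_cosine(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r = np.hypot(yy - center[0], xx - center[1]) / radius
    return np.where(r < 1.0, 0.5 * (1.0 + np.cos(np.pi * np.minimum(r, 1.0))), 0.0)


def add_pigmented_region(
    maps: PigmentMaps, spec: SubjectSpec, max_retries: int = 50
) -> tuple[PigmentMaps, RegionPair]:
    """Add smooth-edged hyperpigmented blobs and return region/surround masks.

    Blobs are raised-cosine bumps added to the targeted pigment map(s).  The
    region mask covers the blob cores (r <= R/2, where the profile is at
    least half its peak); the surround is an annulus at 1.2-1.6 R where the
    profile is identically zero, so the blob mean strictly exceeds the
    surround mean whenever the gain is positive.
    """
    rng = np.random.default_rng(spec.seed + 1)
    h, w = maps.shape
    mel = maps.melanin.copy()
    hem = maps.hemoglobin.copy()
    region = np.zeros((h, w), bool)
    surround = np.zeros((h, w), bool)
    for _ in range(spec.n_blobs):
        radius = rng.uniform(*spec.blob_radius_px)
        gain = rng.uniform(*spec.blob_gain)
        placed = False
        for _ in range(max_retries):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            if (
                cy - 1.6 * radius >= 0
                and cy + 1.6 * radius < h
                and cx - 1.6 * radius >= 0
                and cx + 1.6 * radius < w
            ):
                placed = True
                break
        if not placed:
            raise ValueError("could not place blob inside the image")
        profile = gain * _raised_cosine((h, w), (cy, cx), radius)
        if spec.blob_pigment in ("melanin", "both"):
            mel = mel + profile
        if spec.blob_pigment in ("hemoglobin", "both"):
            hem = hem + profile
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - cy, xx - cx)
        region |= r <= 0.5 * radius
        surround |= (r >= 1.2 * radius) & (r <= 1.6 * radius)
    surround &= ~region
    return (
        PigmentMaps(np.clip(mel, 0, 1), np.clip(hem, 0, 1), maps.shading.copy()),
        RegionPair(region, surround),
    )


def sample_subject_spec(rng: np.random.Generator, **overrides) -> SubjectSpec:
    """Random subject: base levels drawn over the population tone range."""
    params = dict(
        base_melanin=float(rng.uniform(0.02, 0.10)),
        base_hemoglobin=float(rng.uniform(0.30, 0.60)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return SubjectSpec(**params)


def generate_subject(
    spec: SubjectSpec,
    shape: tuple[int, int],
    lut: ReflectanceLUT,
    tissue: TissueParams | None = None,
    with_region: bool = True,
) -> dict:
    """Maps -> render -> gamma for one subject.

    Returns a dict with the sRGB image, the linear render, the ground-truth
    maps, an all-skin mask, and (optionally) the blob region pair.
    """
    maps = generate_pigment_fields(spec, shape)
    pair = None
    if with_region and spec.n_blobs > 0:
        maps, pair = add_pigmented_region(maps, spec)
    linear = render(maps, lut, tissue)
    srgb = linear_to_srgb(np.clip(linear, 0.0, 1.0))
    return {
        "spec": spec,
        "maps": maps,
        "linear": linear,
        "image": srgb,
        "mask": np.ones(shape, bool),
        "region_pair": pair,
    }


def make_subjects(
    n: int,
    lut: ReflectanceLUT,
    shape: tuple[int, int] = (78, 78),
    master_seed: int = 0,
    tissue: TissueParams | None = None,
    with_region: bool = False,
    **spec_overrides,
) -> list[dict]:
    """Generate ``n`` subjects with specs drawn under one master seed."""
    rng = np.random.default_rng(master_seed)
    out = []
    for _ in range(n):
        spec = sample_subject_spec(rng, **spec_overrides)
        out.append(generate_subject(spec, shape, lut, tissue, with_region))
    return out


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def generate_dataset(
    n_subjects: int,
    lut: ReflectanceLUT,
    out_dir: str | Path,
    shape: tuple[int, int] = (256, 256),
    master_seed: int = 0,
    tissue: TissueParams | None = None,
    with_region: bool = True,
) -> dict:
    """Write a labelled synthetic dataset and return its manifest.

    Per subject: 8-bit sRGB image PNG, three 16-bit grayscale truth-map
    PNGs, skin mask PNG, region/surround masks (when blobs are enabled), and
    a manifest JSON recording seeds and array checksums.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"master_seed": master_seed, "shape": list(shape), "subjects": []}
    rng = np.random.default_rng(master_seed)
    for k in range(n_subjects):
        spec = sample_subject_spec(rng)
        subj = generate_subject(spec, shape, lut, tissue, with_region)
        stem = f"subject_{k:03d}"
        iio.imwrite(
            out_dir / f"{stem}_image.png",
            (subj["image"] * 255).round().astype(np.uint8),
        )
        for name in ("melanin", "hemoglobin", "shading"):
            arr = getattr(subj["maps"], name)
            iio.imwrite(
                out_dir / f"{stem}_{name}.png",
                (arr * 65535).round().astype(np.uint16),
            )
        iio.imwrite(
            out_dir / f"{stem}_mask.png",
            subj["mask"].astype(np.uint8) * 255,
        )
        entry = {
            "stem": stem,
            "spec": asdict(spec),
            "image_checksum": _checksum(subj["image"]),
            "maps_checksum": _checksum(
                np.stack(
                    [subj["maps"].melanin, subj["maps"].hemoglobin, subj["maps"].shading]
                )
            ),
        }
        if subj["region_pair"] is not None:
            pair = subj["region_pair"]
            iio.imwrite(
                out_dir / f"{stem}_region.png", pair.region_mask.astype(np.uint8) * 255
            )
            iio.imwrite(
                out_dir / f"{stem}_surround.png",
                pair.surround_mask.astype(np.uint8) * 255,
            )
        manifest["subjects"].append(entry)
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
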