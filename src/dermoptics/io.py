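"""Image and pigment-map file I/O.

Images travel as 8-bit PNG or 8/16-bit TIFF with a JSON sidecar recording
the color-space tag (``linear`` or ``srgb``), since the raster itself
cannot carry that provenance.  Pigment maps persist as three single-channel
16-bit grayscale images plus a sidecar with the volume-fraction ranges they
normalize against.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .renderer import PigmentMaps
from .spectral_optics import TissueParams

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_pigment_maps",
    "load_pigment_maps",
    "chroma_threshold_mask",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path: str | Path, img: np.ndarray, color_space: str = "srgb",
                bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as PNG/TIFF with a color-space sidecar."""
    path = Path(path)
    if color_space not in ("srgb", "linear"):
        raise ValueError("color_space must be 'srgb' or 'linear'")
    arr = np.clip(np.asarray(img, float), 0.0, 1.0)
    if bit_depth == 8:
        raster = (arr * 255).round().astype(np.uint8)
    elif bit_depth == 16:
        raster = (arr * 65535).round().astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if bit_depth == 16 and raster.ndim == 3:
        # 16-bit color rasters go through TIFF; PNG backends only handle
        # 16 bits for single-channel images
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("16-bit color images must use a .tif/.tiff path")
        import tifffile

        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)
    with open(_sidecar(path), "w") as f:
        json.dump({"color_space": color_space, "bit_depth": bit_depth}, f)


def read_image(path: str | Path) -> tuple[np.ndarray, str]:
    """Read an image to [0, 1] float plus its color-space tag.

    Without a sidecar the tag defaults to ``srgb`` (camera-processed input).
    """
    path = Path(path)
    raster = iio.imread(path)
    if raster.dtype == np.uint8:
        img = raster.astype(float) / 255.0
    elif raster.dtype == np.uint16:
        img = raster.astype(float) / 65535.0
    else:
        img = np.asarray(raster, float)
    tag = "srgb"
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as f:
            tag = json.load(f).get("color_space", "srgb")
    return img, tag


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(mask, bool).astype(np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_pigment_maps(directory: str | Path, maps: PigmentMaps,
                      tissue: TissueParams | None = None,
                      stem: str = "maps") -> None:
    """Persist maps as 16-bit grayscale PNGs + a range-recording sidecar."""
    t = tissue or TissueParams()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("melanin", "hemoglobin", "shading"):
        arr = getattr(maps, name)
        iio.imwrite(
            directory / f"{stem}_{name}.png",
            (np.clip(arr, 0, 1) * 65535).round().astype(np.uint16),
        )
    with open(directory / f"{stem}_ranges.json", "w") as f:
        json.dump(
            {
                "melanin_vf_range": list(t.melanin_vf_range),
                "hemoglobin_vf_range": list(t.hemoglobin_vf_range),
            },
            f,
        )


def load_pigment_maps(directory: str | Path, stem: str = "maps") -> PigmentMaps:
    directory = Path(directory)
    arrs = {}
    for name in ("melanin", "hemoglobin", "shading"):
        raster = iio.imread(directory / f"{stem}_{name}.png")
        arrs[name] = raster.astype(float) / 65535.0
    return PigmentMaps(arrs["melanin"], arrs["hemoglobin"], arrs["shading"])


def chroma_threshold_mask(img: np.ndarray, min_value: float = 0.15,
                          max_chroma_ratio: float = 3.0) -> np.ndarray:
    """Crude fallback skin mask for sRGB images without a provided mask.

    Keeps pixels that are bright enough and warm-toned (red >= green >=-ish
    blue); a stand-in for a trained segmentation model, not a replacement.
    """
    arr = np.asarray(img, float)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    value = arr.max(axis=-1)
    warm = (r >= g * 0.95) & (g >= b * 0.8)
    bounded = r <= np.maximum(b, 1e-6) * max_chroma_ratio
    return (value > min_value) & warm & bounded
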