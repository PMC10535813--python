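"""Overlapping patch decomposition and seam-free recombination.

Full images are split into fixed-size patches that overlap by a small band
(15 px by default, mirroring typical patch-inference practice).  Per-patch
outputs are recombined with per-pixel crossfade weights: each patch carries
a separable tent profile (linear ramp in from every edge), and weights are
normalized across patches so they form an exact partition of unity.  In a
two-patch overlap band the normalized weights reduce to the symmetric
linear crossfade, so patches that differ by a constant blend as a straight
ramp with no visible seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatchGrid", "split_into_patches", "blend_patches"]


def _axis_origins(dim: int, patch: int, step: int) -> list[int]:
    """Row-major 1-D origins: stride by step, last patch anchored to the border."""
    if dim <= patch:
        return [0]
    origins = list(range(0, dim - patch, step))
    origins.append(dim - patch)
    return origins


@dataclass(frozen=True)
class PatchGrid:
    """Patch geometry for a full image of shape ``image_shape`` (H, W).

    Patches are ``patch_size`` squares with 0-based row-major half-open
    windows; adjacent interior patches share ``overlap`` pixels.  Images
    smaller than one patch are reflect-padded up to patch size by
    :func:`split_into_patches` (padding recorded on the grid).
    """

    image_shape: tuple[int, int]
    patch_size: int = 256
    overlap: int = 15

    def __post_init__(self) -> None:
        if self.overlap < 0 or self.overlap >= self.patch_size:
            raise ValueError("overlap must satisfy 0 <= overlap < patch_size")
        if min(self.image_shape) < 1:
            raise ValueError("empty image")

    @property
    def padded_shape(self) -> tuple[int, int]:
        return (
            max(self.image_shape[0], self.patch_size),
            max(self.image_shape[1], self.patch_size),
        )

    @property
    def padding(self) -> tuple[int, int]:
        return (
            self.padded_shape[0] - self.image_shape[0],
            self.padded_shape[1] - self.image_shape[1],
        )

    @property
    def origins(self) -> list[tuple[int, int]]:
        """Patch origins (row, col) in row-major order on the padded canvas."""
        step = self.patch_size - self.overlap
        h, w = self.padded_shape
        rows = _axis_origins(h, self.patch_size, step)
        cols = _axis_origins(w, self.patch_size, step)
        return [(r, c) for r in rows for c in cols]

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "patch_size": self.patch_size,
            "overlap": self.overlap,
            "origins": [list(o) for o in self.origins],
        }


def split_into_patches(img: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Split an (H, W[, C]) array into the grid's ordered patch list.

    Inputs smaller than one patch are reflect-padded on the bottom/right.
    """
    if img.shape[:2] != grid.image_shape:
        raise ValueError("image shape does not match grid")
    ph, pw = grid.padding
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="reflect")
    p = grid.patch_size
    return [img[r : r + p, c : c + p].copy() for r, c in grid.origins]


def _tent(length: int) -> np.ndarray:
    # Linear ramp in from both ends; distance-to-edge profile.
    i = np.arange(length, dtype=float)
    return np.minimum(i + 1.0, length - i)


def patch_weights(grid: PatchGrid) -> np.ndarray:
    """Normalized per-patch weight fields, shape (n_patches, H, W) (padded).

    Weights are an exact partition of unity at every pixel.
    """
    p = grid.patch_size
    tent = _tent(p)
    profile = tent[:, None] * tent[None, :]
    h, w = grid.padded_shape
    origins = grid.origins
    raw = np.zeros((len(origins), h, w))
    for k, (r, c) in enumerate(origins):
        raw[k, r : r + p, c : c + p] = profile
    total = raw.sum(axis=0)
    return raw / total


def blend_patches(patches: list[np.ndarray], grid: PatchGrid,
                  out_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Recombine per-patch outputs into a full image with crossfade weights.

    The patch list must be complete and ordered as produced by
    :func:`split_into_patches`.  Splitting an image and blending the patches
    back reproduces it exactly.
    """
    origins = grid.origins
    if len(patches) != len(origins):
        raise ValueError(
            f"expected {len(origins)} patches, got {len(patches)}"
        )
    p = grid.patch_size
    extra = patches[0].shape[2:]
    h, w = grid.padded_shape
    acc = np.zeros((h, w) + extra)
    wsum = np.zeros((h, w))
    tent = _tent(p)
    profile = tent[:, None] * tent[None, :]
    for patch, (r, c) in zip(patches, origins):
        if patch.shape[:2] != (p, p):
            raise ValueError("patch shape does not match grid patch_size")
        wp = profile if not extra else profile[..., None]
        acc[r : r + p, c : c + p] += patch * wp
        wsum[r : r + p, c : c + p] += profile
    out = acc / (wsum if not extra else wsum[..., None])
    h0, w0 = grid.image_shape
    out = out[:h0, :w0]
    if out_shape is not None and out.shape != tuple(out_shape):
        raise ValueError("blended output shape mismatch")
    return out
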