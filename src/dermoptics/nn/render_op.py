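"""Differentiable reflectance-LUT rendering as an autodiff operation.

Bridges the network's (N, 3, H, W) map output — channels ordered (melanin,
hemoglobin, shading), all in [0, 1] — to a linear-RGB image through the
precomputed reflectance table.  The bilinear lookup has closed-form partial
derivatives, so gradients flow from the reconstruction loss back into all
three maps.
"""

from __future__ import annotations

import numpy as np

from ..spectral_optics import ReflectanceLUT, TissueParams
from .autograd import Tensor

__all__ = ["lut_render"]


def lut_render(maps: Tensor, lut: ReflectanceLUT, tissue: TissueParams) -> Tensor:
    """Render normalized pigment maps to a linear-RGB image tensor.

    Per pixel: bilinear LUT lookup at the affinely rescaled (vm, vh), times
    the shading value.  Output shape equals the input shape (N, 3, H, W).
    """
    if maps.data.ndim != 4 or maps.data.shape[1] != 3:
        raise ValueError("expected (N, 3, H, W) map tensor")
    m_lo, m_hi = tissue.melanin_vf_range
    h_lo, h_hi = tissue.hemoglobin_vf_range
    mel = maps.data[:, 0].astype(np.float64)
    hem = maps.data[:, 1].astype(np.float64)
    sha = maps.data[:, 2].astype(np.float64)
    vm = m_lo + mel * (m_hi - m_lo)
    vh = h_lo + hem * (h_hi - h_lo)
    rgb, dvm, dvh = lut.lookup_with_grad(vm, vh)  # (N, H, W, 3) each
    out = rgb * sha[..., None]

    def backward(g):
        if not maps.requires_grad:
            return
        gi = np.moveaxis(g.astype(np.float64), 1, -1)  # (N, H, W, 3)
        d_mel = (gi * dvm).sum(axis=-1) * sha * (m_hi - m_lo)
        d_hem = (gi * dvh).sum(axis=-1) * sha * (h_hi - h_lo)
        d_sha = (gi * rgb).sum(axis=-1)
        maps._accumulate(
            np.stack([d_mel, d_hem, d_sha], axis=1).astype(maps.data.dtype)
        )

    return Tensor(np.moveaxis(out, -1, 1), (maps,), backward)
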