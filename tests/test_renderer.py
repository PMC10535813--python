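"""LUT renderer: map rescaling, rendering, reconstruction metrics, gradients."""

import numpy as np
import pytest

from dermoptics import (
    PigmentMaps,
    maps_to_volume_fractions,
    mse,
    psnr,
    render,
)
from dermoptics.nn import Tensor, lut_render


class TestMapRescaling:
    def test_endpoints_map_to_physiological_bounds(self, tissue):
        maps = PigmentMaps(np.zeros((2, 2)), np.zeros((2, 2)), np.ones((2, 2)))
        vm, vh = maps_to_volume_fractions(maps, tissue)
        assert np.allclose(vm, 0.013)
        assert np.allclose(vh, 0.02)
        maps = PigmentMaps(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)))
        vm, vh = maps_to_volume_fractions(maps, tissue)
        assert np.allclose(vm, 0.43)
        assert np.allclose(vh, 0.07)

    def test_hemoglobin_midpoint(self, tissue):
        maps = PigmentMaps(np.zeros((1, 1)), np.full((1, 1), 0.5), np.ones((1, 1)))
        _, vh = maps_to_volume_fractions(maps, tissue)
        assert np.allclose(vh, 0.045)

    def test_out_of_range_values_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            maps = PigmentMaps(np.full((1, 1), 1.5), np.zeros((1, 1)), np.ones((1, 1)))
        assert maps.melanin[0, 0] == 1.0


class TestRender:
    def test_zero_shading_black_image(self, lut, tissue, rng):
        maps = PigmentMaps(rng.random((8, 8)), rng.random((8, 8)), np.zeros((8, 8)))
        assert np.allclose(render(maps, lut, tissue), 0.0)

    def test_constant_maps_constant_image(self, lut, tissue):
        maps = PigmentMaps(*(np.full((6, 6), v) for v in (0.3, 0.5, 0.9)))
        img = render(maps, lut, tissue)
        assert np.allclose(img, img[0, 0])

    def test_node_pixels_match_lut_nodes(self, lut, tissue):
        # pick normalized values that land exactly on grid nodes
        i, j = 10, 20
        m_lo, m_hi = tissue.melanin_vf_range
        h_lo, h_hi = tissue.hemoglobin_vf_range
        mval = (lut.vm_grid[i] - m_lo) / (m_hi - m_lo)
        hval = (lut.vh_grid[j] - h_lo) / (h_hi - h_lo)
        maps = PigmentMaps(np.full((2, 2), mval), np.full((2, 2), hval),
                           np.ones((2, 2)))
        assert np.allclose(render(maps, lut, tissue), lut.rgb_table[i, j], atol=1e-12)

    def test_more_melanin_darkens_every_channel(self, lut, tissue, rng):
        for _ in range(20):
            m = rng.random((4, 4)) * 0.5
            h = rng.random((4, 4))
            s = rng.random((4, 4)) * 0.5 + 0.5
            a = render(PigmentMaps(m, h, s), lut, tissue)
            b = render(PigmentMaps(m + 0.3, h, s), lut, tissue)
            assert np.all(b <= a + 1e-12)

    def test_homogeneous_in_shading(self, lut, tissue, rng):
        m, h = rng.random((5, 5)), rng.random((5, 5))
        s = rng.random((5, 5)) * 0.5
        one = render(PigmentMaps(m, h, s), lut, tissue)
        two = render(PigmentMaps(m, h, 2 * s), lut, tissue)
        assert np.allclose(two, 2 * one, atol=1e-12)

    def test_autodiff_gradient_matches_finite_differences(self, lut, tissue):
        # off-knot probe; the render op's analytic bilinear gradient
        import dermoptics.nn.autograd as ag

        old = ag.DTYPE
        ag.DTYPE = np.float64
        try:
            rng = np.random.default_rng(3)
            base = rng.uniform(0.2, 0.8, (1, 3, 4, 4))
            eps = 1e-6
            t = Tensor(base, requires_grad=True)
            out = lut_render(t, lut, tissue)
            loss = Tensor(
                np.array(out.data.sum()), (out,),
                lambda g: out._accumulate(np.ones_like(out.data) * g),
            )
            loss.backward()
            for idx in [(0, 0, 1, 2), (0, 1, 3, 0), (0, 2, 2, 2)]:
                pert = base.copy()
                pert[idx] += eps
                up = lut_render(Tensor(pert), lut, tissue).data.sum()
                pert[idx] -= 2 * eps
                dn = lut_render(Tensor(pert), lut, tissue).data.sum()
                num = (up - dn) / (2 * eps)
                assert t.grad[idx] == pytest.approx(num, rel=1e-4)
        finally:
            ag.DTYPE = old


class TestMetrics:
    def test_identical_images_zero_error_infinite_psnr(self, rng):
        img = rng.random((8, 8, 3))
        assert mse(img, img) == 0.0
        assert psnr(img, img) == float("inf")

    def test_constant_offset_closed_form(self):
        a = np.zeros((4, 4, 3))
        b = np.full((4, 4, 3), 0.1)
        assert mse(a, b) == pytest.approx(0.01)

    def test_psnr_forty_db_at_mse_1e_minus_4(self):
        a = np.zeros((10, 10, 3))
        b = np.full((10, 10, 3), 0.01)
        assert psnr(a, b) == pytest.approx(40.0)

    def test_mask_restricts_error_region(self):
        a = np.zeros((4, 4, 3))
        b = a.copy()
        b[0, 0] = 1.0
        mask = np.zeros((4, 4), bool)
        mask[2:, 2:] = True
        assert mse(a, b, mask) == 0.0

    def test_empty_mask_rejected(self):
        a = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            mse(a, a, np.zeros((4, 4), bool))
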