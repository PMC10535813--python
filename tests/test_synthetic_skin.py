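"""Synthetic skin generator: determinism, field statistics, blobs, datasets."""

import json

import numpy as np
import pytest

from dermoptics import (
    SubjectSpec,
    add_pigmented_region,
    generate_dataset,
    generate_pigment_fields,
    generate_subject,
    maps_to_volume_fractions,
)
from dermoptics.synthetic_skin import make_subjects, sample_subject_spec


class TestFields:
    def test_same_seed_bit_identical(self):
        spec = SubjectSpec(seed=7)
        a = generate_pigment_fields(spec, (64, 64))
        b = generate_pigment_fields(spec, (64, 64))
        assert np.array_equal(a.melanin, b.melanin)
        assert np.array_equal(a.hemoglobin, b.hemoglobin)
        assert np.array_equal(a.shading, b.shading)

    def test_zero_noise_gives_constant_maps(self):
        spec = SubjectSpec(noise_amplitude=0.0, seed=1)
        maps = generate_pigment_fields(spec, (32, 32))
        assert np.allclose(maps.melanin, spec.base_melanin)
        assert np.allclose(maps.hemoglobin, spec.base_hemoglobin)

    def test_shading_confined_to_declared_range(self):
        spec = SubjectSpec(seed=3)
        maps = generate_pigment_fields(spec, (64, 64))
        lo, hi = spec.shading_range
        assert maps.shading.min() >= lo and maps.shading.max() <= hi

    def test_autocorrelation_length_matches_smoothness(self):
        # empirical correlogram oracle: the 1/e crossing of the row-lag
        # autocorrelation should sit near the declared correlation length
        target = 10.0
        spec = SubjectSpec(field_smoothness=target, noise_amplitude=0.05,
                           base_melanin=0.5, seed=11)
        maps = generate_pigment_fields(spec, (256, 256))
        f = maps.melanin - maps.melanin.mean()
        corrs = []
        for lag in range(1, 40):
            a, b = f[:, :-lag].ravel(), f[:, lag:].ravel()
            corrs.append(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
        crossing = 1 + int(np.argmax(np.array(corrs) < np.exp(-1)))
        assert abs(crossing - target) <= 0.2 * target

    def test_volume_fractions_stay_physiological(self, tissue):
        maps = generate_pigment_fields(SubjectSpec(seed=5), (64, 64))
        vm, vh = maps_to_volume_fractions(maps, tissue)
        assert vm.min() >= tissue.melanin_vf_range[0] - 1e-12
        assert vm.max() <= tissue.melanin_vf_range[1] + 1e-12
        assert vh.min() >= tissue.hemoglobin_vf_range[0] - 1e-12
        assert vh.max() <= tissue.hemoglobin_vf_range[1] + 1e-12


class TestBlobs:
    def test_zero_gain_leaves_maps_unchanged(self):
        spec = SubjectSpec(blob_gain=(0.0, 0.0), noise_amplitude=0.0, seed=2)
        maps = generate_pigment_fields(spec, (128, 128))
        out, pair = add_pigmented_region(maps, spec)
        assert np.allclose(out.melanin, maps.melanin)
        from dermoptics import region_contrast

        assert region_contrast(out.melanin, pair) == pytest.approx(0.0, abs=1e-12)

    def test_blob_core_contrast_tracks_gain(self):
        # raised-cosine profile averaged over the core disk (r <= R/2):
        # (2/ (1/2)^2) * int_0^{1/2} 0.5 (1 + cos pi x) x dx = 0.7323
        gain = 0.2
        spec = SubjectSpec(noise_amplitude=0.0, blob_gain=(gain, gain),
                           n_blobs=1, seed=4)
        maps = generate_pigment_fields(spec, (128, 128))
        out, pair = add_pigmented_region(maps, spec)
        contrast = (
            out.melanin[pair.region_mask].mean()
            - out.melanin[pair.surround_mask].mean()
        )
        assert contrast == pytest.approx(0.7323 * gain, rel=0.05)

    def test_hemoglobin_only_blob_leaves_melanin_unchanged(self):
        spec = SubjectSpec(blob_pigment="hemoglobin", seed=6)
        maps = generate_pigment_fields(spec, (128, 128))
        out, pair = add_pigmented_region(maps, spec)
        assert np.array_equal(out.melanin, maps.melanin)
        assert (
            out.hemoglobin[pair.region_mask].mean()
            > out.hemoglobin[pair.surround_mask].mean()
        )

    def test_blob_too_large_for_canvas_rejected(self):
        spec = SubjectSpec(blob_radius_px=(60, 60), seed=1)
        maps = generate_pigment_fields(spec, (64, 64))
        with pytest.raises(ValueError):
            add_pigmented_region(maps, spec)


class TestDataset:
    def test_rendered_subjects_darker_with_more_melanin(self, lut, tissue):
        from dermoptics import ita

        light = generate_subject(
            SubjectSpec(base_melanin=0.05, seed=1), (64, 64), lut, tissue,
            with_region=False)
        dark = generate_subject(
            SubjectSpec(base_melanin=0.6, seed=1), (64, 64), lut, tissue,
            with_region=False)
        assert ita(dark["image"]) < ita(light["image"])

    def test_make_subjects_reproducible_under_master_seed(self, lut):
        a = make_subjects(3, lut, shape=(64, 64), master_seed=9)
        b = make_subjects(3, lut, shape=(64, 64), master_seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa["image"], sb["image"])

    def test_generate_dataset_layout_and_checksums(self, lut, tmp_path):
        m1 = generate_dataset(2, lut, tmp_path / "a", shape=(96, 96),
                              master_seed=3, with_region=False)
        m2 = generate_dataset(2, lut, tmp_path / "b", shape=(96, 96),
                              master_seed=3, with_region=False)
        assert len(m1["subjects"]) == 2
        for s1, s2 in zip(m1["subjects"], m2["subjects"]):
            assert s1["image_checksum"] == s2["image_checksum"]
            assert s1["maps_checksum"] == s2["maps_checksum"]
        files = {p.name for p in (tmp_path / "a").iterdir()}
        assert "manifest.json" in files
        assert "subject_000_image.png" in files
        assert "subject_001_melanin.png" in files
        with open(tmp_path / "a" / "manifest.json") as f:
            assert json.load(f)["master_seed"] == 3

    def test_sampled_specs_cover_population_ranges(self):
        rng = np.random.default_rng(0)
        specs = [sample_subject_spec(rng) for _ in range(50)]
        mels = [s.base_melanin for s in specs]
        hbs = [s.base_hemoglobin for s in specs]
        assert 0.02 <= min(mels) and max(mels) <= 0.10
        assert 0.30 <= min(hbs) and max(hbs) <= 0.60
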