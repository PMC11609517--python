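"""En face projection, artifact removal, percentile normalization."""

import warnings

import numpy as np
import pytest

from octaplex.enface import (EnFaceImage, build_single_class_dataset,
                             normalize_image, project_enface,
                             remove_projection_artifact)
from octaplex.phantoms import OctaVolume, generate_cohort


def _volume(voxels):
    return OctaVolume(voxels=np.asarray(voxels), patient_id="p", eye="OD",
                      cube_id="c")


def _brute_force_max(vox, upper, lower):
    h, w, _ = vox.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            lo, hi = int(np.floor(upper[i, j])), int(np.floor(lower[i, j]))
            out[i, j] = max(vox[i, j, z] for z in range(lo, hi + 1))
    return out


class TestProjectEnface:
    def test_single_bright_voxel_found(self):
        vox = np.zeros((8, 8, 16))
        vox[3, 4, 2] = 200.0
        img = project_enface(_volume(vox), np.full((8, 8), 1.0),
                             np.full((8, 8), 3.0))
        assert img.pixels[3, 4] == 200.0
        assert img.pixels[0, 0] == 0.0

    def test_degenerate_interval_equals_slice(self):
        g = np.random.default_rng(0)
        vox = g.integers(0, 256, (8, 8, 16)).astype(np.uint8)
        img = project_enface(_volume(vox), np.full((8, 8), 5.0),
                             np.full((8, 8), 5.0))
        np.testing.assert_array_equal(img.pixels, vox[:, :, 5].astype(float))

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_oracle(self, trial):
        g = np.random.default_rng(trial)
        vox = g.integers(0, 256, (16, 16, 24)).astype(np.uint8)
        upper = g.integers(0, 12, (16, 16)).astype(float)
        lower = upper + g.integers(0, 11, (16, 16))
        img = project_enface(_volume(vox), upper, lower)
        np.testing.assert_array_equal(img.pixels,
                                      _brute_force_max(vox, upper, lower))

    def test_invalid_boundaries_rejected(self):
        vox = np.zeros((8, 8, 16))
        with pytest.raises(ValueError):
            project_enface(_volume(vox), np.full((8, 8), 5.0),
                           np.full((8, 8), 3.0))
        with pytest.raises(ValueError):
            project_enface(_volume(vox), np.full((8, 8), 1.0),
                           np.full((8, 8), 16.0))


class TestProjectionRemoval:
    def test_alpha_zero_is_identity(self):
        g = np.random.default_rng(1)
        deeper = EnFaceImage(g.integers(0, 256, (16, 16)).astype(float),
                             "deep", "c")
        sup = EnFaceImage(g.integers(0, 256, (16, 16)).astype(float),
                          "superficial", "c")
        out = remove_projection_artifact(deeper, sup, 0.0)
        np.testing.assert_array_equal(out.pixels, deeper.pixels)

    def test_full_subtraction_of_self_is_zero(self):
        g = np.random.default_rng(2)
        pix = g.integers(0, 256, (16, 16)).astype(float)
        deeper = EnFaceImage(pix, "deep", "c")
        sup = EnFaceImage(pix.copy(), "superficial", "c")
        assert (remove_projection_artifact(deeper, sup, 1.0).pixels == 0).all()

    def test_attenuated_tail_suppressed_to_background(self):
        # constructed fixture: dark deep slab carrying a 0.4-attenuated
        # copy of a bright superficial vessel
        sup_pix = np.full((16, 16), 50.0)
        sup_pix[8, :] = 250.0
        deep_pix = np.full((16, 16), 30.0) + 0.4 * (sup_pix - 50.0)
        out = remove_projection_artifact(
            EnFaceImage(deep_pix, "deep", "c"),
            EnFaceImage(sup_pix, "superficial", "c"), 0.4)
        background = out.pixels[0, 0]
        assert (out.pixels[8, :] <= background + 1e-9).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            remove_projection_artifact(
                EnFaceImage(np.zeros((8, 8)), "deep", "c"),
                EnFaceImage(np.zeros((8, 9)), "superficial", "c"), 0.4)


class TestNormalization:
    def test_linear_ramp_mapping(self):
        pix = np.arange(100, dtype=float).reshape(10, 10)
        out = normalize_image(EnFaceImage(pix, "deep", "c")).pixels
        lo, hi = np.percentile(pix, 2.0), np.percentile(pix, 99.0)
        assert out[0, 0] == 0 and out[0, 1] == 0     # bottom 2% -> 0
        assert out[9, 9] == 255                       # top 1% -> 255
        mid = np.floor(255.0 * (pix[5, 5] - lo) / (hi - lo) + 0.5)
        assert out[5, 5] == mid

    def test_constant_image_warns_and_passes_through(self):
        pix = np.full((16, 16), 42.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = normalize_image(EnFaceImage(pix, "avascular", "c"))
        assert out.normalized
        np.testing.assert_array_equal(out.pixels, pix)
        assert any("degenerate" in str(w.message) for w in rec)

    def test_tail_fractions(self):
        g = np.random.default_rng(3)
        pix = g.uniform(0, 255, (32, 32))
        out = normalize_image(EnFaceImage(pix, "deep", "c")).pixels
        assert (out == 0).mean() >= 0.02
        assert (out == 255).mean() >= 0.01

    def test_rank_order_preserved_in_central_band(self):
        g = np.random.default_rng(4)
        pix = g.uniform(0, 255, (32, 32))
        lo, hi = np.percentile(pix, 2.0), np.percentile(pix, 99.0)
        out = normalize_image(EnFaceImage(pix, "deep", "c")).pixels
        central = (pix > lo) & (pix < hi)
        a, b = pix[central].ravel(), out[central].ravel()
        order = np.argsort(a)
        assert (np.diff(b[order]) >= 0).all()

    def test_idempotent_up_to_rounding(self):
        g = np.random.default_rng(5)
        pix = g.uniform(0, 255, (40, 40))
        once = normalize_image(EnFaceImage(pix, "deep", "c"))
        twice = normalize_image(once)
        assert np.abs(twice.pixels - once.pixels).max() <= 1.0

    def test_histograms_converge_after_normalization(self):
        """Normalization pulls the superficial and avascular intensity
        histograms together (smaller earth-mover distance)."""
        from scipy.stats import wasserstein_distance
        from octaplex.enface import project_class_slabs
        from octaplex.phantoms import generate_phantom_volume
        vol, b = generate_phantom_volume("p", "OD", (48, 48, 64),
                                         np.random.default_rng(9))
        slabs = project_class_slabs(vol, b)
        sup, avas = slabs["superficial"], slabs["avascular"]
        d_raw = wasserstein_distance(sup.pixels.ravel(), avas.pixels.ravel())
        d_norm = wasserstein_distance(
            normalize_image(sup).pixels.ravel(),
            normalize_image(avas).pixels.ravel())
        assert d_norm < d_raw


class TestSingleClassDataset:
    def test_three_images_per_cube(self, small_cohort):
        images = build_single_class_dataset(small_cohort)
        assert len(images) == 3 * len(small_cohort)
        per_cube = {}
        for img in images:
            per_cube.setdefault(img.cube_id, []).append(img.class_label)
        assert all(sorted(v) == ["avascular", "deep", "superficial"]
                   for v in per_cube.values())

    def test_six_with_normalized(self):
        cohort = generate_cohort(3, (1, 1), (32, 32, 48), seed=2)
        images = build_single_class_dataset(cohort, include_normalized=True)
        assert len(images) == 6 * len(cohort)
        assert sum(img.normalized for img in images) == 3 * len(cohort)
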