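import numpy as np
import pytest

from brixmap.hypercube import Hypercube, WavelengthAxis, nearest_band
from brixmap.segmentation import (build_roi_set, extract_mean_spectrum,
                                  flesh_achene_masks, fruit_mask,
                                  otsu_threshold, pc1_score_image,
                                  remove_saturated, split_top_bottom,
                                  threshold_mask)
from brixmap.synthetic import (CLASS_LABELS, SATURATION_PLATEAU,
                               generate_scene, make_library)


def otsu_objective(values, nbins=256):
    """Independent oracle: between-class variance of every split of the same
    256-bin histogram, computed by explicit per-split summation."""
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    variances = np.full(nbins - 1, -np.inf)
    for split in range(1, nbins):
        w0 = counts[:split].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:split] * centers[:split]).sum() / w0
        mu1 = (counts[split:] * centers[split:]).sum() / w1
        variances[split - 1] = w0 * w1 * (mu0 - mu1) ** 2
    return centers, variances


def brute_force_otsu(values, nbins=256):
    """Threshold (boundary-bin center) maximising the oracle objective."""
    centers, variances = otsu_objective(values, nbins)
    return centers[int(np.argmax(variances))]


def assert_otsu_optimal(t, values, nbins=256):
    """The library threshold must achieve the brute-force maximum of the
    between-class variance.  Comparison is on the objective value because
    empty boundary bins create exact ties between adjacent splits."""
    centers, variances = otsu_objective(values, nbins)
    half_bin = (centers[1] - centers[0]) / 2
    # an edge threshold sits exactly between two bin centers; the split it
    # denotes is one of the adjacent candidates
    near = np.flatnonzero(np.abs(centers - t) <= half_bin * (1 + 1e-9))
    assert near.size > 0
    assert variances[near].max() >= variances.max() * (1 - 1e-9)


def uniform_cube(value, shape=(4, 4), n_bands=20):
    axis = WavelengthAxis(np.linspace(913, 2166, n_bands))
    return Hypercube(np.full(shape + (n_bands,), float(value)), axis)


class TestThresholdMask:
    def test_uniform_above(self):
        cube = uniform_cube(1.3)
        assert threshold_mask(cube, 1077.0, 1.205, "above").all()

    def test_boundary_is_strict(self):
        cube = uniform_cube(1.205)
        assert not threshold_mask(cube, 1077.0, 1.205, "above").any()
        assert not threshold_mask(cube, 1077.0, 1.205, "below").any()

    def test_below_complements_above_off_boundary(self):
        rng = np.random.default_rng(0)
        axis = WavelengthAxis(np.linspace(913, 2166, 5))
        cube = Hypercube(rng.uniform(0, 2, (6, 6, 5)), axis)
        above = threshold_mask(cube, 1077.0, 1.0, "above")
        below = threshold_mask(cube, 1077.0, 1.0, "below")
        assert not np.any(above & below)
        assert np.all(above | below)    # exact 1.0 has probability zero


class TestFruitMask:
    def test_matches_scene_labels_exactly_without_noise(self, library):
        cube, truth = generate_scene(seed=3, noise_sd=0.0, scatter=None,
                                     n_saturated=0, library=library)
        mask = fruit_mask(cube)
        want = truth.labels >= CLASS_LABELS["flesh"]
        np.testing.assert_array_equal(mask, want)

    def test_pure_background_raises(self, library):
        axis = library.axis
        cube = Hypercube(
            np.broadcast_to(library.spectrum("background"),
                            (8, 8, len(axis))).copy(), axis)
        with pytest.raises(ValueError, match="no fruit"):
            fruit_mask(cube)

    def test_degenerate_thresholds_keep_everything(self, library):
        cube, _ = generate_scene(seed=3, library=library)
        mask = fruit_mask(cube, t1077=-1e9, t1940_snv=-1e9)
        assert mask.all()


class TestRemoveSaturated:
    def test_injected_pixels_are_exactly_the_ones_removed(self, scene):
        cube, truth = scene
        full = np.ones(truth.labels.shape, dtype=bool)
        kept = remove_saturated(cube, full, sat_level=SATURATION_PLATEAU)
        removed = np.argwhere(~kept)
        assert {tuple(p) for p in removed} == {tuple(p) for p in truth.saturated}

    def test_huge_level_is_identity(self, scene):
        cube, truth = scene
        full = np.ones(truth.labels.shape, dtype=bool)
        assert remove_saturated(cube, full, sat_level=1e9).all()

    def test_all_saturated_gives_empty_mask(self):
        cube = uniform_cube(3.0)
        full = np.ones((4, 4), dtype=bool)
        assert not remove_saturated(cube, full, sat_level=2.2).any()


class TestPC1:
    def test_two_endmember_mixture_recovered(self, library):
        # pixels mixing flesh and achene along a known fraction
        rng = np.random.default_rng(1)
        frac = rng.uniform(0, 1, size=(30, 30))
        flesh = library.spectrum("flesh")
        achene = library.spectrum("achene")
        data = (1 - frac)[:, :, None] * flesh + frac[:, :, None] * achene
        data += rng.normal(0, 1e-3, data.shape)
        cube = Hypercube(data, library.axis)
        mask = np.ones((30, 30), dtype=bool)
        scores, loading = pc1_score_image(cube, mask)
        r = np.corrcoef(scores[mask], frac[mask])[0, 1]
        assert abs(r) > 0.99
        np.testing.assert_allclose(np.linalg.norm(loading), 1.0, atol=1e-12)

    def test_row_duplication_leaves_loading_unchanged(self, library):
        rng = np.random.default_rng(2)
        frac = rng.uniform(0, 1, size=(20, 20))
        data = ((1 - frac)[:, :, None] * library.spectrum("flesh")
                + frac[:, :, None] * library.spectrum("achene"))
        data += rng.normal(0, 1e-3, data.shape)
        mask = np.ones((20, 20), dtype=bool)
        cube = Hypercube(data, library.axis)
        doubled = Hypercube(np.concatenate([data, data], axis=0),
                            library.axis)
        mask2 = np.ones((40, 20), dtype=bool)
        _, l1 = pc1_score_image(cube, mask)
        _, l2 = pc1_score_image(doubled, mask2)
        assert min(np.abs(l1 - l2).max(), np.abs(l1 + l2).max()) < 1e-8

    def test_too_few_pixels_is_error(self, library):
        cube = Hypercube(np.zeros((2, 2, len(library.axis))), library.axis)
        with pytest.raises(ValueError, match="PCA needs"):
            pc1_score_image(cube, np.ones((2, 2), dtype=bool))


class TestOtsu:
    def test_separates_two_plateaus(self):
        values = np.array([0.0, 0.0, 0.0, 10.0, 10.0])
        t = otsu_threshold(values)
        assert 0.0 < t < 10.0
        assert np.array_equal(values <= t, values == 0.0)
        assert_otsu_optimal(t, values)

    def test_two_gaussians_misclassification_below_1pct(self):
        rng = np.random.default_rng(42)
        a = rng.normal(-5, 0.5, 1000)
        b = rng.normal(5, 0.5, 1000)
        t = otsu_threshold(np.concatenate([a, b]))
        mis = np.mean(a > t) + np.mean(b <= t)
        assert mis < 0.01

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(20, 500)
            values = np.concatenate([
                rng.normal(rng.uniform(-3, 0), rng.uniform(0.2, 1.5), n),
                rng.normal(rng.uniform(1, 4), rng.uniform(0.2, 1.5), n),
            ])
            assert_otsu_optimal(otsu_threshold(values), values)

    def test_partition_agrees_with_skimage(self):
        # independent library implementation: thresholds may sit at different
        # (tied) positions inside the class gap, but must split the sample
        # values identically
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = np.concatenate([
                rng.normal(-2, rng.uniform(0.2, 1.0), 300),
                rng.normal(3, rng.uniform(0.2, 1.0), 300),
            ])
            ours = otsu_threshold(values)
            theirs = threshold_otsu(values, nbins=256)
            # near-ties at the class boundary may shift either threshold by
            # one histogram bin; the partitions must agree everywhere else
            mismatch = np.mean((values > ours) != (values > theirs))
            assert mismatch <= 2 / values.size

    def test_negation_symmetry(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(-2, 0.3, 200),
                                 rng.normal(2, 0.3, 200)])
        t = otsu_threshold(values)
        t_neg = otsu_threshold(-values)
        # negating the values negates the threshold's partition
        np.testing.assert_array_equal(values > t, -values < t_neg)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_threshold(np.ones(10))


class TestFleshAchene:
    def test_partition_and_sign_invariance(self, scene):
        cube, truth = scene
        fruit = fruit_mask(cube)
        fruit = remove_saturated(cube, fruit)
        scores, _ = pc1_score_image(cube, fruit)
        flesh, achene = flesh_achene_masks(scores, fruit)
        assert not np.any(flesh & achene)
        np.testing.assert_array_equal(flesh | achene, fruit)
        flesh2, achene2 = flesh_achene_masks(-scores, fruit)
        np.testing.assert_array_equal(flesh, flesh2)
        np.testing.assert_array_equal(achene, achene2)

    def test_achene_fraction_near_target(self, scene):
        cube, truth = scene
        fruit = remove_saturated(cube, fruit_mask(cube))
        scores, _ = pc1_score_image(cube, fruit)
        flesh, achene = flesh_achene_masks(scores, fruit)
        frac = achene.sum() / fruit.sum()
        assert abs(frac - 0.087) < 0.02


class TestSplitTopBottom:
    def test_rectangle_splits_in_half(self):
        mask = np.zeros((12, 8), dtype=bool)
        mask[1:11, 2:6] = True          # 10 x 4 rectangle, long axis = rows
        bottom, top = split_top_bottom(mask)
        assert bottom.sum() == top.sum() == 20
        assert not np.any(bottom & top)
        np.testing.assert_array_equal(bottom | top, mask)

    def test_asymmetric_blob_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(4)
        mask = rng.random((20, 15)) < 0.4
        mask[0, 0] = True
        bottom, top = split_top_bottom(mask, top_side="low-index")
        rr, cc = np.nonzero(mask)
        long_axis_rows = (rr.max() - rr.min()) >= (cc.max() - cc.min())
        coord = rr if long_axis_rows else cc
        lo = coord.min()
        hi = coord.max()
        mid = (lo + hi) / 2
        for r, c, x in zip(rr, cc, coord):
            if x < mid:
                assert top[r, c]
            else:
                assert bottom[r, c]    # midpoint ties go to bottom

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            split_top_bottom(np.zeros((4, 4), dtype=bool))


class TestMeanSpectrum:
    def test_single_pixel(self, small_cube):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        np.testing.assert_array_equal(
            extract_mean_spectrum(small_cube, mask), small_cube.data[1, 2])

    def test_two_pixel_average(self):
        cube = uniform_cube(1.0)
        cube.data[0, 0, :] = 1.0
        cube.data[0, 1, :] = 3.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        np.testing.assert_allclose(extract_mean_spectrum(cube, mask), 2.0)

    def test_flesh_mean_matches_generator_expectation(self, library):
        cube, truth = generate_scene(seed=9, noise_sd=0.0, scatter=None,
                                     n_saturated=0, library=library)
        mask = truth.labels == CLASS_LABELS["flesh"]
        mean = extract_mean_spectrum(cube, mask)
        # noiseless scene: flesh pixel = endmember - brix * feature
        from brixmap.synthetic import BRIX_FEATURES, _gauss
        wl = library.axis.centers
        feat = sum(d * _gauss(wl, c, w) for c, w, d in BRIX_FEATURES)
        expected = library.spectrum("flesh") - truth.brix_field[mask].mean() * feat
        np.testing.assert_allclose(mean, expected, atol=1e-10)


class TestROISet:
    def test_partition_invariants_across_seeds(self):
        for seed in range(3):
            cube, _ = generate_scene(seed=seed)
            rois = build_roi_set(cube)     # constructor enforces invariants
            fruit = rois.masks["fruit_bottom"] | rois.masks["fruit_top"]
            flesh = rois.masks["flesh_bottom"] | rois.masks["flesh_top"]
            achene = rois.masks["achene_bottom"] | rois.masks["achene_top"]
            np.testing.assert_array_equal(flesh | achene, fruit)
            assert not np.any(rois.masks["fruit_bottom"]
                              & rois.masks["fruit_top"])

    def test_scale_invariance_with_rescaled_threshold(self, scene):
        cube, _ = scene
        rois1 = build_roi_set(cube)
        scaled = Hypercube(cube.data * 3.0, cube.axis)
        rois2 = build_roi_set(scaled, t1077=1.205 * 3.0, sat_level=2.2 * 3.0)
        for name in rois1.masks:
            np.testing.assert_array_equal(rois1.masks[name], rois2.masks[name])
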