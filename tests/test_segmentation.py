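"""EM auto-thresholding: histogram, mixture fit, valley, calibration, mask."""

from __future__ import annotations

import numpy as np
import pytest

from i2m.phantom import (
    IntensityModel,
    PrepSpec,
    make_prep_mesh,
    render_intensities,
    voxelize_impression,
)
from i2m.segmentation import (
    CalibrationRecord,
    GaussianMixtureModel,
    Histogram,
    area_of_conversion,
    calibrate_threshold,
    compute_histogram,
    estimate_valley,
    fit_calibration,
    fit_gmm_em,
    segment,
)
from i2m.surface import extract_isosurface
from i2m.deviation import unsigned_distances
from i2m.volume import GrayVolume


def make_gmm(weights, means, variances) -> GaussianMixtureModel:
    order = np.argsort(means)
    return GaussianMixtureModel(
        weights=np.asarray(weights, float)[order],
        means=np.asarray(means, float)[order],
        variances=np.asarray(variances, float)[order],
        log_likelihood=0.0,
        n_iterations=0,
        converged=True,
    )


def grid_search_valley(gmm, lo, hi, step):
    """Brute-force mixture-density minimization (the independent oracle)."""
    grid = np.arange(lo + step, hi, step)
    return grid[np.argmin(gmm.pdf(grid))]


class TestHistogram:
    def test_exact_binning(self):
        vol = GrayVolume(
            np.array([5.0] * 8 + [10.0] * 8).reshape(2, 2, 4), spacing=[1] * 3
        )
        hist = compute_histogram(vol, n_bins=8)
        assert hist.counts.sum() == 16
        two = compute_histogram(vol, n_bins=8)
        # 8 bins spanning [5, 10]: all 5s in the first bin, all 10s in the last
        assert two.counts[0] == 8 and two.counts[-1] == 8

    def test_count_conservation(self, prep_gray):
        hist = compute_histogram(prep_gray, n_bins=256)
        assert hist.counts.sum() == prep_gray.voxels.size

    def test_constant_volume_rejected(self):
        vol = GrayVolume(np.full((3, 3, 3), 7.0), spacing=[1] * 3)
        with pytest.raises(ValueError, match="constant"):
            compute_histogram(vol)

    def test_two_class_phantom_is_bimodal(self, pure_two_class_gray):
        _occ, gray = pure_two_class_gray
        hist = compute_histogram(gray, n_bins=64)
        smooth = np.convolve(hist.counts, np.ones(3) / 3, mode="valid")
        n_maxima = sum(
            1
            for i in range(1, smooth.size - 1)
            if smooth[i] > smooth[i - 1] and smooth[i] > smooth[i + 1]
        )
        assert n_maxima == 2

    def test_invalid_histograms_rejected(self):
        with pytest.raises(ValueError):
            Histogram([0, 1, 1, 2], [1, 1, 1])
        with pytest.raises(ValueError):
            Histogram([0, 1, 2], [0, 0])


class TestEMFit:
    def test_k1_closed_form(self, rng):
        counts = rng.integers(1, 50, size=32).astype(float)
        edges = np.linspace(-10, 30, 33)
        hist = Histogram(edges, counts)
        gmm = fit_gmm_em(hist, k=1)
        x = hist.centers
        mean = np.average(x, weights=counts)
        var = np.average((x - mean) ** 2, weights=counts)
        assert gmm.means[0] == pytest.approx(mean, abs=1e-9)
        assert gmm.variances[0] == pytest.approx(var, rel=1e-9)
        assert gmm.weights[0] == 1.0

    def test_recovers_generative_two_gaussian_mixture(self):
        rng = np.random.default_rng(123)
        samples = np.concatenate(
            [rng.normal(0.0, 40.0, 500_000), rng.normal(700.0, 40.0, 500_000)]
        )
        counts, edges = np.histogram(samples, bins=256)
        gmm = fit_gmm_em(Histogram(edges, counts.astype(float)), k=2)
        assert abs(gmm.means[0] - 0.0) < 5
        assert abs(gmm.means[1] - 700.0) < 5
        assert abs(gmm.weights[0] - 0.5) < 0.02
        assert np.all(np.diff(gmm.ll_history) >= -1e-7 * np.abs(gmm.ll_history[:-1]))

    def test_log_likelihood_monotone_on_fixtures(self, prep_gray, rng):
        fixtures = [compute_histogram(prep_gray, 128)]
        for _ in range(3):
            counts = rng.integers(0, 100, size=64).astype(float)
            counts[counts.argmin()] = 1  # keep total positive
            fixtures.append(Histogram(np.linspace(0, 64, 65), counts))
        for hist in fixtures:
            for k in (1, 2, 3):
                gmm = fit_gmm_em(hist, k=k)
                diffs = np.diff(gmm.ll_history)
                assert np.all(diffs >= -1e-7 * np.abs(gmm.ll_history[:-1]))

    def test_canonical_ascending_means(self, prep_gray):
        gmm = fit_gmm_em(compute_histogram(prep_gray, 256), k=3)
        assert np.all(np.diff(gmm.means) >= 0)
        assert gmm.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_k_exceeding_nonempty_bins_rejected(self):
        hist = Histogram([0, 1, 2, 3, 4, 5, 6, 7, 8], [5, 0, 0, 3, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="nonempty"):
            fit_gmm_em(hist, k=3)

    def test_parameter_recovery_unbiased_over_seeds(self, prep_mesh):
        """EM means across seeded phantoms are unbiased for the generative
        class means (within 2 standard errors over 20 replicates)."""
        occ = voxelize_impression(prep_mesh, bbox_margin=1.0, spacing=0.2,
                                  supersample_factor=1)
        est = []
        for seed in range(20):
            gray = render_intensities(occ, IntensityModel(noise_seed=seed))
            gmm = fit_gmm_em(compute_histogram(gray, 128), k=2)
            est.append(gmm.means)
        est = np.array(est)
        for j, truth in enumerate((0.0, 700.0)):
            se = est[:, j].std(ddof=1) / np.sqrt(len(est))
            assert abs(est[:, j].mean() - truth) < max(2 * se, 0.5)


class TestValley:
    def test_symmetric_mixture_gives_midpoint(self):
        gmm = make_gmm([0.5, 0.5], [0.0, 700.0], [40.0**2, 40.0**2])
        assert estimate_valley(gmm) == pytest.approx(350.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        gmm = make_gmm([0.5, 0.5], [0.0, 700.0], [40.0**2, 80.0**2])
        step = (700.0 / 256) / 100  # fine grid: bin width / 100
        oracle = grid_search_valley(gmm, 0.0, 700.0, step)
        assert abs(estimate_valley(gmm) - oracle) <= step

    def test_invariant_to_remote_third_component(self):
        gmm3 = make_gmm(
            [0.45, 0.45, 0.10], [0.0, 700.0, 1500.0], [40.0**2, 80.0**2, 50.0**2]
        )
        step = (700.0 / 256) / 100
        oracle = grid_search_valley(gmm3, 0.0, 700.0, step)
        assert abs(estimate_valley(gmm3) - oracle) <= step
        gmm2 = make_gmm([0.5, 0.5], [0.0, 700.0], [40.0**2, 80.0**2])
        assert estimate_valley(gmm3) == pytest.approx(estimate_valley(gmm2), abs=1.0)

    def test_single_component_rejected(self):
        gmm = make_gmm([1.0], [100.0], [25.0])
        with pytest.raises(ValueError):
            estimate_valley(gmm)

    def test_overlapping_components_not_separable(self):
        gmm = make_gmm([0.5, 0.5], [100.0, 101.0], [40.0**2, 40.0**2])
        with pytest.raises(ValueError, match="not separable"):
            estimate_valley(gmm)


class TestCalibration:
    def test_zero_offset_is_identity(self):
        gmm = make_gmm([0.5, 0.5], [0.0, 700.0], [1600.0, 1600.0])
        res = calibrate_threshold(350.0, CalibrationRecord(offset=0.0), gmm)
        assert res.threshold == res.valley == 350.0

    def test_offset_beyond_material_mean_rejected(self):
        gmm = make_gmm([0.5, 0.5], [0.0, 700.0], [1600.0, 1600.0])
        bad = CalibrationRecord(offset=(700.0 - 350.0) + 1.0)
        with pytest.raises(ValueError, match="implausible"):
            calibrate_threshold(350.0, bad, gmm)

    def test_json_round_trip(self, tmp_path):
        rec = CalibrationRecord("light-body PVS", -12.5, "reference scan")
        path = rec.to_json(tmp_path / "cal.json")
        back = CalibrationRecord.from_json(path)
        assert back == rec


@pytest.fixture(scope="module")
def small_phantom():
    spec = PrepSpec(abutment_height=2.0, margin_radius=2.2, chamfer_depth=0.3)
    mesh = make_prep_mesh(spec)
    return spec, mesh


class TestFitCalibration:
    def test_unbiased_phantom_offset_small(self, small_phantom):
        """Without partial-volume skew the fitted offset is a negligible
        fraction of the air/material class separation."""
        _spec, mesh = small_phantom
        occ = voxelize_impression(mesh, bbox_margin=1.0, spacing=0.1,
                                  supersample_factor=1)
        gray = render_intensities(occ, IntensityModel(noise_seed=3))
        cal = fit_calibration(gray, mesh, span=0.9)
        assert abs(cal.offset) < 0.01 * 700.0

    def test_partial_volume_needs_nonzero_offset(self, small_phantom):
        _spec, mesh = small_phantom
        occ = voxelize_impression(mesh, bbox_margin=1.0, spacing=0.1,
                                  supersample_factor=3)
        gray = render_intensities(occ, IntensityModel(noise_seed=3))
        cal = fit_calibration(gray, mesh, span=0.9)
        hist = compute_histogram(gray, 256)
        assert abs(cal.offset) > hist.bin_width

        # the fitted offset must reduce the surface error vs offset 0
        from i2m.segmentation import auto_threshold

        def surface_error(offset):
            thr, _ = auto_threshold(gray, calibration=CalibrationRecord(offset=offset))
            iso = extract_isosurface(gray, thr.threshold)
            return float(np.mean(unsigned_distances(iso.vertices[::5], mesh)))

        assert surface_error(cal.offset) < surface_error(0.0)

    def test_deterministic(self, small_phantom):
        _spec, mesh = small_phantom
        occ = voxelize_impression(mesh, bbox_margin=1.0, spacing=0.15,
                                  supersample_factor=2)
        gray = render_intensities(occ, IntensityModel(noise_seed=5))
        a = fit_calibration(gray, mesh, span=0.9)
        b = fit_calibration(gray, mesh, span=0.9)
        assert a.offset == b.offset


class TestSegment:
    def test_threshold_below_min_selects_everything(self, prep_gray):
        mask = segment(prep_gray, prep_gray.voxels.min() - 1.0)
        assert mask.all()

    def test_monotone_in_threshold(self, prep_gray):
        thresholds = np.linspace(prep_gray.voxels.min(), prep_gray.voxels.max(), 9)
        counts = [segment(prep_gray, t).sum() for t in thresholds]
        assert np.all(np.diff(counts) <= 0)

    def test_mask_volume_matches_generative_occupancy(
        self, prep_occupancy, prep_gray, calibration_default_noise
    ):
        """At the calibrated threshold the segmented material volume agrees
        with the generative partial-volume occupancy within 2%."""
        from i2m.segmentation import auto_threshold

        thr, _ = auto_threshold(prep_gray, calibration=calibration_default_noise)
        mask = segment(prep_gray, thr.threshold)
        true_volume = prep_occupancy.voxels.sum()
        assert abs(mask.sum() - true_volume) / true_volume <= 0.02


class TestAreaOfConversion:
    def test_speckles_removed(self, rng):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[5:27, 6:28, 7:29] = True  # ~10^4 voxel block
        for _ in range(5):
            x, y, z = rng.integers(31, 38, size=3)
            mask[x : x + 2, y : y + 2, z : z + 2] = True  # speckles < 10 voxels
        cropped, offset = area_of_conversion(mask)
        assert cropped.sum() == 22 * 22 * 22
        assert np.array_equal(offset, [3, 4, 5])

    def test_idempotent_on_single_component(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[4:9, 5:10, 6:11] = True
        cropped, offset = area_of_conversion(mask)
        assert cropped.sum() == mask.sum()
        again, off2 = area_of_conversion(cropped)
        assert again.sum() == cropped.sum()

    def test_matches_brute_force_flood_fill(self, rng):
        mask = rng.random((12, 12, 12)) < 0.25

        def flood_sizes(m):
            """Hand-rolled BFS over 26-neighbourhoods."""
            seen = np.zeros_like(m, dtype=bool)
            sizes = []
            offsets = [
                (dx, dy, dz)
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)
            ]
            for start in zip(*np.nonzero(m)):
                if seen[start]:
                    continue
                stack, size = [start], 0
                seen[start] = True
                while stack:
                    x, y, z = stack.pop()
                    size += 1
                    for dx, dy, dz in offsets:
                        p = (x + dx, y + dy, z + dz)
                        if (
                            0 <= p[0] < m.shape[0]
                            and 0 <= p[1] < m.shape[1]
                            and 0 <= p[2] < m.shape[2]
                            and m[p]
                            and not seen[p]
                        ):
                            seen[p] = True
                            stack.append(p)
                sizes.append(size)
            return sizes

        if not mask.any():
            pytest.skip("degenerate draw")
        cropped, _ = area_of_conversion(mask)
        assert cropped.sum() == max(flood_sizes(mask))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            area_of_conversion(np.zeros((5, 5, 5), dtype=bool))
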