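import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletmito._geometry import polygon_to_mask, regular_polygon
from isletmito.io import CellAnnotation, TimeLapseStack, ValidationError
from isletmito.motility import (MotilityMap, NormalizedCell, analyze_movie,
                                classify_cells, motility_result,
                                normalize_to_cell_max, qc_sd_vs_mean,
                                radial_line_profiles, segment_nucleus,
                                temporal_sd_projection)
from isletmito.synthetic import MovieConfig, simulate_movie


def brute_force_sd(frames: np.ndarray) -> np.ndarray:
    """Independent two-pass per-pixel sample SD (pure python accumulation)."""
    t, h, w = frames.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            vals = [float(frames[k, i, j]) for k in range(t)]
            m = sum(vals) / t
            out[i, j] = math.sqrt(sum((v - m) ** 2 for v in vals) / (t - 1))
    return out


def make_stack(frames, pixel_size=0.2, channels=("mito",)):
    data = np.asarray(frames, dtype=float)
    return TimeLapseStack(data=data, pixel_size_um=pixel_size,
                          frame_interval_s=5.0, channels=channels)


class TestTemporalSdProjection:
    def test_identical_frames_give_zero_sd(self):
        stack = make_stack(np.tile(np.arange(12.0).reshape(3, 4), (4, 1, 1)))
        assert temporal_sd_projection(stack, "mito").sd_image.max() == 0.0

    def test_two_point_pixel_matches_hand_computation(self):
        # values {0, 2}: mean 1, sample variance 2, SD = sqrt(2)
        frames = np.zeros((2, 1, 1))
        frames[1, 0, 0] = 2.0
        mm = temporal_sd_projection(make_stack(frames), "mito")
        assert mm.sd_image[0, 0] == pytest.approx(np.sqrt(2), rel=1e-12)
        assert mm.mean_image[0, 0] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_stack(self):
        rng = np.random.default_rng(17)
        frames = rng.uniform(0, 500, (18, 32, 32))
        mm = temporal_sd_projection(make_stack(frames), "mito")
        ref = brute_force_sd(frames)
        assert np.allclose(mm.sd_image, ref, rtol=1e-10, atol=0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(t=st.integers(2, 32), h=st.integers(1, 64), w=st.integers(1, 64),
           seed=st.integers(0, 10_000))
    def test_oracle_equivalence_property(self, t, h, w, seed):
        rng = np.random.default_rng(seed)
        frames = rng.uniform(0, 100, (t, h, w))
        mm = temporal_sd_projection(make_stack(frames), "mito")
        assert np.allclose(mm.sd_image, brute_force_sd(frames),
                           rtol=1e-10, atol=1e-12)

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            temporal_sd_projection(make_stack(np.ones((1, 4, 4))), "mito")

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            temporal_sd_projection(make_stack(np.ones((3, 4, 4))), "gfp")


class TestSegmentNucleus:
    def test_clean_alpha_nucleus_matches_truth_within_one_pixel(self, clean_alpha_movie):
        stack, ann, gt = clean_alpha_movie
        for cell, gtc in zip(ann, gt.cells):
            mask = segment_nucleus(stack, cell, mode="gfp")
            truth = polygon_to_mask(gtc.nucleus_polygon, stack.frame_shape)
            from scipy import ndimage
            band = ndimage.binary_dilation(truth) & ~ndimage.binary_erosion(truth)
            assert not (mask ^ truth)[~band].any()

    def test_uniform_nuclear_channel_raises_not_found(self):
        data = np.zeros((3, 2, 30, 30))
        data[:, 0] = 5.0
        stack = make_stack(data, channels=("mito", "nuclear"))
        cell = CellAnnotation(cell_id="c", polygon=regular_polygon(15, 15, 12))
        with pytest.raises(ValidationError, match="nucleus not found"):
            segment_nucleus(stack, cell, mode="gfp")

    def test_manual_threshold_above_max_rejected(self, clean_alpha_movie):
        stack, ann, _ = clean_alpha_movie
        with pytest.raises(ValidationError, match="threshold"):
            segment_nucleus(stack, ann.cells[0], mode="gfp",
                            manual_threshold=1e9)

    def test_mito_inverse_finds_dark_hole(self):
        # bright cytosol ring with a dark nucleus hole, no marker channel
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        cell_disk = (xx - 20) ** 2 + (yy - 20) ** 2 <= 15 ** 2
        nucleus = (xx - 20) ** 2 + (yy - 20) ** 2 <= 5 ** 2
        img[cell_disk] = 100.0
        img[nucleus] = 1.0
        stack = make_stack(np.tile(img, (2, 1, 1)))
        cell = CellAnnotation(cell_id="c", polygon=regular_polygon(20, 20, 15))
        mask = segment_nucleus(stack, cell, mode="mito_inverse",
                               mito_channel="mito")
        assert (mask & nucleus).sum() / nucleus.sum() > 0.9
        assert (mask & ~nucleus).sum() < 0.1 * nucleus.sum()


class TestClassifyCells:
    def test_noise_free_classification_matches_truth(self, clean_alpha_movie):
        stack, ann, gt = clean_alpha_movie
        for cell in ann:
            segment_nucleus(stack, cell, mode="gfp")
        classify_cells(stack, ann, threshold_mode="fixed", fixed_threshold=100)
        for cell, gtc in zip(ann, gt.cells):
            assert cell.cell_class == gtc.cell_class

    def test_mixed_population_otsu_matches_truth(self):
        stack, ann, gt = simulate_movie(MovieConfig(
            seed=31, n_cells=4, n_frames=6, alpha_fraction=0.5))
        for cell in ann:
            cell.nucleus_mask = polygon_to_mask(cell.nucleus_polygon,
                                                stack.frame_shape)
        classify_cells(stack, ann, threshold_mode="otsu_global")
        for cell, gtc in zip(ann, gt.cells):
            assert cell.cell_class == gtc.cell_class

    def test_zero_channel_fixed_threshold_all_non_alpha(self):
        data = np.zeros((2, 2, 30, 30))
        stack = make_stack(data, channels=("mito", "nuclear"))
        cell = CellAnnotation(cell_id="c", polygon=regular_polygon(15, 15, 12),
                              nucleus_polygon=regular_polygon(15, 15, 4))
        from isletmito.io import AnnotationSet
        ann = AnnotationSet(cells=[cell], pixel_size_um=0.2,
                            image_shape=(30, 30))
        classify_cells(stack, ann, threshold_mode="fixed", fixed_threshold=1.0)
        assert cell.cell_class == "non_alpha"
        classify_cells(stack, ann, threshold_mode="fixed", fixed_threshold=0.0)
        assert cell.cell_class == "alpha"

    def test_otsu_global_needs_two_cells(self):
        data = np.zeros((2, 2, 30, 30))
        stack = make_stack(data, channels=("mito", "nuclear"))
        cell = CellAnnotation(cell_id="c", polygon=regular_polygon(15, 15, 12),
                              nucleus_polygon=regular_polygon(15, 15, 4))
        from isletmito.io import AnnotationSet
        ann = AnnotationSet(cells=[cell], pixel_size_um=0.2,
                            image_shape=(30, 30))
        with pytest.raises(ValidationError, match="fixed"):
            classify_cells(stack, ann, threshold_mode="otsu_global")


class TestNormalization:
    def _map(self, sd):
        return MotilityMap(sd_image=sd, mean_image=np.ones_like(sd),
                           n_frames=2, channel="mito")

    def test_max_maps_to_one(self):
        sd = np.zeros((30, 30))
        sd[10, 10] = 7.5
        sd[12, 12] = 3.0
        cell = CellAnnotation(cell_id="c", polygon=regular_polygon(15, 15, 12))
        norm = normalize_to_cell_max(self._map(sd), cell)
        assert norm.max_raw_sd == 7.5
        assert norm.norm_image[10, 10] == 1.0
        assert norm.norm_image[12, 12] == pytest.approx(0.4)

    def test_all_zero_sd_flagged_degenerate_not_nan(self):
        cell = CellAnnotation(cell_id="c", polygon=regular_polygon(15, 15, 12))
        norm = normalize_to_cell_max(self._map(np.zeros((30, 30))), cell)
        assert norm.degenerate
        assert np.all(norm.norm_image == 0.0)
        assert np.all(np.isfinite(norm.norm_image))

    def test_intensity_scale_invariance_through_pipeline(self):
        cfg = MovieConfig(seed=41, n_cells=1, n_frames=6, poisson=False,
                          gaussian_sigma=0.0, alpha_fraction=1.0)
        stack, ann, _ = simulate_movie(cfg)
        scaled = TimeLapseStack(data=stack.data * 3.0, pixel_size_um=0.2,
                                frame_interval_s=5.0,
                                channels=stack.channels)
        cell = ann.cells[0]
        n1 = normalize_to_cell_max(temporal_sd_projection(stack, "mito"), cell)
        n2 = normalize_to_cell_max(temporal_sd_projection(scaled, "mito"), cell)
        assert np.allclose(n1.norm_image, n2.norm_image, rtol=1e-10, atol=1e-12)
        assert n2.max_raw_sd == pytest.approx(3 * n1.max_raw_sd, rel=1e-12)


def _disk_cell(cell_r_um=12.0, nuc_r_um=4.0, px=0.2, value=None):
    """Circular cell with concentric nucleus on a uniform normalized image."""
    r_px = cell_r_um / px
    c = int(r_px) + 8
    shape = (2 * c, 2 * c)
    cell = CellAnnotation(cell_id="disk",
                          polygon=regular_polygon(c, c, r_px, n=180),
                          nucleus_polygon=regular_polygon(c, c, nuc_r_um / px, n=90))
    cell.nucleus_mask = polygon_to_mask(cell.nucleus_polygon, shape)
    img = np.zeros(shape) if value is None else np.full(shape, value)
    norm = NormalizedCell(norm_image=img, max_raw_sd=1.0,
                          cell_mask=polygon_to_mask(cell.polygon, shape))
    return cell, norm


class TestRadialProfiles:
    @pytest.mark.parametrize("theta,expected", [(10.0, 36), (1.0, 360)])
    def test_candidate_line_count_is_360_over_theta(self, theta, expected):
        cell, norm = _disk_cell()
        prof = radial_line_profiles(norm, cell, 0.2, theta_deg=theta)
        assert prof.n_candidate_lines == expected
        assert prof.n_candidate_lines * theta == 360

    def test_concentric_disk_retains_all_36_lines(self):
        # span 12 - 4 = 8 um >= 7 um on every ray
        cell, norm = _disk_cell()
        prof = radial_line_profiles(norm, cell, 0.2, theta_deg=10.0)
        assert prof.n_retained == 36

    def test_small_cell_retains_no_lines(self):
        cell, norm = _disk_cell(cell_r_um=8.0, nuc_r_um=4.0)  # span 4 < 7
        prof = radial_line_profiles(norm, cell, 0.2, theta_deg=10.0)
        assert prof.n_retained == 0

    def test_uniform_image_gives_constant_profiles(self):
        cell, norm = _disk_cell(value=0.4)
        prof = radial_line_profiles(norm, cell, 0.2, theta_deg=10.0)
        vals = prof.values[prof.retained]
        assert np.allclose(vals, 0.4, rtol=1e-12)

    def test_distances_span_zero_to_fraction(self):
        cell, norm = _disk_cell()
        prof = radial_line_profiles(norm, cell, 0.2, theta_deg=10.0,
                                    fraction_um=7.0)
        assert prof.distances_um[0] == 0.0
        assert prof.distances_um[-1] == pytest.approx(7.0)

    def test_truncate_mode_keeps_short_rays(self):
        cell, norm = _disk_cell(cell_r_um=8.0, nuc_r_um=4.0, value=0.5)
        prof = radial_line_profiles(norm, cell, 0.2, theta_deg=10.0,
                                    short_ray_mode="truncate")
        assert prof.n_retained == 36
        # samples past the cell boundary stay unset
        assert np.isnan(prof.values[0, -1])

    def test_nondividing_theta_rejected(self):
        cell, norm = _disk_cell()
        with pytest.raises(ValidationError):
            radial_line_profiles(norm, cell, 0.2, theta_deg=7.0)


class TestMotilityResult:
    def test_constant_profiles_give_flat_binned_profile(self):
        cell, norm = _disk_cell(value=0.4)
        prof = radial_line_profiles(norm, cell, 0.2)
        mm = MotilityMap(sd_image=norm.norm_image,
                         mean_image=norm.norm_image, n_frames=2, channel="m")
        res = motility_result(prof, mm, norm, cell)
        assert res.overall_mean == pytest.approx(0.4, rel=1e-12)
        assert np.allclose(res.profile, 0.4, rtol=1e-12)
        assert res.qc_sd_mean_r == pytest.approx(1.0)

    def test_ring_of_elevated_sd_peaks_in_right_bin(self):
        cell, norm = _disk_cell()
        # ring at 5 um beyond the nucleus boundary (4 um radius): r = 9 um
        c = norm.norm_image.shape[0] // 2
        yy, xx = np.mgrid[:norm.norm_image.shape[0], :norm.norm_image.shape[1]]
        r_um = np.hypot(xx - c, yy - c) * 0.2
        norm.norm_image[(r_um > 8.7) & (r_um < 9.3)] = 1.0
        prof = radial_line_profiles(norm, cell, 0.2)
        mm = MotilityMap(sd_image=norm.norm_image,
                         mean_image=np.ones_like(norm.norm_image),
                         n_frames=2, channel="m")
        res = motility_result(prof, mm, norm, cell, bin_width_um=0.5)
        peak_bin = int(np.nanargmax(res.profile))
        assert res.bin_centers_um[peak_bin] == pytest.approx(5.25, abs=0.5)

    def test_no_retained_lines_raises_cell_too_small(self):
        cell, norm = _disk_cell(cell_r_um=8.0, nuc_r_um=4.0)
        prof = radial_line_profiles(norm, cell, 0.2)
        mm = MotilityMap(sd_image=norm.norm_image,
                         mean_image=norm.norm_image, n_frames=2, channel="m")
        with pytest.raises(ValidationError, match="cytosolic fraction"):
            motility_result(prof, mm, norm, cell)


class TestQcSdVsMean:
    def _result(self, cid, r):
        return type("R", (), {"cell_id": cid, "qc_sd_mean_r": r})()

    def test_zero_correlations_flag_nothing(self):
        rep = qc_sd_vs_mean([self._result(f"c{i}", 0.0) for i in range(5)])
        assert rep["flagged"] == []
        assert rep["median_r"] == 0.0

    def test_injected_perfect_correlation_flagged(self):
        results = [self._result(f"c{i}", 0.1) for i in range(4)]
        results.append(self._result("hot", 1.0))
        rep = qc_sd_vs_mean(results)
        assert rep["flagged"] == ["hot"]

    def test_independent_fields_have_near_zero_median(self):
        medians = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rs = []
            for _ in range(6):
                a = rng.normal(size=1000)
                b = rng.normal(size=1000)
                a = (a - a.mean())
                b = (b - b.mean())
                rs.append(float((a * b).sum()
                                / np.sqrt((a * a).sum() * (b * b).sum())))
            medians.append(np.median(rs))
        assert abs(np.median(medians)) < 0.1

    def test_needs_three_cells(self):
        with pytest.raises(ValidationError):
            qc_sd_vs_mean([self._result("a", 0.0)])


class TestPipelineIntegration:
    def test_analyze_movie_produces_row_per_cell(self, small_movie):
        stack, ann, _ = small_movie
        results, table = analyze_movie(stack, ann, classify=True,
                                       fixed_threshold=1000)
        assert len(table.df) == len(ann)
        assert set(table.df["cell_id"]) == {c.cell_id for c in ann}
        assert (table.df["n_lines"] <= 36).all()
        assert table.df["mean_norm_motility"].between(0, 1).all()
        assert table.metadata["theta_deg"] == 10.0

    def test_classification_matches_ground_truth(self, small_movie):
        stack, ann, gt = small_movie
        _, table = analyze_movie(stack, ann, classify=True,
                                 fixed_threshold=1000)
        truth = {c.cell_id: c.cell_class for c in gt.cells}
        got = dict(zip(table.df["cell_id"], table.df["class"]))
        assert got == truth
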