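import numpy as np
import pytest

from hepavessel.evaluation import (
    CaseSummary,
    ObjectMetrics,
    ReferenceAreas,
    assd,
    boundary_points,
    case_metrics,
    circle_coverage,
    hausdorff,
    match_objects,
    object_sensitivity,
    phantom_slice_errors,
    reference_areas,
    relative_area_error,
    roc_curve,
    summarize_case,
    tilted_tube_reference,
)
from hepavessel.image_io import Mask, ValidationError, Volume

FIVE_DIAMETERS = [2.56, 3.84, 5.12, 5.76, 7.69]


class TestCoverageModel:
    @pytest.mark.parametrize("d", FIVE_DIAMETERS)
    @pytest.mark.parametrize("placement", ["corner", "edge", "center"])
    def test_area_conservation(self, d, placement):
        cov = circle_coverage(d, placement)
        assert cov.sum() == pytest.approx(np.pi * (d / 2) ** 2, rel=1e-3)

    def test_worked_example_corner_counts(self):
        cov = circle_coverage(2.56, "corner")
        assert int((cov > 0).sum()) == 12
        assert int((cov >= 0.5).sum()) == 4

    def test_reference_areas_monotone_in_diameter(self):
        refs = [reference_areas(d) for d in FIVE_DIAMETERS]
        for a, b in zip(refs, refs[1:]):
            assert a.optimal <= b.optimal
            assert a.maximum <= b.maximum
            assert a.calculated < b.calculated

    def test_continuous_offset_never_below_supersampled_band(self):
        """Canonical-placement band sanity against an arbitrary offset."""
        ref = reference_areas(5.12)
        cov = circle_coverage(5.12, offset=(0.3, 0.7))
        assert ref.optimal <= (cov >= 0.5).sum() * 1.25  # same order of magnitude
        assert (cov > 0).sum() <= ref.maximum + 4

    def test_tilted_reference_is_elliptical(self):
        circ = reference_areas(5.12)
        ell = tilted_tube_reference(5.12, 30.0)
        assert ell.calculated == pytest.approx(circ.calculated / np.cos(np.deg2rad(30)), rel=1e-9)
        assert ell.maximum >= circ.maximum


class TestRelativeAreaError:
    def test_zero_inside_band_linear_outside(self):
        ref = ReferenceAreas(optimal=4, maximum=12, calculated=5.147)
        assert relative_area_error(4, ref) == 0.0
        assert relative_area_error(12, ref) == 0.0
        assert relative_area_error(15, ref) == pytest.approx(3 / 5.147 * 100)
        assert relative_area_error(1, ref) == pytest.approx(3 / 5.147 * 100)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            relative_area_error(-1, ReferenceAreas(1, 2, 1.0))

    def test_phantom_slice_errors_excludes_ends(self):
        seg = Mask(np.ones((2, 2, 6), np.uint8))
        ref = ReferenceAreas(optimal=4, maximum=4, calculated=4.0)
        errs = phantom_slice_errors(seg, ref, exclude_end_slices=2)
        assert len(errs) == 2
        assert (errs == 0).all()


class TestObjectMatching:
    def two_object_masks(self):
        ref = np.zeros((12, 12, 1), np.uint8)
        ref[2:5, 2:5, 0] = 1
        ref[8:11, 8:11, 0] = 1
        return Mask(ref)

    def test_identical_masks_hit_rate_100(self):
        ref = self.two_object_masks()
        _, rate = match_objects(ref, ref)
        assert rate == 100.0

    def test_empty_segmentation_hit_rate_0(self):
        ref = self.two_object_masks()
        _, rate = match_objects(Mask(np.zeros((12, 12, 1), np.uint8)), ref)
        assert rate == 0.0

    def test_half_detected(self):
        ref = self.two_object_masks()
        seg = np.zeros((12, 12, 1), np.uint8)
        seg[3, 3, 0] = 1  # overlaps first object only
        _, rate = match_objects(Mask(seg), ref)
        assert rate == 50.0

    def test_empty_reference_flagged(self):
        seg = Mask(np.ones((4, 4, 1), np.uint8))
        _, rate = match_objects(seg, Mask(np.zeros((4, 4, 1), np.uint8)))
        assert np.isnan(rate)

    def test_object_sensitivity(self):
        a = np.zeros((5, 5), bool)
        a[1:4, 1:4] = True
        assert object_sensitivity(a, a) == 1.0
        assert object_sensitivity(~a, a) == 0.0
        half = a.copy()
        half[1:4, 1] = False
        half[1:4, 2] = False
        assert object_sensitivity(half, a) == pytest.approx(3 / 9)
        with pytest.raises(ValidationError):
            object_sensitivity(a, np.zeros((5, 5), bool))


def brute_force_assd(A, B):
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(A) + len(B))


def brute_force_hausdorff(A, B):
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestSurfaceDistances:
    def test_identical_sets_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert assd(pts, pts) == 0.0
        assert hausdorff(pts, pts) == 0.0

    def test_two_points_closed_form(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[1.0, 0.0]])
        assert assd(a, b) == 1.0
        assert hausdorff(a, b) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 10, (30, 2))
        B = rng.uniform(0, 10, (30, 2))
        assert assd(A, B) == pytest.approx(brute_force_assd(A, B), rel=1e-12)
        assert hausdorff(A, B) == pytest.approx(brute_force_hausdorff(A, B), rel=1e-12)
        # symmetry and ordering
        assert assd(A, B) == pytest.approx(assd(B, A))
        assert hausdorff(A, B) == pytest.approx(hausdorff(B, A))
        assert hausdorff(A, B) >= assd(A, B)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError):
            assd(np.empty((0, 2)), np.array([[0.0, 0.0]]))

    def test_boundary_points_of_square(self):
        obj = np.zeros((8, 8), bool)
        obj[2:6, 2:6] = True
        pts = boundary_points(obj)
        assert len(pts) == 12  # 4x4 square: all but the 2x2 interior
        mm = boundary_points(obj, (0.5, 2.0))
        assert mm[:, 0].max() == pytest.approx(5 * 0.5)
        assert mm[:, 1].max() == pytest.approx(5 * 2.0)


class TestRoc:
    def test_perfect_classifier_passes_corner(self):
        rng = np.random.default_rng(1)
        ref_data = (rng.random((10, 10, 4)) < 0.2).astype(np.uint8)
        ref = Mask(ref_data)
        score = Volume(ref_data.astype(float))
        mask = Mask(np.ones((10, 10, 4), np.uint8))
        fpr, tpr = roc_curve(score, ref, mask)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(2)
        shape = (25, 25, 20)  # > 1e4 voxels
        ref = Mask((rng.random(shape) < 0.3).astype(np.uint8))
        score = Volume(rng.normal(size=shape))
        mask = Mask(np.ones(shape, np.uint8))
        fpr, tpr = roc_curve(score, ref, mask)
        auc = np.trapezoid(tpr, fpr)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(3)
        shape = (12, 12, 4)
        ref = Mask((rng.random(shape) < 0.4).astype(np.uint8))
        score = Volume(rng.normal(size=shape))
        mask = Mask(np.ones(shape, np.uint8))
        fpr, tpr = roc_curve(score, ref, mask)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1

    def test_degenerate_reference_rejected(self):
        shape = (4, 4, 2)
        score = Volume(np.zeros(shape))
        mask = Mask(np.ones(shape, np.uint8))
        with pytest.raises(ValidationError):
            roc_curve(score, Mask(np.zeros(shape, np.uint8)), mask)
        with pytest.raises(ValidationError):
            roc_curve(score, Mask(np.ones(shape, np.uint8)), mask)

    def test_debiased_image_dominates_vesselness_scores(self, liver_case, liver_config):
        """Thresholding the de-biased image can reach higher sensitivity than
        thresholding the vesselness map at matched specificity."""
        from hepavessel.preprocess import apply_mask, remove_bias, resample_isotropic, resample_to_spacing
        from hepavessel.vesselness import frangi_multiscale

        vol, liver = liver_case["volume"], liver_case["liver"]
        truth = liver_case["truth"]
        deb = remove_bias(vol, liver)
        iso = resample_isotropic(apply_mask(deb, liver))
        nu = resample_to_spacing(frangi_multiscale(iso, liver_config), vol.spacing, shape=vol.shape)
        ref = Mask(truth.mask_optimal.data, vol.spacing)
        score_int = Volume(-deb.data, vol.spacing)  # dark vessels: lower = more vessel-like
        score_nu = Volume(np.clip(nu.data, 0, 1), vol.spacing)
        f_i, t_i = roc_curve(score_int, ref, liver)
        f_n, t_n = roc_curve(score_nu, ref, liver)
        grid = np.linspace(0.05, 0.3, 6)
        ti = np.interp(grid, f_i, t_i)
        tn = np.interp(grid, f_n, t_n)
        assert (ti >= tn).mean() >= 0.8  # intensity scores dominate


class TestSummaries:
    def make_metrics(self, s, a, h):
        return ObjectMetrics(sensitivity=s, assd_px=a, assd_mm=a, hausdorff_px=h, hausdorff_mm=h)

    def test_single_object_summary(self):
        m = self.make_metrics(0.9, 1.0, 3.0)
        out = summarize_case([m], hit_rate=100.0)
        assert out.median_sensitivity == pytest.approx(90.0)
        assert out.median_assd_px == 1.0 and out.median_hausdorff_px == 3.0
        assert out.object_count == 1

    def test_odd_length_exact_middle(self):
        ms = [self.make_metrics(s, s, s) for s in (0.1, 0.5, 0.9)]
        out = summarize_case(ms, 50.0)
        assert out.median_sensitivity == pytest.approx(50.0)

    def test_median_robust_to_outlier(self):
        ms = [self.make_metrics(0.9, 1.0, 2.0) for _ in range(4)]
        ms.append(self.make_metrics(0.0, 99.0, 99.0))
        out = summarize_case(ms, 80.0)
        assert out.median_assd_px == 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            summarize_case([], 0.0)

    def test_case_metrics_self_comparison(self):
        data = np.zeros((16, 16, 2), np.uint8)
        data[3:8, 3:8, :] = 1
        data[10:14, 10:14, 1] = 1
        m = Mask(data, (1.188, 1.188, 3.0))
        out = case_metrics(m, m)
        assert out.hit_rate == 100.0
        assert out.median_sensitivity == 100.0
        assert out.median_assd_px == 0.0 and out.median_hausdorff_mm == 0.0
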