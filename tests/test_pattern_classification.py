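import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromadens.densitometry import AlteredRegionSet
from chromadens.head_segmentation import SpermHead
from chromadens.imaging_io import IntensityImage, Micrograph, Stain
from chromadens.pattern_classification import (
    AOHeadObservation,
    Category,
    EmptySampleError,
    GeometryError,
    PatternCall,
    PatternRules,
    TEMGrade,
    TEMHeadObservation,
    UnstainedHeadError,
    classify_ao,
    classify_pattern,
    detect_clear_regions,
    grade_tem,
    head_axes,
    region_partition,
    summarize_smear,
)
from chromadens.phantom import PhantomSpec, generate_phantom, stamp_pattern
from conftest import rasterize_ellipse


def head_from_mask(mask, label=1):
    coords = np.argwhere(mask)
    return SpermHead(
        label=label, mask=mask, bbox=(0, 0, *mask.shape), image_shape=mask.shape,
        centroid=(coords[:, 0].mean(), coords[:, 1].mean()),
        area_px=int(mask.sum()), mean_intensity=0.5, cv_intensity=0.0,
    )


class TestHeadAxes:
    def test_axis_aligned_ellipse_dimensions(self):
        mask = rasterize_ellipse(40, 20)
        frame = head_axes(head_from_mask(mask))
        assert frame.length_px == pytest.approx(80, rel=0.05)
        assert frame.width_px == pytest.approx(40, rel=0.05)
        # major axis along rows for this construction
        assert abs(frame.major_axis @ np.array([1.0, 0.0])) > 0.99

    def test_circle_is_ambiguous(self):
        mask = rasterize_ellipse(15, 15)
        frame = head_axes(head_from_mask(mask))
        assert frame.ambiguous_base
        assert frame.length_px == pytest.approx(frame.width_px, rel=0.05)

    def test_paddle_base_points_to_broad_end(self):
        from chromadens.phantom import _paddle_mask

        theta = 0.4
        mask, _ = _paddle_mask(a=28, b=14, theta=theta, taper=0.35)
        frame = head_axes(head_from_mask(mask))
        assert not frame.ambiguous_base
        # generator's +u direction points base -> apex with base at u = -a
        d = np.array([np.cos(theta), np.sin(theta)])
        assert frame.major_axis @ d > 0.9

    def test_collinear_mask_is_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 2:8] = True
        with pytest.raises(GeometryError):
            head_axes(head_from_mask(mask))


class TestRegionPartition:
    def test_rectangle_quartiles_equal_within_one_row(self):
        mask = np.zeros((60, 40), dtype=bool)
        mask[10:50, 5:35] = True  # 40 rows x 30 cols
        head = head_from_mask(mask)
        part = region_partition(head_axes(head), head)
        areas = [len(q) for q in part.quartiles]
        assert max(areas) - min(areas) <= 30  # one pixel-row of 30 columns

    def test_partition_covers_mask_disjointly(self):
        mask = rasterize_ellipse(25, 12)
        head = head_from_mask(mask)
        part = region_partition(head_axes(head), head)
        union = np.concatenate(part.quartiles)
        assert len(union) == len(set(union.tolist())) == head.area_px
        assert set(union.tolist()) == set(head.linear_indices().tolist())

    def test_axial_band_of_rectangle(self):
        mask = np.zeros((70, 44), dtype=bool)
        mask[5:65, 7:37] = True  # length 60, width 30 -> band half-height 5
        head = head_from_mask(mask)
        frame = head_axes(head)
        part = region_partition(frame, head)
        # |v| <= 30/6 = 5 selects 10 pixel rows (offsets are half-integers)
        assert len(part.axial_band) == pytest.approx(60 * 10, rel=0.05)
        assert set(part.axial_band.tolist()) <= set(head.linear_indices().tolist())


def ars_from_mask(altered, head, min_component_px=1, tau=0.07):
    from scipy import ndimage

    labels, n = ndimage.label(altered, structure=np.ones((3, 3), dtype=int))
    comps = [np.argwhere(labels == i) for i in range(1, n + 1)]
    return AlteredRegionSet(
        head_label=head.label, components=comps, altered_mask=altered,
        bbox=head.bbox, image_shape=head.image_shape,
        head_area_px=head.area_px,
        altered_fraction=float(altered.sum()) / head.area_px,
        tau=tau, min_component_px=min_component_px,
    )


class TestClassifyPattern:
    def _classify_stamp(self, category, seed=0):
        rng = np.random.default_rng(seed)
        from chromadens.phantom import _paddle_mask

        mask, _ = _paddle_mask(a=28, b=14, theta=0.7, taper=0.3)
        head = head_from_mask(mask)
        stamp = stamp_pattern(mask, head.bbox, head.image_shape, category, rng)
        part = region_partition(head_axes(head), head)
        return classify_pattern(ars_from_mask(stamp, head), part)

    def test_zero_altered_fraction_is_normal(self):
        mask = rasterize_ellipse(25, 12)
        head = head_from_mask(mask)
        part = region_partition(head_axes(head), head)
        call = classify_pattern(ars_from_mask(np.zeros_like(mask), head), part)
        assert call.category is Category.N

    def test_whole_head_altered_is_total_decompaction(self):
        mask = rasterize_ellipse(25, 12)
        head = head_from_mask(mask)
        part = region_partition(head_axes(head), head)
        call = classify_pattern(ars_from_mask(mask.copy(), head), part)
        assert call.category is Category.TD

    @pytest.mark.parametrize("category", ["BD", "BHD", "CAD", "BAD", "TD", "DD"])
    def test_stamped_templates_recover_their_category(self, category):
        call = self._classify_stamp(category)
        assert call.category.value == category

    def test_exactly_one_category_and_determinism(self):
        c1 = self._classify_stamp("BAD", seed=4)
        c2 = self._classify_stamp("BAD", seed=4)
        assert c1.category == c2.category
        assert isinstance(c1.category, Category)

    def test_basal_and_apical_coverage_drive_bad(self):
        call = self._classify_stamp("BAD")
        f = call.features
        assert f["quartile_coverage"][0] >= 0.25
        assert f["quartile_coverage"][3] >= 0.25


class TestDetectClearRegions:
    def _tem_scene(self):
        mask = rasterize_ellipse(25, 13)
        values = np.where(mask, 0.25, 0.75)
        return mask, values

    def test_two_small_spots(self):
        mask, values = self._tem_scene()
        head = head_from_mask(mask)
        spot = rasterize_ellipse(1.6, 1.6, pad=0)  # ~9 px, ~1% of head
        for r0 in (15, 30):
            values[r0:r0 + spot.shape[0], 10:10 + spot.shape[1]][spot] = 0.8
        obs = detect_clear_regions(IntensityImage(values, Stain.TEM), head)
        assert obs.n_clear_spots == 2 and obs.largest_clear_fraction == 0.0

    def test_large_region_fraction(self):
        mask, values = self._tem_scene()
        head = head_from_mask(mask)
        rows = np.argwhere(mask)[:, 0]
        cut = np.quantile(rows, 0.4)
        region = mask & (np.arange(mask.shape[0])[:, None] <= cut)
        values[region] = 0.8
        obs = detect_clear_regions(IntensityImage(values, Stain.TEM), head)
        assert obs.n_clear_spots == 0
        assert obs.largest_clear_fraction == pytest.approx(0.4, abs=0.03)

    def test_uniform_dark_head(self):
        mask, values = self._tem_scene()
        obs = detect_clear_regions(IntensityImage(values, Stain.TEM), head_from_mask(mask))
        assert obs.n_clear_spots == 0 and obs.largest_clear_fraction == 0.0


class TestGradeTEM:
    @pytest.mark.parametrize(
        "n_spots, fraction, expected",
        [
            (0, 0.0, TEMGrade.N0),
            (1, 0.0, TEMGrade.G1),
            (2, 0.0, TEMGrade.G1),
            (3, 0.0, TEMGrade.G1),
            (4, 0.0, TEMGrade.G2),
            (5, 0.0, TEMGrade.G2),
            (6, 0.0, TEMGrade.G2),
            (0, 0.10, TEMGrade.G2),
            (0, 0.25, TEMGrade.G2),
            (7, 0.0, TEMGrade.G3),
            (8, 0.0, TEMGrade.G3),
            (0, 0.30, TEMGrade.G3),
            (0, 0.50, TEMGrade.G3),
            (0, 0.51, TEMGrade.G4),
            (0, 0.60, TEMGrade.G4),
            (2, 0.60, TEMGrade.G4),
        ],
    )
    def test_grading_rules(self, n_spots, fraction, expected):
        obs = TEMHeadObservation(1, n_spots, fraction)
        assert grade_tem(obs) is expected
        assert obs.grade is expected

    _order = [TEMGrade.N0, TEMGrade.G1, TEMGrade.G2, TEMGrade.G3, TEMGrade.G4]

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        n=st.integers(0, 12),
        f=st.floats(0, 1, allow_nan=False),
        dn=st.integers(0, 4),
        df=st.floats(0, 0.5, allow_nan=False),
    )
    def test_grading_monotone_in_both_inputs(self, n, f, dn, df):
        g0 = self._order.index(grade_tem(TEMHeadObservation(1, n, f)))
        g_spots = self._order.index(grade_tem(TEMHeadObservation(1, n + dn, f)))
        g_frac = self._order.index(grade_tem(TEMHeadObservation(1, n, min(1.0, f + df))))
        assert g_spots >= g0
        assert g_frac >= g0


class TestClassifyAO:
    def _micrograph(self, r, g, b=0):
        px = np.zeros((6, 6, 3), dtype=np.uint8)
        px[:, :, 0], px[:, :, 1], px[:, :, 2] = r, g, b
        return Micrograph(px, 8, Stain.AO)

    def _head(self):
        mask = np.ones((6, 6), dtype=bool)
        return head_from_mask(mask)

    def test_pure_green_is_intact(self):
        obs = classify_ao(self._micrograph(0, 204), self._head())
        assert obs.red_fraction == 0.0 and obs.call == "intact"

    def test_pure_red_is_denatured(self):
        obs = classify_ao(self._micrograph(204, 0), self._head())
        assert obs.red_fraction == 1.0 and obs.call == "denatured"

    def test_boundary_is_inclusive(self):
        # equal red and green -> red fraction exactly 0.5; a threshold set
        # right at the measured fraction must still call denatured
        obs = classify_ao(self._micrograph(100, 100), self._head(),
                          red_fraction_threshold=0.5)
        assert obs.red_fraction == 0.5
        assert obs.call == "denatured"
        below = classify_ao(self._micrograph(99, 100), self._head(),
                            red_fraction_threshold=0.5)
        assert below.call == "intact"

    def test_default_threshold_near_boundary(self):
        # R:G = 2:3 sits at the 0.40 onset of yellow/orange
        obs = classify_ao(self._micrograph(102, 153), self._head())
        assert obs.red_fraction == pytest.approx(0.40, abs=1e-12)
        nearly = classify_ao(self._micrograph(90, 153), self._head())
        assert nearly.call == "intact"
        clearly = classify_ao(self._micrograph(120, 153), self._head())
        assert clearly.call == "denatured"

    def test_unstained_head_is_error(self):
        with pytest.raises(UnstainedHeadError):
            classify_ao(self._micrograph(0, 0), self._head())

    def test_more_red_never_flips_to_intact(self):
        base = classify_ao(self._micrograph(110, 140), self._head())
        redder = classify_ao(self._micrograph(160, 140), self._head())
        assert base.call == "denatured"
        assert redder.call == "denatured"


class TestSummarizeSmear:
    def test_pattern_counts_and_percent(self):
        calls = [PatternCall(i, Category.N) for i in range(180)]
        calls += [PatternCall(200 + i, Category.BD) for i in range(20)]
        s = summarize_smear(calls)
        assert s.n_heads == 200
        assert s.counts == {"N": 180, "BD": 20}
        assert s.percent_altered == pytest.approx(10.0)
        assert sum(s.counts.values()) == s.n_heads

    def test_all_normal(self):
        s = summarize_smear([PatternCall(i, Category.N) for i in range(30)])
        assert s.percent_altered == 0.0

    def test_ao_percent(self):
        calls = [AOHeadObservation(i, 0.1, 0.8, 0.1 / 0.9, "intact") for i in range(120)]
        calls += [AOHeadObservation(i, 0.8, 0.2, 0.8, "denatured") for i in range(30)]
        assert summarize_smear(calls).percent_altered == pytest.approx(20.0)

    def test_tem_altered_excludes_n0(self):
        calls = [TEMHeadObservation(1, 0, 0.0), TEMHeadObservation(2, 2, 0.0)]
        s = summarize_smear(calls)
        assert s.percent_altered == pytest.approx(50.0)
        assert s.counts == {"N0": 1, "G1": 1}

    def test_empty_and_mixed_rejected(self):
        with pytest.raises(EmptySampleError):
            summarize_smear([])
        with pytest.raises(ValueError):
            summarize_smear([PatternCall(1, Category.N), TEMHeadObservation(2, 0, 0.0)])
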