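"""Segmentation and morphometry: threshold exactness, sub-pixel centroid
tracking, nucleus boundaries and migration grading."""

import numpy as np
import pytest

from conftest import dice, maps_from_truth, truth_labelmap

from discqmri.phantom import (
    CANAL,
    FissureSpec,
    NUCLEUS,
    PhantomSpec,
    make_phantom,
    simulate_ir_series,
    simulate_me_series,
)
from discqmri.relaxometry import fit_t1_map, fit_t2_map
from discqmri.segmentation import (
    SegmentationError,
    SegmentationOptions,
    centroid,
    fissure_metrics,
    nucleus_boundaries,
    nucleus_geometry,
    segment_disc,
)


class TestThresholdSegmentation:
    def test_exact_value_maps_give_perfect_dice(self, intact_truth):
        """Threshold rule on exact truth-valued maps is a fixed point."""
        t1, t2 = maps_from_truth(intact_truth)
        lm = segment_disc(t1, t2)
        assert dice(lm.labels == NUCLEUS, intact_truth.labels == NUCLEUS) == 1.0
        assert dice(lm.labels == CANAL, intact_truth.labels == CANAL) == 1.0

    def test_segmentation_idempotent_on_own_output(self, fissured_truth):
        t1, t2 = maps_from_truth(fissured_truth)
        lm1 = segment_disc(t1, t2)
        # feed the segmented compartments back as exact-valued maps
        relabelled = make_phantom(fissured_truth.spec)
        relabelled.labels = lm1.labels.copy()
        props = fissured_truth.spec.compartment_props
        for lab, region in [(1, "annulus"), (2, "nucleus"), (3, "canal"), (4, "nucleus")]:
            m = lm1.labels == lab
            relabelled.t1[m], relabelled.t2[m], relabelled.pd[m] = props[region]
        relabelled.pd[lm1.labels == 0] = 0.0
        t1b, t2b = maps_from_truth(relabelled)
        lm2 = segment_disc(t1b, t2b)
        assert np.array_equal(lm1.labels, lm2.labels)

    def test_noiseless_pipeline_dice_is_one(self, intact_truth):
        ir = simulate_ir_series(intact_truth, noise_sigma=0.0, signed=True)
        me = simulate_me_series(intact_truth, noise_sigma=0.0)
        lm = segment_disc(fit_t1_map(ir), fit_t2_map(me))
        assert dice(lm.labels == NUCLEUS, intact_truth.labels == NUCLEUS) == 1.0
        assert dice(lm.labels == CANAL, intact_truth.labels == CANAL) == 1.0

    def test_noisy_pipeline_dice(self, intact_truth):
        for seed in (1, 2):
            ir = simulate_ir_series(intact_truth, seed=seed, signed=False)
            me = simulate_me_series(intact_truth, seed=1000 + seed)
            lm = segment_disc(fit_t1_map(ir), fit_t2_map(me))
            assert dice(lm.labels == NUCLEUS, intact_truth.labels == NUCLEUS) >= 0.95

    def test_no_nucleus_raises(self, intact_truth):
        t1, t2 = maps_from_truth(intact_truth)
        t1.values = np.where(t1.valid_mask, 400.0, np.nan)  # everything annulus-like
        with pytest.raises(SegmentationError, match="no nucleus"):
            segment_disc(t1, t2)


class TestCentroid:
    def test_symmetric_ellipse_centroid_at_center(self, intact_spec, intact_truth):
        lm = truth_labelmap(intact_truth)
        r, c = centroid(lm, NUCLEUS)
        assert r == pytest.approx(intact_spec.disc_center[0], abs=intact_spec.pixel_spacing / 2)
        assert c == pytest.approx(intact_spec.disc_center[1], abs=intact_spec.pixel_spacing / 2)

    @pytest.mark.parametrize("shift", [0.3, 0.7, 2.0])
    def test_subpixel_shift_recovered_within_tenth_pixel(self, shift):
        """Partial-volume boundary signal plus intensity weighting tracks
        imposed sub-pixel nucleus motion to <= 0.1 pixel (0.05 mm)."""
        from discqmri.segmentation import weighted_centroid

        spec = PhantomSpec(partial_volume=True)

        def np_row(shift_ap):
            truth = make_phantom(spec, shift_ap=shift_ap)
            t1, t2 = maps_from_truth(truth)
            lm = segment_disc(t1, t2)
            return weighted_centroid(lm, t1, NUCLEUS)[0]

        recovered = -(np_row(shift) - np_row(0.0))  # anterior positive
        assert recovered == pytest.approx(shift, abs=0.1 * spec.pixel_spacing)
        assert recovered == pytest.approx(shift, abs=0.05)

    def test_absent_label_raises(self, intact_truth):
        lm = truth_labelmap(intact_truth)
        with pytest.raises(SegmentationError):
            centroid(lm, 4)

    def test_single_pixel_region(self, intact_truth):
        lm = truth_labelmap(intact_truth)
        lm.labels[3, 5] = 4
        r, c = centroid(lm, 4)
        s = lm.pixel_spacing
        assert (r, c) == ((3 + 0.5) * s, (5 + 0.5) * s)


class TestBoundaries:
    def test_nucleus_extent_matches_imposed_diameter(self, intact_spec, intact_truth):
        _, _, w = nucleus_boundaries(truth_labelmap(intact_truth))
        assert w == pytest.approx(2 * intact_spec.nucleus_semiaxes[0], abs=intact_spec.pixel_spacing)

    def test_extent_invariant_under_lateral_shift(self, intact_spec):
        base = make_phantom(intact_spec)
        lateral = PhantomSpec(nucleus_center_offset=(0.0, 1.3))
        shifted = make_phantom(lateral)
        _, _, w0 = nucleus_boundaries(truth_labelmap(base))
        _, _, w1 = nucleus_boundaries(truth_labelmap(shifted))
        assert w1 == pytest.approx(w0, abs=intact_spec.pixel_spacing)

    def test_infiltration_extends_extent(self, intact_truth, fissured_truth):
        _, _, w0 = nucleus_boundaries(truth_labelmap(intact_truth))
        _, _, w1 = nucleus_boundaries(truth_labelmap(fissured_truth))
        spec = fissured_truth.spec
        expected_ext = spec.disc_outer_semiaxes[0] - spec.nucleus_semiaxes[0]
        assert w1 - w0 == pytest.approx(expected_ext, abs=2 * spec.pixel_spacing)


class TestMigration:
    def test_intact_migration_zero_grade_0(self, intact_truth):
        m, g = fissure_metrics(truth_labelmap(intact_truth))
        assert m == 0.0 and g == "0"

    @pytest.mark.parametrize("fill,expected,grade", [(0.21, 21.0, "I"), (0.5, 50.0, "I II"), (1.0, 100.0, "II")])
    def test_partial_and_total_migration(self, fissured_truth, fill, expected, grade):
        truth = make_phantom(fissured_truth.spec, infiltration_fraction=fill)
        m, g = fissure_metrics(truth_labelmap(truth))
        spec = truth.spec
        thickness = spec.disc_outer_semiaxes[0] - spec.nucleus_semiaxes[0]
        quant = 100.0 * spec.pixel_spacing / thickness  # one-pixel quantization
        assert m == pytest.approx(expected, abs=1.5 * quant)
        assert g in grade.split()

    def test_noisy_intact_migration_stays_zero(self, intact_truth):
        ir = simulate_ir_series(intact_truth, seed=21, signed=False)
        me = simulate_me_series(intact_truth, seed=22)
        lm = segment_disc(fit_t1_map(ir), fit_t2_map(me))
        m, g = fissure_metrics(lm)
        assert m == 0.0 and g == "0"


def test_nucleus_geometry_summary(fissured_truth):
    g = nucleus_geometry(truth_labelmap(fissured_truth))
    assert g.migration == pytest.approx(100.0, abs=10.0)
    assert g.dallas_like_grade == "II"
    assert g.posterior_boundary > g.anterior_boundary
    assert g.w > 0 and g.annulus_thickness_anterior > 0
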