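"""Phantom generator: geometry, signal models, kinematics imposition."""

import numpy as np
import pytest

from discqmri.phantom import (
    ANNULUS,
    CANAL,
    INFILTRATION,
    NUCLEUS,
    DEFAULT_ECHO_TIMES,
    DEFAULT_INVERSION_TIMES,
    FissureSpec,
    InvalidSpecError,
    PhantomSpec,
    apply_mechanical_state,
    make_marker_frames,
    make_phantom,
    simulate_ir_series,
    simulate_me_series,
)
from discqmri.kinematics import axial_strain, bending_angle


def nucleus_centroid_mm(truth):
    idx = np.argwhere(truth.labels == NUCLEUS)
    return (idx.mean(axis=0) + 0.5) * truth.pixel_spacing


class TestGeometry:
    def test_nucleus_area_matches_analytic_ellipse(self, intact_spec, intact_truth):
        a, b = intact_spec.nucleus_semiaxes
        area_px = (intact_truth.labels == NUCLEUS).sum() * intact_spec.pixel_spacing**2
        analytic = np.pi * a * b
        # rasterization error bounded by ~perimeter x pixel area
        perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        assert abs(area_px - analytic) <= 2 * perimeter * intact_spec.pixel_spacing

    def test_intact_phantom_has_no_infiltration(self, intact_truth):
        assert (intact_truth.labels == INFILTRATION).sum() == 0
        assert intact_truth.imposed_migration == 0.0

    def test_full_fissure_imposes_total_migration(self, fissured_truth):
        assert fissured_truth.imposed_migration == 100.0
        assert (fissured_truth.labels == INFILTRATION).sum() > 0

    def test_truth_maps_constant_within_compartments(self, fissured_truth):
        for lab, region in [(NUCLEUS, "nucleus"), (ANNULUS, "annulus"), (CANAL, "canal")]:
            t1v, t2v, pdv = fissured_truth.spec.compartment_props[region]
            m = fissured_truth.labels == lab
            assert np.all(fissured_truth.t1[m] == t1v)
            assert np.all(fissured_truth.t2[m] == t2v)
        infil = fissured_truth.labels == INFILTRATION
        assert np.all(fissured_truth.t1[infil] == fissured_truth.spec.compartment_props["nucleus"][0])

    def test_overlapping_geometry_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(nucleus_semiaxes=(11.0, 14.0))  # as large as the disc
        with pytest.raises(InvalidSpecError):
            PhantomSpec(canal_center=(25.0, 25.0))  # inside the disc


class TestMechanicalState:
    def test_zero_shift_is_identity(self, fissured_truth):
        out = apply_mechanical_state(fissured_truth, shift_ap=0.0, infiltration_fraction=1.0)
        assert np.array_equal(out.labels, fissured_truth.labels)

    def test_shift_moves_nucleus_centroid(self, intact_truth):
        shifted = apply_mechanical_state(intact_truth, shift_ap=2.0)
        d_row = nucleus_centroid_mm(shifted)[0] - nucleus_centroid_mm(intact_truth)[0]
        # anterior-positive shift decreases the row coordinate
        assert d_row == pytest.approx(-2.0, abs=0.06)
        assert shifted.imposed_nucleus_shift == 2.0

    def test_reduced_infiltration_shrinks_fissure(self, fissured_truth):
        partial = apply_mechanical_state(fissured_truth, infiltration_fraction=0.21)
        n_full = (fissured_truth.labels == INFILTRATION).sum()
        n_part = (partial.labels == INFILTRATION).sum()
        assert 0 < n_part < n_full
        assert partial.imposed_migration == pytest.approx(21.0)

    def test_excessive_shift_rejected(self, intact_truth):
        with pytest.raises(InvalidSpecError):
            apply_mechanical_state(intact_truth, shift_ap=6.0)


class TestSignalSimulation:
    def test_ir_closed_form_on_protocol_schedule(self, intact_truth):
        series = simulate_ir_series(intact_truth, DEFAULT_INVERSION_TIMES,
                                    noise_sigma=0.0, signed=True)
        i, j = np.argwhere(intact_truth.labels == NUCLEUS)[0]
        t1, _, pd = intact_truth.spec.compartment_props["nucleus"]
        for k, ti in enumerate(DEFAULT_INVERSION_TIMES):
            expected = pd * (1.0 - 2.0 * np.exp(-ti / t1))  # independent evaluation
            assert series.frames[k, i, j] == pytest.approx(expected, rel=1e-12)

    def test_ir_null_point_and_asymptote(self, intact_truth):
        t1 = intact_truth.spec.compartment_props["nucleus"][0]
        null = simulate_ir_series(intact_truth, [t1 * np.log(2.0)], noise_sigma=0.0, signed=True)
        i, j = np.argwhere(intact_truth.labels == NUCLEUS)[0]
        assert null.frames[0, i, j] == pytest.approx(0.0, abs=1e-12)
        late = simulate_ir_series(intact_truth, [10.0 * t1], noise_sigma=0.0, signed=True)
        pd = intact_truth.spec.compartment_props["nucleus"][2]
        assert late.frames[0, i, j] == pytest.approx(pd, rel=2.1 * np.exp(-10.0))

    def test_me_geometric_decay(self, intact_truth):
        series = simulate_me_series(intact_truth, DEFAULT_ECHO_TIMES, noise_sigma=0.0)
        assert series.timing[0] == 30.0 and series.timing[-1] == 960.0 and len(series.timing) == 32
        i, j = np.argwhere(intact_truth.labels == NUCLEUS)[0]
        t2, pd = intact_truth.spec.compartment_props["nucleus"][1], intact_truth.spec.compartment_props["nucleus"][2]
        assert series.frames[0, i, j] == pytest.approx(pd * np.exp(-30.0 / t2), rel=1e-12)
        ratios = series.frames[1:, i, j] / series.frames[:-1, i, j]
        assert np.allclose(ratios, np.exp(-30.0 / t2), rtol=1e-12)

    def test_noise_is_seeded_and_reproducible(self, intact_truth):
        a = simulate_me_series(intact_truth, seed=7)
        b = simulate_me_series(intact_truth, seed=7)
        c = simulate_me_series(intact_truth, seed=8)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_nonpositive_timing_rejected(self, intact_truth):
        with pytest.raises(ValueError):
            simulate_ir_series(intact_truth, [-5.0, 30.0])
        with pytest.raises(ValueError):
            simulate_me_series(intact_truth, [])


class TestMarkerFrames:
    def test_identity_frames_give_zero_kinematics(self):
        f0, f = make_marker_frames(4.7, 4.7, 100.0, 100.0)
        assert bending_angle(f, f0) == pytest.approx(0.0, abs=1e-12)
        assert axial_strain(f, f0) == pytest.approx(0.0, abs=1e-12)

    def test_imposed_extension_angle_recovered(self):
        f0, f = make_marker_frames(4.7, 10.4, 100.0, 95.4)
        assert bending_angle(f, f0) == pytest.approx(5.7, abs=1e-9)
        assert axial_strain(f, f0) == pytest.approx(-4.6, abs=1e-9)

    def test_noise_monte_carlo_angle_uncertainty(self):
        # jitter of 0.05 mm on an 80 mm stick: per-frame angle sd
        # ~ sqrt(2)*0.05/80 rad; the frame difference doubles the variance
        errs = []
        for seed in range(100):
            f0, f = make_marker_frames(4.7, 10.4, 100.0, 100.0, noise_mm=0.05, seed=seed)
            errs.append(bending_angle(f, f0) - 5.7)
        rms = float(np.sqrt(np.mean(np.square(errs))))
        predicted = np.degrees(np.sqrt(2.0) * 0.05 / 80.0) * np.sqrt(2.0)
        assert 0.0 < rms < 2.5 * predicted
        assert rms == pytest.approx(predicted, rel=0.5)

    def test_invalid_marker_arguments(self):
        with pytest.raises(ValueError):
            make_marker_frames(0, 0, -1.0, 100.0)
        with pytest.raises(ValueError):
            make_marker_frames(0, 0, 100.0, 100.0, stick_length_mm=0.0)
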