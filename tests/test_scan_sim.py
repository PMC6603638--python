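import dataclasses

import numpy as np
import pytest

from nodulemap.phantom import GeometryError, Phantom, local_stiffness
from nodulemap.scan_sim import (
    AcquisitionConfig,
    echo_model,
    load_dataset,
    point_rngs,
    reference_echo_amplitude,
    render_scene_image,
    save_dataset,
    simulate_ascan,
    simulate_indentation,
    simulate_scan,
)


def slope_after_contact(record, contact_depth):
    sel = record.z_trace > contact_depth + 1e-12
    z = record.z_trace[sel]
    f = record.force_trace[sel]
    return np.polyfit(z, f, 1)[0]


class TestIndentation:
    @pytest.mark.parametrize("k_true", [0.33, 4.6])
    def test_noiseless_slope_equals_true_stiffness(self, k_true, noiseless_config):
        rec = simulate_indentation(k_true, noiseless_config)
        assert slope_after_contact(rec, noiseless_config.contact_depth_mm) == pytest.approx(
            k_true, rel=1e-9
        )

    def test_trigger_travel_matches_ratio(self, noiseless_config):
        """0.2 N at 4.6 N/mm is reached after ~0.0435 mm of post-contact travel."""
        rec = simulate_indentation(4.6, noiseless_config)
        travel = rec.z_trace[rec.trigger_index] - noiseless_config.contact_depth_mm
        dz = noiseless_config.indentation_speed_mm_s / noiseless_config.force_sample_rate_hz
        assert abs(travel - 0.2 / 4.6) <= dz

    def test_noiseless_force_monotone_after_contact(self, noiseless_config):
        rec = simulate_indentation(1.7, noiseless_config)
        assert np.all(np.diff(rec.force_trace) >= 0)

    def test_trace_ends_at_trigger(self, noiseless_config):
        rec = simulate_indentation(0.5, noiseless_config)
        assert rec.trigger_index == len(rec.force_trace) - 1
        assert rec.force_trace[rec.trigger_index] >= noiseless_config.force_trigger_n
        assert np.all(rec.force_trace[:-1] < noiseless_config.force_trigger_n)

    def test_rejects_nonpositive_stiffness(self, noiseless_config):
        with pytest.raises(ValueError):
            simulate_indentation(0.0, noiseless_config)


class TestAScan:
    def test_arrival_time_homogeneous(self, homogeneous_healthy, noiseless_config):
        """Echo arrives at the two-way time of flight 2T/c (~20.59 us)."""
        scan = simulate_ascan(homogeneous_healthy, 50, 30, noiseless_config)
        peak = np.argmax(np.abs(scan.waveform)) / scan.sample_rate_hz
        expected = 2 * 15e-3 / 1457.0
        assert abs(peak - expected) <= 1.0 / scan.sample_rate_hz

    def test_attenuation_log_linearity(self, noiseless_config):
        """Doubling the dB/cm attenuation squares the amplitude ratio A/A0."""
        base = Phantom()
        double = Phantom(
            matrix_material=dataclasses.replace(
                base.matrix_material, attenuation_db_cm=2.5
            )
        )
        a1 = reference_echo_amplitude(base, noiseless_config)
        a2 = reference_echo_amplitude(double, noiseless_config)
        a0 = noiseless_config.pulse_amplitude
        assert a2 / a0 == pytest.approx((a1 / a0) ** 2, rel=1e-12)

    def test_echo_weaker_over_inclusion(self, fixed_phantom, noiseless_config):
        inc = fixed_phantom.inclusions[0]
        over = simulate_ascan(fixed_phantom, inc.center_mm[0], inc.center_mm[1], noiseless_config)
        off = simulate_ascan(fixed_phantom, 50.0, 30.0, noiseless_config)
        assert np.max(np.abs(over.waveform)) < np.max(np.abs(off.waveform))

    def test_air_bubble_restores_amplitude(self, noiseless_config):
        from nodulemap.phantom import Inclusion

        solid = Phantom(inclusions=[Inclusion(center_mm=(50, 30, 7.5), diameter_mm=12)])
        bubbly = Phantom(
            inclusions=[
                Inclusion(
                    center_mm=(50, 30, 7.5),
                    diameter_mm=12,
                    has_air_bubble=True,
                    bubble_fraction=0.9,
                )
            ]
        )
        _, a_solid = echo_model(solid, 50, 30, noiseless_config)
        _, a_bubbly = echo_model(bubbly, 50, 30, noiseless_config)
        a_ref = reference_echo_amplitude(solid, noiseless_config)
        assert a_solid < a_bubbly < a_ref
        assert a_bubbly == pytest.approx(a_solid + 0.9 * (a_ref - a_solid))

    def test_envelope_bandwidth_at_minus_6db(self, homogeneous_healthy, noiseless_config):
        """Spectrum's half-amplitude width matches the 0.25 fractional bandwidth."""
        scan = simulate_ascan(homogeneous_healthy, 50, 30, noiseless_config)
        spec = np.abs(np.fft.rfft(scan.waveform))
        freqs = np.fft.rfftfreq(scan.waveform.size, 1 / scan.sample_rate_hz)
        half = spec >= spec.max() / 2
        width = freqs[half].max() - freqs[half].min()
        assert width == pytest.approx(0.25 * 16e6, rel=0.05)

    def test_deterministic_given_rng(self, homogeneous_healthy):
        config = AcquisitionConfig()
        a = simulate_ascan(homogeneous_healthy, 10, 10, config, np.random.default_rng(7))
        b = simulate_ascan(homogeneous_healthy, 10, 10, config, np.random.default_rng(7))
        assert np.array_equal(a.waveform, b.waveform)


class TestScan:
    def test_cardinality_and_alignment(self, fixed_phantom):
        grid = [(10, 10), (20, 20), (30, 30), (40, 40), (50, 50)]
        ds = simulate_scan(fixed_phantom, grid, AcquisitionConfig())
        assert len(ds.records) == len(ds.ascans) == len(ds.grid) == 5
        for (x, y), rec in zip(ds.grid, ds.records):
            assert rec.grid_point == (x, y)

    def test_same_seed_bit_identical(self, fixed_phantom):
        grid = [(10, 10), (50, 30)]
        d1 = simulate_scan(fixed_phantom, grid, AcquisitionConfig(seed=3))
        d2 = simulate_scan(fixed_phantom, grid, AcquisitionConfig(seed=3))
        for r1, r2 in zip(d1.records, d2.records):
            assert np.array_equal(r1.force_trace, r2.force_trace)
        for a1, a2 in zip(d1.ascans, d2.ascans):
            assert np.array_equal(a1.waveform, a2.waveform)

    def test_point_noise_invariant_to_grid_order(self, fixed_phantom):
        config = AcquisitionConfig(seed=5)
        fwd = simulate_scan(fixed_phantom, [(10, 10), (50, 30)], config)
        rev = simulate_scan(fixed_phantom, [(50, 30), (10, 10)], config)
        assert np.array_equal(fwd.ascans[0].waveform, rev.ascans[1].waveform)
        assert np.array_equal(fwd.records[1].force_trace, rev.records[0].force_trace)

    def test_homogeneous_slopes_identical(self, homogeneous_healthy, noiseless_config):
        ds = simulate_scan(homogeneous_healthy, [(10, 10), (60, 40), (90, 50)], noiseless_config)
        slopes = [
            slope_after_contact(r, noiseless_config.contact_depth_mm) for r in ds.records
        ]
        assert np.ptp(slopes) < 1e-9

    def test_error_identifies_offending_point(self, fixed_phantom):
        with pytest.raises(GeometryError, match=r"grid point 1"):
            simulate_scan(fixed_phantom, [(10, 10), (500, 30)], AcquisitionConfig())

    def test_round_trip_npy_and_tsv(self, tmp_path, fixed_phantom):
        config = AcquisitionConfig(seed=2, record_duration_us=25.0, us_sample_rate_hz=2e8)
        ds = simulate_scan(fixed_phantom, [(10, 10), (14, 16)], config)
        for fmt in ("npy", "tsv"):
            out = tmp_path / fmt
            save_dataset(ds, out, waveform_format=fmt)
            back = load_dataset(out)
            assert back.config == config
            assert np.allclose(back.grid, ds.grid)
            for a, b in zip(ds.records, back.records):
                assert np.allclose(a.force_trace, b.force_trace, rtol=0, atol=0)
            for a, b in zip(ds.ascans, back.ascans):
                assert np.allclose(a.waveform, b.waveform, rtol=0, atol=0)
            assert back.phantom_truth == fixed_phantom


class TestSceneRendering:
    def test_aligned_difference_is_the_rectangle(self, homogeneous_healthy):
        scene = render_scene_image(homogeneous_healthy, pose=(0, 0, 0), seed=1)
        diff = np.abs(scene.sample - scene.background) > 0.05
        rows = np.flatnonzero(diff.any(axis=1))
        cols = np.flatnonzero(diff.any(axis=0))
        h_mm = (rows[-1] - rows[0] + 1) * scene.mm_per_pixel
        w_mm = (cols[-1] - cols[0] + 1) * scene.mm_per_pixel
        assert abs(w_mm - 100.0) <= 2 * scene.mm_per_pixel
        assert abs(h_mm - 60.0) <= 2 * scene.mm_per_pixel

    def test_identical_seeds_identical_images(self, homogeneous_healthy):
        s1 = render_scene_image(homogeneous_healthy, pose=(2, -3, 12), seed=9)
        s2 = render_scene_image(homogeneous_healthy, pose=(2, -3, 12), seed=9)
        assert np.array_equal(s1.sample, s2.sample)
        assert np.array_equal(s1.background, s2.background)

    def test_rotation_preserves_mask_area(self, homogeneous_healthy):
        def area(scene):
            return float((np.abs(scene.sample - scene.background) > 0.05).sum())

        a0 = area(render_scene_image(homogeneous_healthy, pose=(0, 0, 0), seed=1))
        a30 = area(render_scene_image(homogeneous_healthy, pose=(0, 0, 30), seed=1))
        assert a30 == pytest.approx(a0, rel=0.02)

    def test_pose_outside_frame_raises(self, homogeneous_healthy):
        with pytest.raises(GeometryError):
            render_scene_image(homogeneous_healthy, pose=(60, 0, 0), seed=1)


def test_point_rngs_distinct_streams():
    config = AcquisitionConfig(seed=1)
    f1, u1 = point_rngs(config, 10.0, 10.0)
    f2, u2 = point_rngs(config, 12.0, 10.0)
    assert f1.normal() != f2.normal()
    assert u1.normal() != u2.normal()
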