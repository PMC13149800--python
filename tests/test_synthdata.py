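import numpy as np
import pytest

from carotidfr.synthdata import (
    PhantomSpec,
    PressurePair,
    make_coil_maps,
    make_diameter_waveform,
    render_phantom,
    simulate_acquisition,
    simulate_mmode,
    simulate_physio,
    simulate_pressures,
)
from carotidfr.trajectory import TrajectorySpec, make_trajectory


class TestWaveform:
    def test_extrema_are_exact(self):
        wf = make_diameter_waveform(5.5, 6.4, 960, 0.35, 12)
        assert wf.diameters.min() == 5.5
        assert wf.diameters.max() == 6.4

    def test_constant_when_dd_equals_ds(self):
        wf = make_diameter_waveform(6.0, 6.0)
        np.testing.assert_array_equal(wf.diameters, 6.0)

    def test_rdc_matches_direct_arithmetic(self):
        wf = make_diameter_waveform(5.5, 6.4)
        assert wf.rdc_true == pytest.approx((6.4 - 5.5) / 5.5 * 100.0, abs=1e-12)

    def test_periodic(self):
        wf = make_diameter_waveform(5.5, 6.4)
        assert wf.at_fraction(0.9999) == pytest.approx(wf.diameters[0], abs=1e-6)

    @pytest.mark.parametrize("shape", ["bump", "pulse"])
    def test_shapes_share_extrema(self, shape):
        wf = make_diameter_waveform(5.5, 6.4, shape=shape)
        assert wf.diameters.min() == 5.5 and wf.diameters.max() == 6.4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_diameter_waveform(6.4, 5.5)
        with pytest.raises(ValueError):
            make_diameter_waveform(-1.0, 2.0)
        with pytest.raises(ValueError):
            make_diameter_waveform(5.5, 6.4, systolic_fraction=1.5)


class TestPhantom:
    def test_interior_voxel_is_pure_lumen(self, phantom_spec):
        img = render_phantom(phantom_spec, 5.5)
        cx, cy = phantom_spec.vessel_centers_mm[0]
        i, j = int(cx / 0.6), int(cy / 0.6)
        assert img[i, j, 10] == phantom_spec.lumen_intensity

    def test_occupancy_monotone_in_diameter(self, phantom_spec):
        sums = [render_phantom(phantom_spec, d).sum() for d in (5.0, 5.5, 6.0, 6.4)]
        assert np.all(np.diff(sums) > 0)

    def test_vessel_exiting_grid_rejected(self):
        spec = PhantomSpec(grid_size=16, vessel_centers_mm=((1.0, 4.8), (7.0, 4.8)))
        with pytest.raises(ValueError):
            render_phantom(spec, 5.5)

    def test_lumen_must_be_brightest(self):
        with pytest.raises(ValueError):
            PhantomSpec(lumen_intensity=0.5, background_intensity=1.0)


class TestPhysio:
    def test_constant_rr_grid(self):
        rec = simulate_physio(10000, 1000, 0, seed=3)
        np.testing.assert_array_equal(rec.trigger_times, np.arange(10) * 1000.0)

    def test_reproducible_under_seed(self):
        a = simulate_physio(60000, 960, 40, seed=9)
        b = simulate_physio(60000, 960, 40, seed=9)
        np.testing.assert_array_equal(a.trigger_times, b.trigger_times)

    def test_sample_mean_rr(self):
        rec = simulate_physio(600000, 960, 40, seed=7)
        rr = np.diff(rec.trigger_times)
        assert abs(rr.mean() - 960) / 960 < 0.02

    def test_excessive_variability_rejected(self):
        with pytest.raises(ValueError):
            simulate_physio(10000, 400, 100, seed=0)


class TestAcquisition:
    @pytest.fixture(scope="class")
    def setup(self):
        spec = PhantomSpec(
            grid_size=16,
            vessel_centers_mm=((3.2, 4.8), (6.4, 4.8)),
            wall_thickness_mm=0.3,
            background_roi=((1, 3), (1, 15), (1, 15)),
        )
        traj = make_trajectory(TrajectorySpec(10, 5, 17, 0.5))
        maps = np.ones((1, 16, 16, 16), dtype=complex)
        return spec, traj, maps

    def test_dc_sample_equals_spatial_sum(self, setup):
        spec, traj, maps = setup
        wf = make_diameter_waveform(2.0, 2.0)
        raw = simulate_acquisition(wf, spec, traj, maps, 5.97, 0.0, seed=0,
                                   forward_model="dft")
        img = render_phantom(spec, 2.0)
        # odd sample count: the middle sample of each spoke is k = 0
        np.testing.assert_allclose(raw.data[:, 8, 0], img.sum(), rtol=1e-12)

    def test_static_phantom_is_phase_independent(self, setup):
        spec, traj, maps = setup
        wf = make_diameter_waveform(2.0, 2.0)
        raw = simulate_acquisition(wf, spec, traj, maps, 5.97, 0.0, seed=0,
                                   forward_model="dft")
        wf2 = make_diameter_waveform(2.0, 2.0, rr_ms=700.0)
        raw2 = simulate_acquisition(wf2, spec, traj, maps, 5.97, 0.0, seed=0,
                                    forward_model="dft")
        np.testing.assert_allclose(raw.data, raw2.data, rtol=1e-12)

    def test_exact_dft_mode_matches_brute_force(self, setup):
        """Direct-summation forward model vs a literal per-voxel sum."""
        spec, traj, maps = setup
        wf = make_diameter_waveform(2.0, 2.4)
        raw = simulate_acquisition(wf, spec, traj, maps, 5.97, 0.0, seed=0,
                                   forward_model="dft")
        # recompute one readout by brute force at its rendered phase
        t = raw.timestamps[7]
        trig = raw.physio.trigger_times
        i = np.searchsorted(trig, t, side="right")
        prev = trig[i - 1]
        nxt = trig[i] if i < len(trig) else prev + wf.rr_ms
        p = wf.nearest_phase((t - prev) / (nxt - prev))
        img = render_phantom(spec, wf.diameters[p])
        offs = np.arange(16) - 8
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        for s in (0, 8, 16):
            k = raw.trajectory.samples[7, s]
            val = np.sum(img * np.exp(-2j * np.pi * (k[0] * ox + k[1] * oy + k[2] * oz)))
            assert abs(val - raw.data[7, s, 0]) / max(abs(val), 1e-12) < 1e-10

    def test_noise_reproducible(self, setup):
        spec, traj, maps = setup
        wf = make_diameter_waveform(2.0, 2.0)
        a = simulate_acquisition(wf, spec, traj, maps, 5.97, 0.5, seed=4)
        b = simulate_acquisition(wf, spec, traj, maps, 5.97, 0.5, seed=4)
        np.testing.assert_array_equal(a.data, b.data)


class TestMMode:
    def test_noiseless_separation_equals_waveform(self):
        wf = make_diameter_waveform(5.5, 6.4)
        tr = simulate_mmode(wf, 5, 0.0, 0.0, imt_mm=0.0)
        assert len(tr.time_s) == 1200  # 4.8 s x 250 fps
        sep = tr.lower_mm - tr.upper_mm
        assert sep.min() == pytest.approx(5.5, abs=1e-12)
        assert sep.max() == pytest.approx(6.4, abs=1e-12)

    def test_common_mode_drift_cancels(self):
        wf = make_diameter_waveform(5.5, 6.4)
        a = simulate_mmode(wf, 5, 0.0, 0.0, imt_mm=0.6)
        b = simulate_mmode(wf, 5, 0.1, 0.0, imt_mm=0.6)
        np.testing.assert_allclose(
            a.lower_mm - a.upper_mm, b.lower_mm - b.upper_mm, atol=1e-9
        )

    def test_boundary_order_enforced(self):
        from carotidfr.synthdata import MModeTrace

        with pytest.raises(ValueError):
            MModeTrace(
                time_s=np.arange(3) / 250.0,
                upper_mm=np.array([5.0, 5.0, 5.0]),
                lower_mm=np.array([4.0, 6.0, 6.0]),
            )


class TestPressures:
    def test_noiseless_passthrough(self):
        p = simulate_pressures(113, 63, 0.0, seed=0)
        assert (p.p_s, p.p_d) == (113.0, 63.0)

    def test_averaging_reduces_noise_sd(self):
        vals = np.array([simulate_pressures(113, 63, 4.0, seed=s).p_s for s in range(10000)])
        assert vals.std() == pytest.approx(4.0 / np.sqrt(2), rel=0.05)

    def test_order_enforced(self):
        with pytest.raises(ValueError):
            simulate_pressures(63, 113, 0.0, seed=0)
        with pytest.raises(ValueError):
            PressurePair(60, 70)


def test_coil_maps_sos_normalized():
    maps = make_coil_maps(16, 4)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    np.testing.assert_allclose(sos, 1.0, atol=1e-12)
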