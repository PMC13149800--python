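import numpy as np
import pytest

from carotidfr.mmode import (
    DiameterTrace,
    _ampd_maxima,
    ampd_peaks,
    analyze_mmode,
    beats_to_diameters,
    diameter_from_boundaries,
)
from carotidfr.synthdata import MModeTrace, make_diameter_waveform, simulate_mmode


def _trace_from_diameter(diam, fps=250.0):
    t = np.arange(len(diam)) / fps
    return MModeTrace(time_s=t, upper_mm=-diam / 2, lower_mm=diam / 2, fps=fps)


class TestDiameterFromBoundaries:
    def test_constant_boundaries(self):
        tr = MModeTrace(
            time_s=np.arange(1000) / 250.0,
            upper_mm=np.full(1000, 2.0),
            lower_mm=np.full(1000, 8.0),
        )
        dt = diameter_from_boundaries(tr)
        np.testing.assert_allclose(dt.diameter_mm, 6.0, atol=1e-12)

    def test_added_drift_is_removed(self):
        """Construct-and-subtract oracle: adding a shared linear drift to
        both boundaries leaves the diameter output unchanged."""
        wf = make_diameter_waveform(5.5, 6.4)
        base = simulate_mmode(wf, 5, 0.0, 0.0, imt_mm=0.0)
        t = base.time_s
        drifted = MModeTrace(
            time_s=t, upper_mm=base.upper_mm + 0.3 * t, lower_mm=base.lower_mm + 0.3 * t
        )
        a = diameter_from_boundaries(base)
        b = diameter_from_boundaries(drifted)
        np.testing.assert_allclose(a.diameter_mm, b.diameter_mm, atol=1e-9)

    def test_detrending_is_idempotent(self):
        wf = make_diameter_waveform(5.5, 6.4)
        tr = simulate_mmode(wf, 5, 0.0, 0.0, imt_mm=0.0)
        once = diameter_from_boundaries(tr)
        again = diameter_from_boundaries(
            MModeTrace(
                time_s=once.time_s,
                upper_mm=-once.diameter_mm / 2,
                lower_mm=once.diameter_mm / 2,
            )
        )
        assert abs(again.trend_slope_mm_per_s) < 1e-9
        np.testing.assert_allclose(again.diameter_mm, once.diameter_mm, atol=1e-9)

    def test_irregular_sampling_is_interpolated(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 4.0, 500))
        tr = MModeTrace(time_s=t, upper_mm=np.full(500, 1.0), lower_mm=np.full(500, 7.0))
        dt = diameter_from_boundaries(tr)
        assert np.allclose(np.diff(dt.time_s), 1 / 250.0)
        np.testing.assert_allclose(dt.diameter_mm, 6.0, atol=1e-12)

    def test_crossed_boundaries_rejected(self):
        tr = MModeTrace(
            time_s=np.arange(10) / 250.0,
            upper_mm=np.zeros(10),
            lower_mm=np.ones(10),
        )
        tr.lower_mm[3] = -0.5
        with pytest.raises(ValueError):
            diameter_from_boundaries(tr)


class TestAmpd:
    def test_clean_sine_five_cycles(self):
        t = np.arange(1200)
        x = np.sin(2 * np.pi * 5 * t / 1200)
        peaks, troughs = ampd_peaks(DiameterTrace(t / 250.0, x, 0.0))
        np.testing.assert_array_equal(peaks, [60, 300, 540, 780, 1020])
        np.testing.assert_array_equal(troughs, [180, 420, 660, 900, 1140])

    def test_negation_swaps_peaks_and_troughs(self):
        t = np.arange(1200)
        x = np.sin(2 * np.pi * 5 * t / 1200)
        p1, t1 = ampd_peaks(DiameterTrace(t / 250.0, x, 0.0))
        p2, t2 = ampd_peaks(DiameterTrace(t / 250.0, -x, 0.0))
        np.testing.assert_array_equal(p1, t2)
        np.testing.assert_array_equal(t1, p2)

    def test_noisy_sine_within_two_samples(self):
        t = np.arange(1200)
        x = np.sin(2 * np.pi * 5 * t / 1200)
        noisy = x + 0.02 * np.random.default_rng(3).standard_normal(1200)
        peaks, troughs = ampd_peaks(DiameterTrace(t / 250.0, noisy, 0.0))
        assert len(peaks) == 5 and len(troughs) == 5
        assert np.abs(peaks - np.array([60, 300, 540, 780, 1020])).max() <= 2
        assert np.abs(troughs - np.array([180, 420, 660, 900, 1140])).max() <= 2

    def test_monotone_trace_warns_and_returns_empty(self):
        t = np.arange(100)
        with pytest.warns(RuntimeWarning):
            peaks, troughs = ampd_peaks(DiameterTrace(t / 250.0, t * 1.0, 0.0))
        assert len(peaks) == 0 and len(troughs) == 0

    def test_scalogram_on_very_short_signal(self):
        assert len(_ampd_maxima(np.array([1.0, 2.0, 1.0]))) == 0


class TestBeatsToDiameters:
    def _trace(self, values):
        return DiameterTrace(np.arange(len(values)) / 250.0, np.asarray(values), 0.0)

    def test_arithmetic_example(self):
        x = np.zeros(100)
        peaks = np.array([5, 25, 45, 65, 85])
        troughs = np.array([15, 35, 55, 75, 95])
        x[peaks] = 8.0
        x[troughs] = 7.0
        be = beats_to_diameters(self._trace(x), peaks, troughs, imt_mm=0.5)
        assert (be.d_s, be.d_d) == (7.0, 6.0)

    def test_zero_imt_gives_plain_means(self):
        x = np.zeros(100)
        peaks = np.array([5, 25, 45, 65, 85])
        troughs = np.array([15, 35, 55, 75, 95])
        x[peaks] = np.array([8.0, 8.1, 8.2, 8.3, 8.4])
        x[troughs] = 7.0
        be = beats_to_diameters(self._trace(x), peaks, troughs, imt_mm=0.0)
        assert be.d_s == pytest.approx(8.2)
        assert be.d_d == pytest.approx(7.0)

    def test_too_few_peaks_rejected(self):
        x = np.sin(np.arange(200) / 10.0)
        with pytest.raises(ValueError, match="peaks"):
            beats_to_diameters(self._trace(x), np.array([10, 72]), np.array([41]), 0.0)

    def test_overcorrection_rejected(self):
        x = np.zeros(100)
        peaks = np.array([5, 25, 45, 65, 85])
        troughs = np.array([15, 35, 55, 75, 95])
        x[peaks] = 2.0
        x[troughs] = 1.0
        with pytest.raises(ValueError, match="diastolic"):
            beats_to_diameters(self._trace(x), peaks, troughs, imt_mm=0.6)


class TestFullChain:
    @pytest.mark.parametrize("drift", [0.0, 0.1, -0.5, 2.0])
    def test_noiseless_recovery_for_any_drift(self, drift):
        """Generator ground truth is recovered to interpolation tolerance
        after the 2x IMT correction, independent of common-mode drift."""
        wf = make_diameter_waveform(5.5, 6.4)
        tr = simulate_mmode(wf, 5, drift_mm_per_s=drift, noise_sd_mm=0.0, imt_mm=0.6)
        be = analyze_mmode(tr)
        assert be.d_s == pytest.approx(6.4, abs=1e-6)
        assert be.d_d == pytest.approx(5.5, abs=1e-6)

    def test_rdc_invariant_to_drift_and_offset(self):
        wf = make_diameter_waveform(5.5, 6.4)
        rdc = []
        for drift, center in ((0.0, 6.0), (0.4, 6.0), (0.0, 11.0)):
            tr = simulate_mmode(
                wf, 5, drift_mm_per_s=drift, noise_sd_mm=0.0, imt_mm=0.6,
                center_mm=center,
            )
            be = analyze_mmode(tr)
            rdc.append((be.d_s - be.d_d) / be.d_d * 100.0)
        np.testing.assert_allclose(rdc, rdc[0], atol=1e-9)

    def test_noisy_recovery_is_reasonable(self):
        wf = make_diameter_waveform(5.5, 6.4)
        tr = simulate_mmode(wf, 5, 0.2, 0.05, imt_mm=0.6, seed=11)
        be = analyze_mmode(tr)
        assert be.d_s == pytest.approx(6.4, abs=0.15)
        assert be.d_d == pytest.approx(5.5, abs=0.25)
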