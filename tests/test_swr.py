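import numpy as np
import pytest

from oscillotype import AnalysisConfig, Recording, analyze_swr, swr_summary
from oscillotype.filters import fft_lowpass
from oscillotype.swr import (
    SwrEvent,
    _triple_point_amplitude,
    detect_sharp_waves,
    extract_ripples,
    ripple_frequency,
    sw_area,
)
from oscillotype.synthetic_data import SwrSimConfig, gen_swr_train


class TestDetectSharpWaves:
    def test_injected_events_recalled(self):
        rec, truth = gen_swr_train(SwrSimConfig(seed=3, incidence_hz=0.5))
        events, _ = detect_sharp_waves(rec)
        det = np.array([e.t_max for e in events])
        hits = sum(np.min(np.abs(det - t)) < 0.02 for t in truth.times)
        assert hits >= len(truth.times) - 1
        assert abs(len(events) - len(truth.times)) <= 1

    def test_close_pair_merged_to_one(self):
        """Two sharp waves 50 ms apart violate the 100 ms separation rule."""
        fs = 5000.0
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(20 * fs)) * 0.01
        t_grid = np.arange(x.size) / fs
        for t0 in (10.0, 10.05):
            x += 0.3 * np.exp(-((t_grid - t0) ** 2) / (2 * 0.008**2))
        events, _ = detect_sharp_waves(Recording(x, fs))
        near = [e for e in events if 9.9 < e.t_max < 10.2]
        assert len(near) == 1

    def test_noise_only_rate_matches_rice_oracle(self):
        """Threshold crossings of Gaussian noise follow Rice's formula; the
        detector must not exceed that rate."""
        rec, _ = gen_swr_train(SwrSimConfig(seed=5, incidence_hz=0.0))
        events, lp = detect_sharp_waves(rec)
        # Rice rate for mean+3SD upcrossings of the low-passed noise
        dlp = np.diff(lp)
        nu = np.sqrt(np.var(dlp) / np.var(lp)) * rec.fs / (2 * np.pi)
        rice = nu * np.exp(-9.0 / 2.0)
        assert len(events) / rec.duration <= 1.5 * rice + 0.05


class TestSwArea:
    def test_triangle_closed_form(self):
        """Symmetric triangle, height 0.2 mV, base 40 ms → area ≈ 4 mV·ms."""
        fs = 5000.0
        x = np.zeros(int(10 * fs))
        half = int(0.020 * fs)
        k = 25000
        x[k - half:k + half + 1] = 0.2 * (1 - np.abs(np.arange(-half, half + 1)) / half)
        ev = SwrEvent(t_max=k / fs, peak_mV=0.2)
        ev = sw_area(x, fs, ev)
        assert ev.sw_area == pytest.approx(4.0, rel=0.03)

    def test_gaussian_numeric_oracle(self):
        """Gaussian SW: area matches direct numeric integration between the
        mean crossings."""
        fs = 5000.0
        a, sigma = 0.25, 0.010
        x = np.zeros(int(20 * fs))
        t = np.arange(x.size) / fs
        x += a * np.exp(-((t - 10.0) ** 2) / (2 * sigma**2))
        mean = x.mean()
        dev = x - mean
        k = int(10.0 * fs)
        left = np.flatnonzero(dev[:k] <= 0)[-1]
        right = k + np.flatnonzero(dev[k:] <= 0)[0]
        oracle = np.trapezoid(np.clip(dev[left:right + 1], 0, None),
                              dx=1 / fs) * 1000.0
        ev = sw_area(x, fs, SwrEvent(t_max=10.0, peak_mV=a))
        assert ev.sw_area == pytest.approx(oracle, rel=1e-6)
        # close to the untruncated closed form a·σ·√(2π)
        assert ev.sw_area == pytest.approx(a * 10.0 * np.sqrt(2 * np.pi), rel=0.1)

    def test_edge_event_flagged_missing(self):
        fs = 5000.0
        x = np.linspace(0, 0.5, int(fs))  # rises to the segment edge
        ev = sw_area(x, fs, SwrEvent(t_max=0.9998, peak_mV=0.5))
        assert ev.sw_area is None
        assert ev.edge_clipped


class TestTriplePointAmplitude:
    def test_pure_cosine_symmetric(self):
        """Cosine trough: amplitude 2a, zero asymmetry → included."""
        fs = 5000.0
        t = np.arange(int(0.1 * fs)) / fs
        a = 0.05
        bp = a * np.cos(2 * np.pi * 200 * t)
        # second trough (1.5 periods in) so both flanking maxima are interior
        period = fs / 200.0
        lo, hi = int(period), int(2 * period)
        trough = lo + int(np.argmin(bp[lo:hi]))
        amp = _triple_point_amplitude(bp, trough, 0.75, "normdiff")
        assert amp == pytest.approx(2 * a, rel=0.01)

    def test_asymmetric_trough_excluded(self):
        """r = 1.0, f = 0.2 → |r−f|/max = 0.8 > 0.75 → excluded."""
        bp = np.array([0.0, 1.0, 0.5, 0.0, 0.1, 0.2, 0.1, 0.0])
        # trough at index 3: M1=1.0 (idx1), m=0.0, M2=0.2 (idx5)
        amp = _triple_point_amplitude(bp, 3, 0.75, "normdiff")
        assert amp is None

    def test_moderate_asymmetry_included(self):
        bp = np.array([0.0, 1.0, 0.5, 0.0, 0.3, 0.6, 0.3, 0.0])
        # r=1.0, f=0.6 → 0.4/1.0 < 0.75 → included, amp = 0.8
        amp = _triple_point_amplitude(bp, 3, 0.75, "normdiff")
        assert amp == pytest.approx(0.8)

    def test_inclusion_boundary_via_asymmetry_sweep(self):
        """Graded falling components cross the 0.75 boundary where expected."""
        included = []
        fracs = np.linspace(0.05, 0.95, 19)
        for f_frac in fracs:
            bp = np.array([0.0, 1.0, 0.5, 0.0, f_frac / 2, f_frac, f_frac / 2, 0.0])
            amp = _triple_point_amplitude(bp, 3, 0.75, "normdiff")
            included.append(amp is not None)
        # asymmetry |1−f|/1 < 0.75 ⇔ f > 0.25
        expected = [f > 0.25 for f in fracs]
        assert included == expected

    def test_missing_flank_rejected(self):
        bp = np.array([0.5, 0.2, -0.1, -0.3])  # monotone: no flanking maxima
        assert _triple_point_amplitude(bp, 2, 0.75, "normdiff") is None


class TestRippleFrequency:
    def test_troughs_5ms_apart_give_200hz(self):
        ev = SwrEvent(t_max=1.0, peak_mV=0.2)
        ev.ripple_trough_times = np.array([0.995, 1.000, 1.005])
        assert ripple_frequency(ev) == pytest.approx(200.0)

    def test_single_trough_missing(self):
        ev = SwrEvent(t_max=1.0, peak_mV=0.2)
        ev.ripple_trough_times = np.array([1.0])
        assert ripple_frequency(ev) is None

    @pytest.mark.parametrize("f", [140.0, 180.0, 220.0, 260.0])
    def test_noise_free_tone_bursts_exact(self, f):
        rec, truth = gen_swr_train(SwrSimConfig(
            seed=6, ripple_f_hz=f, noise_mV=1e-6, incidence_hz=0.4))
        _, summary = analyze_swr(rec)
        # one-sample trough-timing tolerance at 5 kHz
        tol = 1.0 / (1.0 / f - 0.0002) - f
        assert summary.mean_ripple_freq == pytest.approx(f, abs=max(tol, 3.0))

    def test_injected_180hz_recovered_under_noise(self):
        rec, _ = gen_swr_train(SwrSimConfig(seed=8, ripple_f_hz=180.0))
        _, summary = analyze_swr(rec)
        assert summary.mean_ripple_freq == pytest.approx(180.0, abs=5.0)


class TestExtractRipples:
    def test_sw_without_ripple_content_keeps_event(self):
        fs = 5000.0
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(20 * fs)) * 0.005
        t = np.arange(x.size) / fs
        x += 0.3 * np.exp(-((t - 10.0) ** 2) / (2 * 0.010**2))
        events, summary = analyze_swr(Recording(x, fs))
        ev = [e for e in events if abs(e.t_max - 10.0) < 0.02][0]
        assert ev.n_ripples <= 1  # no tone burst → no inter-trough structure
        assert ev.sw_area is not None

    def test_event_near_edge_skipped_for_ripples(self):
        fs = 5000.0
        x = np.zeros(int(1.0 * fs))
        t = np.arange(x.size) / fs
        x += 0.3 * np.exp(-((t - 0.03) ** 2) / (2 * 0.008**2))  # 30 ms from edge
        rec = Recording(x + 1e-4 * np.random.default_rng(1).standard_normal(x.size), fs)
        events, lp = detect_sharp_waves(rec)
        ev = [e for e in events if abs(e.t_max - 0.03) < 0.02][0]
        ev = extract_ripples(rec, ev)
        assert ev.n_ripples == 0


class TestSummary:
    def test_incidence_is_count_over_duration(self):
        events = [SwrEvent(t_max=i, peak_mV=0.1) for i in range(60)]
        s = swr_summary(events, 120.0)
        assert s.incidence_hz == pytest.approx(0.5)

    def test_empty_summary(self):
        s = swr_summary([], 120.0)
        assert s.incidence_hz == 0.0
        assert s.mean_sw_area is None
        assert s.mean_ripple_freq is None

    @pytest.mark.parametrize("lam", [0.3, 0.6, 1.2])
    def test_incidence_recovered_within_poisson_error(self, lam):
        rec, truth = gen_swr_train(SwrSimConfig(seed=10, incidence_hz=lam))
        _, summary = analyze_swr(rec)
        tol = 3.0 * np.sqrt(lam / rec.duration)
        assert summary.incidence_hz == pytest.approx(
            truth.times.size / rec.duration, abs=tol)
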