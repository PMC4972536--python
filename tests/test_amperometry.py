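import numpy as np
import pytest

from vesiclekin import amperometry as amp
from vesiclekin import synthgen as sg
from vesiclekin.amperometry import (DetectionConfig, FootSignal, SpikeEvent,
                                    detect_events, detect_foot,
                                    estimate_baseline, event_frequency,
                                    foot_fluctuations, foot_rms_derivative,
                                    lowpass, spike_params)
from vesiclekin.trace import Trace

FS = 25_000.0


def _current_trace(samples, filtered=True):
    tr = Trace(samples=np.asarray(samples, float), fs=FS, kind="current")
    if filtered:
        tr.meta["lowpass_cutoff"] = 2000.0
    return tr


def _manual_event(trace):
    """SpikeEvent spanning the whole trace, for direct parametrization."""
    pk = int(np.argmax(trace.samples))
    ev = SpikeEvent(peak_time=trace.times[pk],
                    amplitude=float(trace.samples[pk]),
                    charge=float(np.trapezoid(trace.samples,
                                              dx=trace.dt * 1e3)),
                    event_window=(0, trace.n), baseline=0.0)
    ev._peak_index = pk
    return ev


class TestBaseline:
    def test_zero_segment(self):
        tr = _current_trace(np.zeros(1000))
        level, sd = estimate_baseline(tr, (0.0, 0.03))
        assert level == 0.0 and sd == 0.0

    def test_gaussian_noise_sd_recovered(self):
        rng = np.random.default_rng(0)
        tr = _current_trace(rng.normal(2.0, 1.5, 10_000))
        level, sd = estimate_baseline(tr, (0.0, 0.4))
        assert level == pytest.approx(2.0, abs=0.1)
        assert sd == pytest.approx(1.5, rel=0.05)

    def test_drift_detrended(self):
        # 1 pA/s drift contributes nothing to the detrended residual sd
        t = np.arange(25_000) / FS
        tr = _current_trace(1.0 * t)
        _, sd = estimate_baseline(tr, (0.0, 1.0))
        assert sd < 1e-9

    def test_empty_window_rejected(self):
        tr = _current_trace(np.zeros(100))
        with pytest.raises(ValueError):
            estimate_baseline(tr, (0.0, 0.0))


class TestDetectEvents:
    def test_noise_only_trace_empty(self):
        rng = np.random.default_rng(1)
        tr = lowpass(Trace(rng.normal(0, 1.0, 100_000), fs=FS), 2000.0)
        assert detect_events(tr) == []

    def test_amplitude_and_charge_selection(self):
        # 3 qualifying events, 1 below the 4 pA cut, 1 above 5000 fC
        events = [
            sg.EventTruth(onset_time=100.0, spike_amplitude=20.0,
                          spike_charge=300.0, kernel="rect"),
            sg.EventTruth(onset_time=400.0, spike_amplitude=20.0,
                          spike_charge=300.0, kernel="rect"),
            sg.EventTruth(onset_time=700.0, spike_amplitude=20.0,
                          spike_charge=300.0, kernel="rect"),
            sg.EventTruth(onset_time=1000.0, spike_amplitude=3.0,
                          spike_charge=30.0, kernel="rect"),
            sg.EventTruth(onset_time=1300.0, spike_amplitude=20.0,
                          spike_charge=6000.0, kernel="rect"),
        ]
        trace, _ = sg.gen_amperometric_trace(events, duration=2.0,
                                             baseline_sd=0.0, seed=0)
        filt = lowpass(trace, 2000.0)
        found = detect_events(filt, baseline=(0.0, 0.05))
        assert len(found) == 3
        assert all(ev.amplitude > 4.0 for ev in found)
        assert all(10.0 <= ev.charge <= 5000.0 for ev in found)

    def test_requires_filtered_current_trace(self):
        tr = Trace(np.zeros(1000), fs=FS, kind="current")
        with pytest.raises(ValueError):
            detect_events(tr)
        cap = Trace(np.zeros(1000), fs=FS, kind="capacitance")
        cap.meta["lowpass_cutoff"] = 2000.0
        with pytest.raises(ValueError):
            detect_events(cap)

    def test_selection_filter_order_independent(self, snr10_recording):
        trace, _, _ = snr10_recording
        filt = lowpass(trace, 2000.0)
        cfg = DetectionConfig()
        events = detect_events(filt, cfg)
        amp_then_charge = [e for e in events
                           if e.amplitude > cfg.amp_threshold_freq]
        amp_then_charge = [e for e in amp_then_charge
                           if cfg.charge_min <= e.charge <= cfg.charge_max]
        charge_then_amp = [e for e in events
                           if cfg.charge_min <= e.charge <= cfg.charge_max]
        charge_then_amp = [e for e in charge_then_amp
                           if e.amplitude > cfg.amp_threshold_freq]
        assert amp_then_charge == charge_then_amp


class TestSpikeParams:
    def test_linear_rise_interpolated(self):
        # 0 -> 20 pA over 1 ms: time from 50% to 90% is 400 us
        n_rise = int(1e-3 * FS)
        y = np.concatenate([np.zeros(100),
                            np.linspace(0.0, 20.0, n_rise + 1),
                            np.zeros(100)])
        tr = _current_trace(y)
        ev = spike_params(tr, _manual_event(tr))
        assert ev.rise_time_50_90 == pytest.approx(400.0, rel=0.02)

    def test_rectangular_pulse(self):
        width = int(2e-3 * FS)
        y = np.concatenate([np.zeros(200), np.full(width, 20.0),
                            np.zeros(200)])
        tr = _current_trace(y)
        ev = spike_params(tr, _manual_event(tr))
        assert ev.half_width == pytest.approx(2.0, rel=0.03)
        assert ev.charge == pytest.approx(40.0, rel=0.03)

    def test_biexp_against_oversampled_oracle(self):
        # oracle: same kernel sampled at 1 MHz
        tr_ms, td_ms, peak = 0.1, 1.0, 30.0

        def kernel(t_ms):
            y = np.exp(-t_ms / td_ms) - np.exp(-t_ms / tr_ms)
            return peak * y / y.max()

        t_hi = np.arange(0, 15.0, 1e-3)          # 1 MHz grid, ms
        y_hi = kernel(t_hi)
        amp_hi = y_hi.max()
        above = y_hi >= 0.5 * amp_hi
        hw_oracle = (above.sum()) * 1e-3          # ms
        pk_hi = int(np.argmax(y_hi))
        rise = y_hi[:pk_hi + 1]
        t50 = t_hi[np.searchsorted(rise, 0.5 * amp_hi)]
        t90 = t_hi[np.searchsorted(rise, 0.9 * amp_hi)]
        rise_oracle = (t90 - t50) * 1e3           # us

        t_lo = np.arange(0, 15.0, 1e3 / FS)
        tr = _current_trace(np.concatenate([np.zeros(100), kernel(t_lo)]))
        ev = spike_params(tr, _manual_event(tr))
        one_sample_ms = 1e3 / FS
        assert abs(ev.half_width - hw_oracle) <= one_sample_ms
        assert abs(ev.rise_time_50_90 - rise_oracle) <= one_sample_ms * 1e3

    def test_edge_peak_flagged_unreliable(self):
        y = np.linspace(0.0, 20.0, 500)  # peak at the last sample
        tr = _current_trace(y)
        ev = spike_params(tr, _manual_event(tr))
        assert ev.unreliable


class TestFootDetection:
    def _one_event_trace(self, foot_duration, foot_amplitude=6.0,
                         n_flicker=0, seed=2, baseline_sd=0.3):
        ev = sg.EventTruth(onset_time=50.0, foot_duration=foot_duration,
                           foot_amplitude=foot_amplitude,
                           n_flicker=n_flicker, spike_amplitude=30.0)
        trace, _ = sg.gen_amperometric_trace([ev], duration=0.2,
                                             baseline_sd=baseline_sd,
                                             seed=seed)
        return trace

    def _detect(self, trace):
        cfg = DetectionConfig()
        filt = lowpass(trace, cfg.lowpass_cutoff)
        level, sd = amp._auto_baseline(filt)
        events = detect_events(filt, cfg, baseline=(level, sd))
        assert len(events) == 1
        return filt, events[0], sd, cfg

    def test_no_foot_returns_none(self):
        filt, ev, sd, cfg = self._detect(self._one_event_trace(0.0))
        assert detect_foot(filt, ev, cfg, baseline_sd=sd) is None

    def test_foot_geometry_recovered(self):
        # 6 pA x 4 ms plateau: duration and amplitude within 10%
        filt, ev, sd, cfg = self._detect(self._one_event_trace(4.0))
        foot = detect_foot(filt, ev, cfg, baseline_sd=sd)
        assert foot is not None
        assert foot.duration == pytest.approx(4.0, rel=0.10)
        assert foot.amplitude == pytest.approx(6.0, rel=0.10)

    def test_short_foot_excluded_from_fluctuations(self):
        # feet under 2 ms are not eligible for fluctuation statistics
        filt, ev, sd, cfg = self._detect(self._one_event_trace(1.5))
        foot = detect_foot(filt, ev, cfg, baseline_sd=sd)
        if foot is None:
            pytest.skip("sub-resolution foot not localized at this noise")
        done = foot_fluctuations(filt, foot, cfg)
        assert not done.fluct_applicable
        assert foot_rms_derivative(filt, foot, cfg) is None


class TestFluctuations:
    def _constructed_foot(self, n_flicker, duration_ms=4.0, slope=20.0):
        """Foot segment alone (plateau + sawtooth), no spike attached."""
        ev = sg.EventTruth(onset_time=20.0, foot_duration=duration_ms,
                           foot_amplitude=6.0, n_flicker=n_flicker,
                           spike_amplitude=30.0, flicker_slope=slope)
        t_ms = np.arange(int(0.1 * FS)) / FS * 1e3
        y = sg._foot_kernel(ev, t_ms - 20.0)
        tr = _current_trace(y)
        foot = FootSignal(onset_time=20e-3, end_time=(20.0 + duration_ms) * 1e-3,
                          duration=duration_ms, amplitude=6.0, charge=0.0)
        return tr, foot

    @pytest.mark.parametrize("k", [0, 1, 2, 4, 6])
    def test_sawtooth_counts_exact(self, k):
        tr, foot = self._constructed_foot(k)
        done = foot_fluctuations(tr, foot)
        assert done.fluct_pos == k
        assert done.fluct_neg == k
        assert done.fluct_frequency == pytest.approx(2 * k / 4.0)

    def test_subthreshold_ramp_zero(self):
        # a 3 pA/ms ramp never crosses the 6 pA/ms threshold
        n = int(8e-3 * FS)
        y = np.concatenate([np.zeros(200), 3.0 * np.arange(n) / FS * 1e3,
                            np.zeros(200)])
        tr = _current_trace(y)
        foot = FootSignal(onset_time=200 / FS, end_time=(200 + n) / FS,
                          duration=8.0, amplitude=6.0, charge=0.0)
        done = foot_fluctuations(tr, foot)
        assert done.fluct_pos == 0 and done.fluct_neg == 0

    def test_threshold_monotonicity(self):
        # raising the derivative threshold never increases the counts
        tr, foot = self._constructed_foot(4)
        counts = []
        for thr in (2.0, 4.0, 6.0, 10.0, 20.0, 40.0):
            cfg = DetectionConfig(deriv_threshold=thr)
            done = foot_fluctuations(tr, foot, cfg)
            counts.append(done.fluct_pos + done.fluct_neg)
        assert counts == sorted(counts, reverse=True)

    def test_frequency_identity(self):
        tr, foot = self._constructed_foot(3, duration_ms=6.0)
        done = foot_fluctuations(tr, foot)
        assert done.fluct_frequency == pytest.approx(
            (done.fluct_pos + done.fluct_neg) / done.duration)

    def test_threshold_cross_check_warns(self):
        rng = np.random.default_rng(3)
        tr = _current_trace(rng.normal(0, 0.01, 50_000))
        cfg = DetectionConfig()
        with pytest.warns(UserWarning, match="deviates"):
            amp.check_derivative_threshold(tr, cfg, (0.0, 1.0))


class TestRmsDerivative:
    def test_constant_slope_is_zero(self):
        n = int(6e-3 * FS)
        tr = _current_trace(np.concatenate([np.zeros(100),
                                            np.linspace(0, 30, n),
                                            np.full(100, 30.0)]))
        foot = FootSignal(onset_time=100 / FS, end_time=(100 + n) / FS,
                          duration=6.0, amplitude=15.0, charge=0.0)
        assert foot_rms_derivative(tr, foot) < 0.5

    def test_sinusoidal_derivative_closed_form(self):
        # signal a/w * sin(w t) has derivative a*cos(w t): rms = a/sqrt(2)
        f_hz = 150.0  # deep inside the 1.2 kHz derivative band
        a = 12.0      # pA/ms
        t = np.arange(int(0.2 * FS)) / FS
        w = 2 * np.pi * f_hz
        y = a / (w / 1e3) * np.sin(w * t)
        tr = _current_trace(y)
        foot = FootSignal(onset_time=0.05, end_time=0.15, duration=100.0,
                          amplitude=1.0, charge=0.0)
        rms = foot_rms_derivative(tr, foot)
        assert rms == pytest.approx(a / np.sqrt(2), rel=0.02)


class TestEventFrequency:
    def test_simple_rates(self):
        assert event_frequency([], 120.0) == 0.0
        fake = [SpikeEvent(peak_time=i, amplitude=10.0, charge=100.0,
                           event_window=(0, 1), baseline=0.0)
                for i in range(60)]
        assert event_frequency(fake, 120.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            event_frequency(fake, 0.0)

    def test_poisson_rate_recovered(self):
        # schedule at rate 0.4 Hz over 20 seeds: mean estimate within 3 SE
        lam, duration = 0.4, 60.0
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = rng.poisson(lam * duration)
            onsets = np.sort(rng.uniform(100.0, duration * 1e3 - 200.0, n))
            onsets = onsets[np.diff(onsets, prepend=-50.0) > 30.0]
            schedule = [sg.EventTruth(onset_time=float(t),
                                      spike_amplitude=20.0, decay_tau=1.5)
                        for t in onsets]
            trace, _ = sg.gen_amperometric_trace(
                schedule, duration=duration, baseline_sd=1.0,
                seed=2000 + seed)
            events = detect_events(lowpass(trace, 2000.0),
                                   baseline=(0.0, 1.0))
            rates.append(event_frequency(events, duration))
        se = lam / np.sqrt(len(rates) * duration * lam)
        # thinning from the enforced separation keeps this a one-sided check
        assert abs(np.mean(rates) - lam) < max(3 * se, 0.05)
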