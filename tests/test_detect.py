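import math

import numpy as np
import pytest

from minidetect.detect import (
    DetectionParams,
    EventDetector,
    apply_filters,
    find_event_manual,
    find_onset,
    fit_decay,
    measure,
    scan_auto,
)
from minidetect.recording import Recording
from minidetect.synth import (
    SharpEventSpec,
    add_hum,
    build_recording,
    sharp_sampler,
    sharp_waveform,
)
from tests.conftest import embed_events

DT = 0.1  # ms

CLEAN = DetectionParams(auto_diameter_ms=20.0, ma_window=100, min_amplitude=0.3)


class TestFindOnset:
    def test_hand_traced_six_sample_scan(self):
        """Backward scan on [0,0,0,0,0.5,2] with a 3-point average: the running
        mean is 0 everywhere left of the rise, ties continue leftward, and the
        onset lands on the first sample that departs from the flat baseline."""
        trace = np.array([0.0, 0.0, 0.0, 0.0, 0.5, 2.0])
        params = DetectionParams(ma_window=3)
        onset, baseline, warn = find_onset(trace, peak_index=5, params=params, dt_ms=1.0)
        assert onset == 4
        assert baseline == 0.0

    def test_onset_exact_on_negative_drift(self):
        """An event on a decaying baseline: with the averaging window short
        relative to the drift (its lag is ~ slope*W/2*dt), the crossing of
        trace and trailing average pins the onset to within one sample."""
        spec = SharpEventSpec(t_rise=2.0, amplitude=1.0, tau_decay=10.0)
        y, _ = sharp_waveform(spec, DT)
        n = 3000
        onset_true = 1500
        drift = -0.05 * (np.arange(n) * DT)  # -0.05 units/ms, 5% of amplitude
        trace = drift.copy()
        trace[onset_true : onset_true + y.size] += y[: n - onset_true]
        peak = onset_true + int(round(2.0 / DT))
        params = DetectionParams(ma_window=5)
        onset, baseline, warn = find_onset(trace, peak, params, DT)
        assert abs(onset - onset_true) <= 1
        assert not warn
        # baseline tracks the local trailing mean, not the global mean
        local_mean = trace[onset_true - 5 : onset_true].mean()
        assert baseline == pytest.approx(local_mean, abs=0.01)

    def test_fixed_left_window_baseline(self):
        trace = np.zeros(1000)
        trace[500:600] = np.linspace(0, 1, 100)
        params = DetectionParams(
            baseline_mode="fixed_left_window", fixed_offset_ms=20.0, fixed_window_ms=2.0
        )
        onset, baseline, warn = find_onset(trace, peak_index=599, params=params, dt_ms=DT)
        assert baseline == 0.0
        assert onset == 501  # first sample strictly above the flat baseline

    def test_fixed_window_cancels_hum_better_than_moving_average(self):
        """With the baseline window one hum period left of the peak, the hum is
        in phase at peak and baseline and the amplitude error shrinks."""
        spec = SharpEventSpec(t_rise=2.0, amplitude=1.0, tau_decay=10.0)
        y, _ = sharp_waveform(spec, DT)
        onset = 3000
        rec = embed_events([(onset, y)], n_total=8000)
        # place the peak on a hum crest: peak index 3020 -> t=302 ms; shift hum
        rec = add_hum(rec, hum_amplitude=0.2, hum_period_ms=20.0)
        fixed = DetectionParams(
            baseline_mode="fixed_left_window",
            fixed_offset_ms=20.0,
            fixed_window_ms=2.0,
            min_amplitude=0.3,
        )
        moving = DetectionParams(ma_window=100, min_amplitude=0.3)
        ev_fixed = find_event_manual(rec, 0.302, fixed)
        ev_moving = find_event_manual(rec, 0.302, moving)
        err_fixed = abs(ev_fixed.amplitude - 1.0)
        err_moving = abs(ev_moving.amplitude - 1.0)
        assert err_fixed < err_moving
        assert err_fixed < 0.1

    def test_peak_at_edge_or_without_baseline_room_raises(self):
        with pytest.raises(ValueError, match="edge"):
            find_onset(np.zeros(50), 0, CLEAN, DT)
        with pytest.raises(ValueError, match="no room"):
            find_onset(np.zeros(50), 49, CLEAN, DT)  # ma_window=100 > peak


class TestMeasure:
    def test_ideal_ramp_rise_time(self, single_sharp_event):
        rec, truth, onset, spec = single_sharp_event
        trace = rec.sweeps[0]
        peak = onset + int(round(spec.t_rise / DT))
        amp, rise, halfwidth = measure(trace, onset + 1, peak, 0.0, DT)
        assert amp == pytest.approx(1.0, abs=1e-9)
        assert rise == pytest.approx(1.6, abs=DT)

    def test_halfwidth_of_instant_rise_exponential(self):
        """A=1, t_rise->0, tau=10 ms: the 50% crossing on the decay sits at
        10 ln2 ms, so the half-width approaches 6.93 ms."""
        spec = SharpEventSpec(t_rise=DT, amplitude=1.0, tau_decay=10.0)
        y, _ = sharp_waveform(spec, DT)
        rec = embed_events([(200, y)], n_total=2000)
        trace = rec.sweeps[0]
        peak = 200 + 1
        amp, rise, halfwidth = measure(trace, 200, peak, 0.0, DT)
        assert halfwidth == pytest.approx(10 * math.log(2), abs=0.15)

    def test_translation_invariance(self, single_sharp_event):
        rec, truth, onset, spec = single_sharp_event
        trace = rec.sweeps[0]
        peak = onset + int(round(spec.t_rise / DT))
        a0 = measure(trace, onset + 1, peak, 0.0, DT)
        a1 = measure(trace + 5.0, onset + 1, peak, 5.0, DT)
        assert a0 == pytest.approx(a1)

    def test_undefined_halfwidth_when_decay_truncated(self):
        trace = np.concatenate([np.zeros(100), np.linspace(0, 1, 20)])
        amp, rise, halfwidth = measure(trace, 100, 119, 0.0, DT)
        assert math.isnan(halfwidth)


class TestFitDecay:
    def test_pure_exponential_both_methods(self):
        spec = SharpEventSpec(t_rise=DT, amplitude=1.0, tau_decay=10.0)
        y, _ = sharp_waveform(spec, DT)
        rec = embed_events([(100, y)], n_total=3000)
        trace = rec.sweeps[0]
        peak = 101
        for method in ("lm_fit", "one_over_e"):
            params = DetectionParams(decay_method=method)
            tau, b = fit_decay(trace, peak, 0.0, params, DT)
            assert tau == pytest.approx(10.0, abs=0.01), method

    def test_one_over_e_equals_lm_on_single_exponential(self):
        """The shape-agnostic 1/e readout matches the fitted constant on a
        true single exponential, even with mild noise."""
        rng = np.random.default_rng(0)
        spec = SharpEventSpec(t_rise=DT, amplitude=1.0, tau_decay=12.0)
        y, _ = sharp_waveform(spec, DT)
        trace = np.zeros(3000)
        trace[100 : 100 + y.size] = y
        trace += rng.normal(0, 1e-3, trace.size)
        tau_lm, _ = fit_decay(trace, 101, 0.0, DetectionParams(decay_method="lm_fit"), DT)
        tau_1e, _ = fit_decay(trace, 101, 0.0, DetectionParams(decay_method="one_over_e"), DT)
        assert tau_1e == pytest.approx(tau_lm, rel=0.01)

    def test_lm_matches_grid_search_oracle_on_noisy_events(self):
        """Levenberg-Marquardt tau agrees with an exhaustive grid-search
        least-squares oracle to <1% on 50 noisy single-exponential decays."""
        rng = np.random.default_rng(42)
        params = DetectionParams(decay_method="lm_fit", decay_fit_max_ms=50.0)
        n_fit = int(round(50.0 / DT)) + 1
        taus_grid = np.geomspace(0.5, 50.0, 6000)
        for _ in range(50):
            tau_true = rng.uniform(3, 25)
            amp = rng.uniform(0.5, 2.5)
            y = amp * np.exp(-np.arange(800) * DT / tau_true)
            trace = np.concatenate([np.zeros(50), y])
            trace += rng.normal(0, 0.013, trace.size)
            tau_lm, _ = fit_decay(trace, 50, 0.0, params, DT)
            # oracle: for each tau, the optimal B is closed form; minimize SSE
            seg = trace[50 : 50 + n_fit]
            t = np.arange(seg.size) * DT
            e = np.exp(-t[None, :] / taus_grid[:, None])
            b_opt = (e @ seg) / np.sum(e * e, axis=1)
            sse = np.sum((seg[None, :] - b_opt[:, None] * e) ** 2, axis=1)
            tau_oracle = taus_grid[np.argmin(sse)]
            assert tau_lm == pytest.approx(tau_oracle, rel=0.01)

    def test_biexp_fit_matches_grid_oracle(self):
        """On a biexponential event the single-exponential tau is defined by
        least squares; the LM fit must land on the same optimum as a grid search."""
        from minidetect.synth import BiexpEventSpec, biexp_waveform

        spec = BiexpEventSpec(tau1=5.0, tau2=10.0, amplitude=1.0)
        y, truth = biexp_waveform(spec, DT)
        trace = np.concatenate([np.zeros(50), y, np.zeros(200)])
        peak = 50 + int(np.argmax(y))
        span = 50.0
        params = DetectionParams(decay_method="lm_fit", decay_fit_max_ms=span)
        tau_lm, _ = fit_decay(trace, peak, 0.0, params, DT)
        n_fit = int(round(span / DT)) + 1
        seg = trace[peak : peak + n_fit]
        t = np.arange(seg.size) * DT
        taus_grid = np.geomspace(0.5, 50.0, 12000)
        e = np.exp(-t[None, :] / taus_grid[:, None])
        b_opt = (e @ seg) / np.sum(e * e, axis=1)
        sse = np.sum((seg[None, :] - b_opt[:, None] * e) ** 2, axis=1)
        tau_oracle = taus_grid[np.argmin(sse)]
        assert tau_lm == pytest.approx(tau_oracle, rel=0.01)
        assert tau_lm != pytest.approx(spec.tau2, rel=0.01)  # not tau2 itself

    def test_too_few_samples_gives_nan(self):
        trace = np.concatenate([np.zeros(10), [1.0], np.zeros(2)])
        tau, b = fit_decay(trace, 10, 0.0, DetectionParams(), DT, stop_index=12)
        assert math.isnan(tau)


class TestFilters:
    def _event(self, **kw):
        from minidetect.detect import DetectedEvent

        base = dict(
            sweep_index=0, onset_index=10, onset_time_s=1e-3, peak_index=20,
            peak_time_s=2e-3, baseline_value=0.0, amplitude=1.0,
            rise_10_90_ms=1.0, halfwidth_ms=5.0, tau_ms=10.0,
            decay_fit_amplitude=1.0,
        )
        base.update(kw)
        return DetectedEvent(**base)

    def test_first_violation_wins_in_fixed_order(self):
        ev = apply_filters(
            self._event(amplitude=0.3, rise_10_90_ms=99.0),
            DetectionParams(min_amplitude=0.5, max_rise_ms=1.0),
        )
        assert ev.status == "rejected"
        assert ev.reject_reason == "amplitude"

    def test_all_unset_accepts(self):
        ev = apply_filters(self._event(), DetectionParams())
        assert ev.status == "accepted"

    def test_undefined_tau_fails_set_tau_filter(self):
        ev = apply_filters(self._event(tau_ms=math.nan), DetectionParams(max_tau_ms=50.0))
        assert ev.status == "rejected"
        assert ev.reject_reason == "tau"

    def test_negative_directed_amplitude_always_rejected(self):
        ev = apply_filters(self._event(amplitude=-0.2), DetectionParams())
        assert ev.status == "rejected"
        assert ev.reject_reason == "amplitude"


class TestScanAuto:
    def test_noiseless_single_sharp_event_recovery(self, single_sharp_event):
        rec, truth, onset, spec = single_sharp_event
        events = scan_auto(rec, CLEAN)
        acc = [e for e in events if e.status == "accepted"]
        assert len(acc) == 1
        ev = acc[0]
        assert ev.amplitude == pytest.approx(1.0, abs=1e-6)
        assert ev.tau_ms == pytest.approx(10.0, abs=0.01)
        assert abs(ev.onset_index - onset) <= 1

    def test_flat_trace_yields_no_accepted_events(self):
        rec = Recording(sweeps=[np.zeros(5000)], dt=1e-4)
        events = scan_auto(rec, CLEAN)
        assert [e for e in events if e.status == "accepted"] == []

    def test_determinism(self):
        rec, _ = build_recording(20, event_sampler=sharp_sampler, seed=5)
        from minidetect.synth import add_correlated_noise

        rec = add_correlated_noise(rec, seed=5)
        e1 = scan_auto(rec, CLEAN)
        e2 = scan_auto(rec, CLEAN)
        assert [(e.peak_index, e.amplitude, e.tau_ms) for e in e1] == [
            (e.peak_index, e.amplitude, e.tau_ms) for e in e2
        ]

    def test_sign_symmetry(self):
        rec, _ = build_recording(10, event_sampler=sharp_sampler, seed=8)
        neg = Recording(sweeps=[-rec.sweeps[0]], dt=rec.dt)
        pos_events = [e for e in scan_auto(rec, CLEAN) if e.status == "accepted"]
        neg_params = DetectionParams(
            direction="negative", auto_diameter_ms=20.0, ma_window=100, min_amplitude=0.3
        )
        neg_events = [e for e in scan_auto(neg, neg_params) if e.status == "accepted"]
        assert len(pos_events) == len(neg_events) == 10
        for p, n in zip(pos_events, neg_events):
            assert p.peak_index == n.peak_index
            assert p.amplitude == pytest.approx(n.amplitude)
            assert p.baseline_value == pytest.approx(-n.baseline_value)

    def test_translation_invariance_of_scan(self):
        rec, _ = build_recording(5, event_sampler=sharp_sampler, seed=3)
        shifted = Recording(sweeps=[rec.sweeps[0] + 2.5], dt=rec.dt)
        a = [e for e in scan_auto(rec, CLEAN) if e.status == "accepted"]
        b = [e for e in scan_auto(shifted, CLEAN) if e.status == "accepted"]
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert eb.baseline_value == pytest.approx(ea.baseline_value + 2.5, abs=1e-9)
            assert eb.amplitude == pytest.approx(ea.amplitude, abs=1e-9)
            assert eb.peak_index == ea.peak_index

    def test_noise_free_recovery_property_over_random_specs(self):
        """Every generated event is recovered from a noise-free trace: onset
        within 1 sample, 1/e tau within 1%, and amplitude exact up to peak
        discretization (<1e-3 of the smooth biexponential maxima; bounded by
        A*dt/t_rise at the sharp shape's cusp, which no sample-reading
        detector can beat)."""
        # sharp events, LM decay fit: tau is the true decay constant
        rec, truths = build_recording(50, event_sampler=sharp_sampler, seed=21)
        acc = [e for e in scan_auto(rec, CLEAN) if e.status == "accepted"]
        assert len(acc) == len(truths)
        dt_ms = rec.dt * 1e3
        for ev, tr in zip(acc, truths):
            cusp_bound = tr.amplitude * dt_ms / tr.spec.t_rise + 1e-9
            assert abs(ev.amplitude - tr.amplitude) < cusp_bound
            assert abs(ev.onset_time_s - tr.onset_time) <= rec.dt + 1e-12
            assert abs(ev.tau_ms - tr.tau_1e) / tr.tau_1e < 0.01
        # biexponential events, shape-agnostic 1/e readout against true 1/e time
        rec, truths = build_recording(50, seed=22)
        params = DetectionParams(
            auto_diameter_ms=20.0, ma_window=100, min_amplitude=0.3,
            decay_method="one_over_e",
        )
        acc = [e for e in scan_auto(rec, params) if e.status == "accepted"]
        assert len(acc) == len(truths)
        for ev, tr in zip(acc, truths):
            assert abs(ev.amplitude - tr.amplitude) < 1e-3
            assert abs(ev.onset_time_s - tr.onset_time) <= rec.dt + 1e-12
            assert abs(ev.tau_ms - tr.tau_1e) / tr.tau_1e < 0.01

    def test_recording_shorter_than_window_still_scanned(self):
        spec = SharpEventSpec(t_rise=1.0, amplitude=1.0, tau_decay=3.0)
        y, _ = sharp_waveform(spec, DT)
        rec = embed_events([(30, y)], n_total=y.size + 60)
        params = DetectionParams(auto_diameter_ms=1000.0, ma_window=20, min_amplitude=0.3)
        acc = [e for e in scan_auto(rec, params) if e.status == "accepted"]
        assert len(acc) == 1


class TestManualMode:
    def test_manual_equals_auto_at_same_peak(self, single_sharp_event):
        rec, truth, onset, spec = single_sharp_event
        auto = [e for e in scan_auto(rec, CLEAN) if e.status == "accepted"][0]
        manual = find_event_manual(rec, auto.peak_time_s, CLEAN)
        assert manual.peak_index == auto.peak_index
        assert manual.amplitude == pytest.approx(auto.amplitude)
        assert manual.tau_ms == pytest.approx(auto.tau_ms, rel=1e-6)

    def test_flat_baseline_with_min_amplitude_rejected(self):
        rec = Recording(sweeps=[np.zeros(5000)], dt=1e-4)
        ev = find_event_manual(rec, 0.25, CLEAN)
        assert ev.status == "rejected"
        assert ev.reject_reason == "amplitude"

    def test_larger_extremum_wins_within_radius(self):
        small, _ = sharp_waveform(SharpEventSpec(t_rise=1.0, amplitude=0.5, tau_decay=5.0), DT)
        big, _ = sharp_waveform(SharpEventSpec(t_rise=1.0, amplitude=1.5, tau_decay=5.0), DT)
        rec = embed_events([(500, small), (800, big)], n_total=2000)
        params = DetectionParams(search_radius_ms=25.0, ma_window=100, min_amplitude=0.3)
        ev = find_event_manual(rec, 0.065, params)  # radius covers both peaks
        assert ev.peak_index == 800 + 10
        assert ev.amplitude == pytest.approx(1.5, abs=0.01)


class TestCompound:
    def _pair(self, sep_ms: float):
        spec = SharpEventSpec(t_rise=0.5, amplitude=1.0, tau_decay=10.0)
        y, _ = sharp_waveform(spec, DT)
        onset1 = 500
        onset2 = onset1 + int(round(sep_ms / DT))  # equal rise: peak sep = onset sep
        rec = embed_events([(onset1, y), (onset2, y)], n_total=4000)
        return rec, onset1, onset2, spec

    def test_pair_at_30ms_separated_with_decay_subtraction(self):
        """Two summed A=1, tau=10 ms events 30 ms apart: the valley returns to
        ~5% of baseline, so both are kept and the later amplitude is measured
        from the extrapolated decay of the earlier (residue exp(-3) ~ 0.05)."""
        rec, onset1, onset2, spec = self._pair(30.0)
        params = DetectionParams(
            auto_diameter_ms=20.0, ma_window=100, min_amplitude=0.3,
            compound_enabled=True, min_peak_separation_ms=40.0, valley_percent=50.0,
        )
        acc = [e for e in scan_auto(rec, params) if e.status == "accepted"]
        assert len(acc) == 2
        assert acc[1].compound
        assert acc[0].amplitude == pytest.approx(1.0, abs=0.02)
        assert acc[1].amplitude == pytest.approx(1.0, abs=0.02)

    def test_pair_at_2ms_is_single_event(self):
        """At 2 ms separation no point between the peaks returns within 50% of
        baseline, so the trace is analysed as one event."""
        rec, onset1, onset2, spec = self._pair(2.0)
        params = DetectionParams(
            auto_diameter_ms=20.0, ma_window=100, min_amplitude=0.3,
            compound_enabled=True, min_peak_separation_ms=40.0, valley_percent=50.0,
        )
        acc = [e for e in scan_auto(rec, params) if e.status == "accepted"]
        assert len(acc) == 1

    def test_evoked_train_amplitudes_from_decayed_baseline(self):
        """A 20 Hz train surrogate (5 events, 50 ms apart, tau=15 ms): every
        event is detected and amplitudes are measured from the level to which
        the previous event has decayed, not from the original baseline."""
        spec = SharpEventSpec(t_rise=0.5, amplitude=1.0, tau_decay=15.0)
        y, _ = sharp_waveform(spec, DT)
        waves = [(1000 + k * 500, y) for k in range(5)]
        rec = embed_events(waves, n_total=6000)
        params = DetectionParams(
            auto_diameter_ms=20.0, ma_window=100, min_amplitude=0.3,
            compound_enabled=True, min_peak_separation_ms=60.0, valley_percent=80.0,
        )
        acc = [e for e in scan_auto(rec, params) if e.status == "accepted"]
        assert len(acc) == 5
        for ev in acc:
            assert ev.amplitude == pytest.approx(1.0, abs=0.02)
        assert all(e.compound for e in acc[1:])
        # each later event is measured from the decayed level of its
        # predecessors (exp(-50/15) ~ 0.036), not from the original 0 baseline
        for ev in acc[1:]:
            assert 0.02 < ev.baseline_value < 0.05


class TestResultsObject:
    def test_fit_returns_frame_and_summary(self, single_sharp_event):
        rec, *_ = single_sharp_event
        res = EventDetector(rec, CLEAN).fit()
        frame = res.to_frame()
        assert list(frame.columns) == [
            "sweep", "onset_time_s", "peak_time_s", "baseline", "amplitude",
            "rise_10_90_ms", "halfwidth_ms", "tau_ms", "compound", "status",
            "reject_reason",
        ]
        assert res.n_accepted == 1
        assert "accepted:          1" in res.summary()
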