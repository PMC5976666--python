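"""AP detection, kinetics, sweep-selection rules and spike-train statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicephys import (
    APEvent,
    PassiveModel,
    SpikeModel,
    StepDescriptor,
    ValidationError,
    ap_kinetics,
    cv_isi,
    detect_aps,
    rheobase,
    select_single_ap,
    select_train,
    sfa,
    simulate_spiking_sweep,
)
from slicephys.spikes import events_by_sweep

from conftest import flat_sweep, make_sweep, recording_from_sweeps


def triangular_spike_sweep(base_ms=2.0, height=80.0, rate=50_000.0):
    """Flat 0 mV trace with one symmetric triangular spike."""
    n = int(0.4 * rate)
    v = np.zeros(n)
    half = int(base_ms / 2 * 1e-3 * rate)
    apex = int(0.3 * rate)
    rise = np.linspace(0.0, height, half + 1)
    v[apex - half:apex + 1] = rise
    v[apex:apex + half + 1] = rise[::-1]
    return make_sweep(v, rate=rate, onset=0.1, duration=0.25)


def fabricated_event(t_thr, thr=-40.0, peak=40.0, dt=0.001):
    return APEvent(threshold_time_s=t_thr, threshold_v_mv=thr,
                   peak_time_s=t_thr + dt, peak_v_mv=peak,
                   amplitude_mv=peak - thr, halfwidth_ms=1.0)


def events_at(*latencies, onset=0.2):
    return [fabricated_event(onset + lat) for lat in latencies]


class TestDetection:
    def test_flat_trace_yields_nothing(self):
        assert detect_aps(flat_sweep(-70.0)) == []

    def test_detects_every_spliced_ap_at_log_times(self, quiet_passive):
        sm = SpikeModel()
        sweep, log = simulate_spiking_sweep(quiet_passive, sm,
                                            StepDescriptor(300.0, 0.2, 1.0))
        events = detect_aps(sweep)
        assert len(events) == len(log)
        det = np.array([e.threshold_time_s for e in events])
        true = np.array([e["time_s"] for e in log])
        assert np.max(np.abs(det - true)) <= 1.5 * sweep.dt

    def test_threshold_voltage_recovered_with_noise(self, passive):
        sm = SpikeModel(threshold_true_mv=-40.0)
        sweep, log = simulate_spiking_sweep(passive, sm,
                                            StepDescriptor(300.0, 0.2, 1.0),
                                            seed=5)
        events = detect_aps(sweep)
        assert len(events) == len(log)
        for e in events:
            assert e.threshold_v_mv == pytest.approx(-40.0, abs=1.0)

    def test_noise_alone_never_triggers(self):
        rng = np.random.default_rng(0)
        sweep = make_sweep(-70.0 + rng.normal(0, 0.3, 70_000))
        assert detect_aps(sweep) == []


class TestKinetics:
    def test_triangular_halfwidth_exact_by_interpolation(self):
        sweep = triangular_spike_sweep(base_ms=2.0, height=80.0)
        (event,) = detect_aps(sweep)
        amp, hw = ap_kinetics(sweep, event)
        assert hw == pytest.approx(1.0, abs=0.01)

    def test_amplitude_is_threshold_to_peak(self):
        # peak +10 mV from threshold -40 mV -> amplitude 50 mV
        e = APEvent(threshold_time_s=0.1, threshold_v_mv=-40.0,
                    peak_time_s=0.101, peak_v_mv=10.0, amplitude_mv=50.0,
                    halfwidth_ms=1.0)
        assert e.amplitude_mv == pytest.approx(10.0 - (-40.0))

    def test_template_kinetics_recovered(self, quiet_passive):
        sm = SpikeModel(amplitude_true_mv=80.0, halfwidth_true_ms=1.0)
        sweep, _ = simulate_spiking_sweep(quiet_passive, sm,
                                          StepDescriptor(300.0, 0.2, 1.0))
        event = detect_aps(sweep)[0]
        amp, hw = ap_kinetics(sweep, event)
        assert amp == pytest.approx(80.0, abs=1.0)
        assert hw == pytest.approx(1.0, abs=0.05)

    def test_truncated_repolarization_flags_halfwidth(self):
        rate = 50_000.0
        n = int(0.3 * rate)
        v = np.full(n, -70.0)
        v[-40:] = np.linspace(-70.0, 40.0, 40)  # rise, never repolarizes
        sweep = make_sweep(v, rate=rate, onset=0.1, duration=0.15)
        (event,) = detect_aps(sweep)
        _, hw = ap_kinetics(sweep, event)
        assert hw is None


class TestSelectionRules:
    def recording(self, amps):
        sweeps = [flat_sweep(amplitude=a, n=70_000, sweep_id=f"s{a:+.0f}")
                  for a in amps]
        return recording_from_sweeps(sweeps)

    def test_single_ap_window_unique_qualifier(self):
        rec = self.recording([200.0, 250.0])
        events = {"s+200": [], "s+250": events_at(0.045)}
        sweep, event, fallback = select_single_ap(rec, events)
        assert sweep.step.amplitude_pa == 250.0 and not fallback

    def test_single_ap_lowest_amplitude_wins(self):
        rec = self.recording([200.0, 250.0])
        events = {"s+200": events_at(0.048), "s+250": events_at(0.042)}
        sweep, _, fallback = select_single_ap(rec, events)
        assert sweep.step.amplitude_pa == 200.0 and not fallback

    def test_single_ap_fallback_to_rheobase_sweep(self):
        rec = self.recording([200.0, 250.0])
        events = {"s+200": events_at(0.085), "s+250": events_at(0.012)}
        sweep, event, fallback = select_single_ap(rec, events)
        assert fallback
        assert sweep.step.amplitude_pa == 200.0
        assert event is events["s+200"][0]

    def test_rheobase_first_spiking_amplitude(self):
        rec = self.recording([100.0, 200.0, 300.0])
        events = {"s+100": [], "s+200": events_at(0.05), "s+300": events_at(0.02)}
        assert rheobase(rec, events) == 200.0
        assert rheobase(rec, {k: [] for k in events}) is None

    def test_train_selection_closest_to_ten(self):
        rec = self.recording([100.0, 200.0, 300.0])
        events = {"s+100": events_at(*np.linspace(0.01, 0.9, 4)),
                  "s+200": events_at(*np.linspace(0.01, 0.9, 9)),
                  "s+300": events_at(*np.linspace(0.01, 0.9, 15))}
        sweep, train = select_train(rec, events)
        assert sweep.step.amplitude_pa == 200.0 and len(train) == 9

    def test_train_tie_goes_to_lower_amplitude(self):
        rec = self.recording([100.0, 200.0])
        events = {"s+100": events_at(*np.linspace(0.01, 0.9, 8)),
                  "s+200": events_at(*np.linspace(0.01, 0.9, 12))}
        sweep, train = select_train(rec, events)
        assert sweep.step.amplitude_pa == 100.0 and len(train) == 8

    def test_no_qualifying_train(self):
        rec = self.recording([100.0])
        events = {"s+100": events_at(*np.linspace(0.01, 0.9, 5))}
        assert select_train(rec, events) is None


class TestTrainStatistics:
    def from_isis(self, isis_ms):
        t, out = 0.1, []
        out.append(fabricated_event(t))
        for isi in isis_ms:
            t += isi * 1e-3
            out.append(fabricated_event(t))
        return out

    def test_sfa_ratio_of_last_to_first_isi(self):
        assert sfa(self.from_isis([50, 60, 75, 100])) == pytest.approx(2.0)
        assert sfa(self.from_isis([80, 80, 80])) == pytest.approx(1.0)

    def test_cv_sample_sd_over_mean(self):
        assert cv_isi(self.from_isis([100, 100, 100])) == pytest.approx(0.0)
        # sd1([50,100]) = 35.355.., mean 75
        assert cv_isi(self.from_isis([50, 100])) == pytest.approx(
            np.sqrt(1250.0) / 75.0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            sfa(self.from_isis([50]))
        with pytest.raises(ValidationError):
            cv_isi(self.from_isis([50]))

    def test_statistics_match_event_log_oracle(self, quiet_passive):
        sm = SpikeModel(adaptation_strength=1.2)
        _, log = simulate_spiking_sweep(quiet_passive, sm,
                                        StepDescriptor(300.0, 0.2, 1.0))
        isis = np.diff([e["time_s"] for e in log])
        events = self.from_isis([])  # rebuild from log times
        events = [fabricated_event(e["time_s"]) for e in log]
        assert sfa(events) == pytest.approx(isis[-1] / isis[0], rel=1e-12)
        assert cv_isi(events) == pytest.approx(
            np.std(isis, ddof=1) / np.mean(isis), rel=1e-12)

    @given(shift=st.floats(-5.0, 5.0, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, shift):
        isis = [40, 55, 80, 95]
        base = self.from_isis(isis)
        shifted = [fabricated_event(e.threshold_time_s + 10.0 + shift)
                   for e in base]
        assert sfa(shifted) == pytest.approx(sfa(base), rel=1e-9)
        assert cv_isi(shifted) == pytest.approx(cv_isi(base), rel=1e-9)


def test_spike_count_monotone_in_amplitude(quiet_passive):
    sm = SpikeModel(adaptation_strength=1.0)
    counts = []
    for amp in (200.0, 250.0, 300.0, 350.0, 400.0):
        _, log = simulate_spiking_sweep(quiet_passive, sm,
                                        StepDescriptor(amp, 0.2, 1.0))
        counts.append(len(log))
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_events_by_sweep_covers_all_sweeps(quiet_passive):
    sm = SpikeModel()
    sweeps = []
    for k, amp in enumerate((-50.0, 300.0)):
        sweep, _ = simulate_spiking_sweep(quiet_passive, sm,
                                          StepDescriptor(amp, 0.2, 1.0),
                                          sweep_id=f"s{k}")
        sweeps.append(sweep)
    rec = recording_from_sweeps(sweeps)
    ev = events_by_sweep(rec)
    assert set(ev) == {"s0", "s1"}
    assert not ev["s0"] and ev["s1"]
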