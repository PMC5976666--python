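"""Simulator ground truth, determinism and limiting cases."""

import numpy as np
import pytest

from slicephys import (
    CalciumModel,
    CohortSpec,
    PassiveModel,
    SpikeModel,
    StepDescriptor,
    ValidationError,
    compute_dff,
    simulate_cohort,
    simulate_fluorescence,
    simulate_neuron,
    simulate_passive_sweep,
    simulate_spiking_sweep,
)
from slicephys.synth import (
    build_ap_template,
    default_protocol,
    draw_cohort_parameters,
    peak_dff_per_spike,
    true_dff,
)


def dense_bracket_oracle(model, t_ms):
    """Independent closed-form evaluation of the effective-resistance curve."""
    r_ss = model.r_input_mohm - model.r_sag_mohm
    gm = 1.0 - np.exp(-t_ms / model.tau_m_ms)
    gh = 1.0 - np.exp(-t_ms / model.tau_h_ms)
    return r_ss * gm + model.r_sag_mohm * (gm - gh)


class TestPassive:
    def test_no_sag_limit_monotone_charging(self, step_m100):
        m = PassiveModel(r_input_mohm=150.0, r_sag_mohm=0.0, noise_sd_mv=0.0)
        sweep, gt = simulate_passive_sweep(m, step_m100)
        i0, i1 = sweep.index_at(0.2), sweep.index_at(1.2)
        seg = sweep.voltage_mv[i0:i1]
        assert np.all(np.diff(seg) <= 1e-12)  # monotone hyperpolarizing charge
        assert seg[-1] == pytest.approx(-69.0 - 100 * 150 / 1000, abs=1e-6)
        assert gt["sag_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_steady_state_deflection_arithmetic(self, quiet_passive, step_m100):
        # 100 pA x 120 MOhm = 12 mV
        sweep, gt = simulate_passive_sweep(quiet_passive, step_m100)
        assert gt["rn_ss"] == 120.0
        ss = sweep.voltage_mv[sweep.index_at(1.2) - 1]
        assert ss == pytest.approx(-69.0 - 12.0, abs=1e-4)

    def test_rn_max_matches_dense_grid_oracle(self, quiet_passive):
        t = np.arange(0.0, 1000.0, 0.005)
        oracle = float(np.max(dense_bracket_oracle(quiet_passive, t)))
        _, gt = simulate_passive_sweep(quiet_passive, StepDescriptor(-100, 0.2, 1.0))
        assert gt["rn_max"] == pytest.approx(oracle, rel=1e-6)
        assert gt["sag_ratio"] == pytest.approx(oracle / 120.0, rel=1e-6)

    def test_noiseless_linearity_of_deflections(self, quiet_passive):
        # IV fit over noiseless deflections is linear to machine precision
        from slicephys import fit_iv_points, step_deflections
        currents, maxima, plateaus = [], [], []
        for amp in (-150.0, -100.0, -50.0, 50.0):
            sweep, _ = simulate_passive_sweep(quiet_passive,
                                              StepDescriptor(amp, 0.2, 1.0))
            mx, ss = step_deflections(sweep)
            currents.append(amp); maxima.append(mx); plateaus.append(ss)
        curve = fit_iv_points(currents, maxima, plateaus)
        assert curve.fit_ss[2] > 1 - 1e-10
        assert curve.fit_max[2] > 1 - 1e-10

    def test_rejects_nonpositive_rate(self, quiet_passive, step_m100):
        with pytest.raises(ValidationError):
            simulate_passive_sweep(quiet_passive, step_m100, sampling_rate=0.0)


class TestSpiking:
    def test_no_adaptation_gives_constant_isis(self, quiet_passive):
        sm = SpikeModel(adaptation_strength=0.0)
        _, log = simulate_spiking_sweep(quiet_passive, sm,
                                        StepDescriptor(320.0, 0.2, 1.0))
        times = np.array([e["time_s"] for e in log])
        isis = np.diff(times)
        assert len(log) >= 3
        assert np.ptp(isis) <= 2.5e-5  # one sample at 50 kHz

    def test_adaptation_lengthens_isis(self, quiet_passive):
        sm = SpikeModel(adaptation_strength=1.5)
        _, log = simulate_spiking_sweep(quiet_passive, sm,
                                        StepDescriptor(320.0, 0.2, 1.0))
        isis = np.diff([e["time_s"] for e in log])
        assert len(isis) >= 2
        # ISIs lengthen monotonically, strictly so until the adaptation
        # current reaches its spike-rate equilibrium
        assert np.all(np.diff(isis) >= -1e-12)
        assert isis[1] > isis[0]
        assert isis[-1] / isis[0] > 1.2

    def test_subthreshold_step_gives_empty_log(self, quiet_passive, spike_model):
        _, log = simulate_spiking_sweep(quiet_passive, spike_model,
                                        StepDescriptor(100.0, 0.2, 1.0))
        assert log == []

    def test_template_halfwidth_is_analytic(self, spike_model):
        # continuous-waveform width at half amplitude == halfwidth_true
        dt = 1e-4  # 10 MHz grid: discretization negligible
        u = build_ap_template(spike_model, dt)
        a = spike_model.amplitude_true_mv
        above = np.flatnonzero(u >= a / 2)
        width = (above[-1] - above[0] + 1) * dt
        assert width == pytest.approx(spike_model.halfwidth_true_ms, abs=1e-3)
        assert np.max(u) == pytest.approx(a, abs=0.02)  # sampled corner

    def test_infeasible_halfwidth_rejected(self):
        with pytest.raises(ValidationError, match="halfwidth"):
            SpikeModel(halfwidth_true_ms=0.2, upstroke_rate_mv_ms=100.0)


class TestNeuronAndCohort:
    def test_default_protocol_yields_12_sweeps(self, quiet_passive, spike_model):
        rec, _ = simulate_neuron(quiet_passive, spike_model, seed=0)
        assert len(rec.sweeps) == 12

    def test_seed_determinism_bit_identical(self, passive, spike_model):
        protocol = default_protocol(-100, 300, 100)
        rec1, _ = simulate_neuron(passive, spike_model, protocol, 20_000.0, seed=7)
        rec2, _ = simulate_neuron(passive, spike_model, protocol, 20_000.0, seed=7)
        for a, b in zip(rec1.sweeps, rec2.sweeps):
            np.testing.assert_array_equal(a.voltage_mv, b.voltage_mv)

    def test_ground_truth_rheobase_from_noiseless_scan(self, quiet_passive,
                                                       spike_model):
        # threshold -40, rest -69, r_ss 120 MOhm -> analytic rheobase just
        # under 250 pA; with 50 pA steps the first spiking step is +250
        rec, truth = simulate_neuron(quiet_passive, spike_model, seed=1)
        assert truth["rheobase"] == 250.0
        spiking = [sid for sid, log in truth["event_logs"].items() if log]
        amps = {s.sweep_id: s.step.amplitude_pa for s in rec.sweeps}
        assert min(amps[sid] for sid in spiking) == 250.0

    def test_event_log_matches_spliced_waveforms(self, quiet_passive, spike_model):
        sweep, log = simulate_spiking_sweep(quiet_passive, spike_model,
                                            StepDescriptor(300.0, 0.2, 1.0))
        overshoot = spike_model.overshoot_mv()
        # count waveform peaks present in the trace
        peaks = np.flatnonzero(sweep.voltage_mv > overshoot - 2.0)
        n_groups = 1 + int(np.sum(np.diff(peaks) > 1)) if peaks.size else 0
        assert n_groups == len(log)

    def test_cohort_zero_variance_collapses_to_mean(self):
        spec = CohortSpec(n_neurons=5, features={"v_rest_mv": (-65.0, 0.0)},
                          seed=3)
        params = draw_cohort_parameters(spec)
        assert np.allclose(params["v_rest_mv"], -65.0)

    def test_cohort_seeds_differ_but_specs_match(self):
        spec_a = CohortSpec(n_neurons=200, seed=1)
        spec_b = CohortSpec(n_neurons=200, seed=2)
        pa, pb = draw_cohort_parameters(spec_a), draw_cohort_parameters(spec_b)
        assert not np.allclose(pa["v_rest_mv"], pb["v_rest_mv"])
        assert np.mean(pa["v_rest_mv"]) == pytest.approx(
            np.mean(pb["v_rest_mv"]), abs=1.0)

    def test_simulate_cohort_truth_table_columns(self):
        spec = CohortSpec(n_neurons=2, seed=0)
        protocol = default_protocol(-150, -50, 50, onset_s=0.15, duration_s=0.4)
        recs, truth = simulate_cohort(spec, protocol, sampling_rate=10_000.0)
        assert len(recs) == 2
        assert {"rmp_mV", "rn_ss_MOhm", "sag_ratio"} <= set(truth.columns)

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_neurons=0)


class TestFluorescence:
    def test_no_spikes_flat_at_f0(self):
        m = CalciumModel(noise_sd=0.0)
        trace, dff = simulate_fluorescence([], m, duration_s=5.0)
        assert np.allclose(trace.f, m.f0_true)
        assert np.allclose(dff, 0.0)

    def test_single_spike_peak_matches_dense_grid(self):
        m = CalciumModel(noise_sd=0.0)
        trace, dff = simulate_fluorescence([1.0], m, duration_s=8.0,
                                           sampling_rate=1_000.0)
        assert np.max(dff) == pytest.approx(peak_dff_per_spike(m), rel=1e-4)

    def test_normalization_invariance_to_f_range(self):
        spikes = [1.0, 1.5, 2.0]
        narrow = CalciumModel(f0_true=50.0, fb_true=20.0, noise_sd=0.0)
        wide = CalciumModel(f0_true=80.0, fb_true=20.0, noise_sd=0.0)
        out = []
        for m in (narrow, wide):
            trace, _ = simulate_fluorescence(spikes, m, duration_s=6.0)
            out.append(compute_dff(trace).dff)
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValidationError):
            simulate_fluorescence([], CalciumModel(), duration_s=0.0)

    def test_spikes_outside_duration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_fluorescence([9.0], CalciumModel(), duration_s=5.0)

    def test_true_dff_is_causal(self):
        m = CalciumModel(noise_sd=0.0)
        t = np.linspace(0, 4, 500)
        dff = true_dff([2.0], m, t)
        assert np.all(dff[t < 2.0] == 0.0)
        assert dff[-1] > 0
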