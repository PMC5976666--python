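"""Parameter-recovery validation suite.

Every analysis stage in this package is exercised against the forward
simulators, whose feature values are exact by construction.  The functions
here run those recovery studies at standard sizes and return raw per-case
results, so calling code (tests, reports, scripts) can summarize or assert on
them.  All randomness flows from an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .calcium import compute_dff, stim_response_curve
from .intrinsic import build_iv_curve, input_resistance, sag_ratio
from .models import FeatureRow, NeuronRecording, StepDescriptor, Sweep
from .pipeline import extract_features
from .spikes import ap_kinetics, cv_isi, detect_aps, sfa
from .synth import (
    CalciumModel,
    CohortSpec,
    PassiveModel,
    SpikeModel,
    build_ap_template,
    bout_spike_times,
    default_protocol,
    passive_ground_truth,
    simulate_cohort,
    simulate_fluorescence,
    simulate_passive_sweep,
)

IV_PROTOCOL = default_protocol(-150, 50, 50)


# ---------------------------------------------------------------------------
# subthreshold recovery
# ---------------------------------------------------------------------------

def subthreshold_recovery_grid(n_grid: int = 5, noise_sd_mv: float = 0.2,
                               seed: int = 0,
                               sampling_rate: float = 50_000.0) -> pd.DataFrame:
    """Recover R_N (steady-state) and sag over a grid of passive models.

    Grid: r_input 80–300 MΩ × r_sag 0–60 MΩ, each simulated with the
    subthreshold IV protocol at the given measurement noise; one row per grid
    point with true and extracted values.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r_input in np.linspace(80.0, 300.0, n_grid):
        for r_sag in np.linspace(0.0, 60.0, n_grid):
            model = PassiveModel(r_input_mohm=r_input, r_sag_mohm=r_sag,
                                 noise_sd_mv=noise_sd_mv)
            truth = passive_ground_truth(model)
            sweeps = [
                simulate_passive_sweep(model, step, sampling_rate, rng,
                                       sweep_id=f"s{k}")[0]
                for k, step in enumerate(IV_PROTOCOL)
            ]
            rec = NeuronRecording(neuron_id="grid", sweeps=sweeps)
            rn_max, rn_ss = input_resistance(build_iv_curve(rec))
            rows.append({
                "r_input": r_input, "r_sag": r_sag,
                "rn_ss_true": truth["rn_ss"], "rn_ss_est": rn_ss,
                "sag_true": truth["sag_ratio"],
                "sag_est": sag_ratio(rn_max, rn_ss),
            })
    df = pd.DataFrame(rows)
    df["rn_ss_rel_err"] = (df.rn_ss_est - df.rn_ss_true).abs() / df.rn_ss_true
    df["sag_abs_err"] = (df.sag_est - df.sag_true).abs()
    return df


# ---------------------------------------------------------------------------
# AP kinetics recovery
# ---------------------------------------------------------------------------

def _single_ap_sweep(spikes: SpikeModel, v_rest: float, noise_sd: float,
                     rng: np.random.Generator,
                     sampling_rate: float) -> tuple[Sweep, SpikeModel]:
    """One AP on a slow depolarizing approach ramp, plus relaxation tail."""
    dt_ms = 1e3 / sampling_rate
    baseline = np.full(int(0.1 * sampling_rate), v_rest)
    ramp_n = int(0.02 * sampling_rate)
    ramp = np.linspace(v_rest, spikes.threshold_true_mv, ramp_n, endpoint=False)
    tmpl = spikes.threshold_true_mv + build_ap_template(spikes, dt_ms)
    tail_n = int(0.05 * sampling_rate)
    tail = v_rest + (tmpl[-1] - v_rest) * np.exp(
        -np.arange(1, tail_n + 1) * dt_ms / 20.0)
    v = np.concatenate([baseline, ramp, tmpl, tail])
    v = v + rng.normal(0.0, noise_sd, size=v.size)
    onset = 0.1
    duration = (v.size / sampling_rate) - onset - 1e-4
    return Sweep(voltage_mv=v, sampling_rate_hz=sampling_rate,
                 step=StepDescriptor(300.0, onset, duration), sweep_id="ap"), spikes


def ap_kinetics_recovery(n: int = 500, noise_sd_mv: float = 0.1, seed: int = 0,
                         sampling_rate: float = 50_000.0) -> pd.DataFrame:
    """Detect + measure n random template APs; per-AP recovery errors."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        spikes = SpikeModel(
            threshold_true_mv=rng.uniform(-45.0, -35.0),
            amplitude_true_mv=rng.uniform(70.0, 100.0),
            halfwidth_true_ms=rng.uniform(0.6, 1.5),
            upstroke_rate_mv_ms=rng.uniform(250.0, 500.0),
        )
        sweep, _ = _single_ap_sweep(spikes, -69.0, noise_sd_mv, rng, sampling_rate)
        events = detect_aps(sweep)
        if len(events) != 1:
            rows.append({"detected": len(events), "thr_err": np.inf,
                         "amp_err": np.inf, "hw_err": np.inf})
            continue
        amp, hw = ap_kinetics(sweep, events[0])
        rows.append({
            "detected": 1,
            "thr_err": abs(events[0].threshold_v_mv - spikes.threshold_true_mv),
            "amp_err": abs(amp - spikes.amplitude_true_mv),
            "hw_err": np.inf if hw is None else abs(hw - spikes.halfwidth_true_ms),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spike-train oracle
# ---------------------------------------------------------------------------

def spike_train_oracle_check(n: int = 1000, noise_sd_mv: float = 0.3,
                             seed: int = 0,
                             sampling_rate: float = 50_000.0) -> pd.DataFrame:
    """Detection vs event-log recomputation on random adapting trains.

    Per train: spike counts from detection and from the simulator log, the
    worst threshold-time discrepancy in samples, SFA and CV from both routes,
    and the timing-jitter bounds implied by a few samples of threshold
    uncertainty.
    """
    from .synth import simulate_spiking_sweep

    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    rows = []
    for _ in range(n):
        v_rest = rng.uniform(-72.0, -66.0)
        thr = rng.uniform(-42.0, -38.0)
        passive = PassiveModel(
            v_rest_mv=v_rest,
            r_input_mohm=rng.uniform(100.0, 250.0),
            r_sag_mohm=rng.uniform(0.0, 50.0),
            noise_sd_mv=noise_sd_mv,
        )
        spikes = SpikeModel(
            threshold_true_mv=thr,
            amplitude_true_mv=rng.uniform(70.0, 95.0),
            halfwidth_true_ms=rng.uniform(0.7, 1.4),
            upstroke_rate_mv_ms=rng.uniform(250.0, 450.0),
            adaptation_strength=rng.uniform(0.8, 2.0),
        )
        i_rheo = (thr - v_rest) / passive.r_ss_mohm * 1000.0
        step = StepDescriptor(i_rheo + rng.uniform(30.0, 80.0), 0.2, 1.0)
        sweep, log = simulate_spiking_sweep(passive, spikes, step,
                                            sampling_rate, rng, tail_s=0.05)
        events = detect_aps(sweep)
        row = {"n_log": len(log), "n_det": len(events)}
        if len(events) == len(log) and len(log) >= 1:
            det_t = np.array([e.threshold_time_s for e in events])
            log_t = np.array([e["time_s"] for e in log])
            row["max_time_err_samples"] = float(np.max(np.abs(det_t - log_t)) / dt)
        else:
            row["max_time_err_samples"] = np.inf
        if len(events) == len(log) and len(log) >= 3:
            isis = np.diff([e["time_s"] for e in log])
            first, last = isis[0], isis[-1]
            e_t = 5.0 * dt  # timing slack: a few samples of threshold jitter
            row.update({
                "sfa_log": last / first,
                "sfa_det": sfa(events),
                "sfa_bound": (last + e_t) / (first - e_t)
                - (last - e_t) / (first + e_t),
                "cv_log": float(np.std(isis, ddof=1) / np.mean(isis)),
                "cv_det": cv_isi(events),
                "cv_bound": 6.0 * e_t / float(np.mean(isis)),
            })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics oracles and calibration
# ---------------------------------------------------------------------------

def mwu_oracle_check(n_cases: int = 1000, seed: int = 0) -> float:
    """Fraction of random small-sample cases where the rank-based U equals
    the exhaustive pair-count double loop."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cases):
        a = rng.integers(1, 9, size=rng.integers(2, 7)).astype(float)
        b = rng.integers(1, 9, size=rng.integers(2, 7)).astype(float)
        brute = sum(1.0 if x < y else 0.5 if x == y else 0.0
                    for x in a for y in b)
        res = stats.mann_whitney_u(a, b)
        hits += abs(res.extra["u_ab"] - brute) < 1e-9
    return hits / n_cases


def welch_closed_form_diff() -> float:
    """|package Welch t − hand-evaluated formula| on fixed vectors."""
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
    hand = (a.mean() - b.mean()) / np.sqrt(
        a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return abs(stats.welch_t(a, b).statistic - hand)


def regression_r2_identity_diff(seed: int = 0, n: int = 200) -> float:
    """|r² − squared Pearson r| on random regression data."""
    rng = np.random.default_rng(seed)
    h = rng.uniform(1, 75, n)
    y = -69 + 0.05 * h + rng.normal(0, 2, n)
    df = pd.DataFrame({"hours_post_slicing": h, "rmp_mV": y})
    res = stats.feature_vs_time(df, "rmp_mV")
    r = float(np.corrcoef(h, y)[0, 1])
    return abs(res.r_squared - r**2)


def null_calibration(n_sims: int = 1000, seed: int = 0, alpha: float = 0.05
                     ) -> dict:
    """Empirical type-I error of feature_vs_time (n=100) and welch_t (20/20)."""
    rng = np.random.default_rng(seed)
    reg_hits = 0
    for _ in range(n_sims):
        h = rng.uniform(1, 75, 100)
        y = rng.normal(-69.0, 2.0, 100)
        reg_hits += sps.linregress(h, y).pvalue < alpha
    # cross-check a subsample through the package surface
    df = pd.DataFrame({"hours_post_slicing": rng.uniform(1, 75, 100),
                       "rmp_mV": rng.normal(-69, 2, 100)})
    stats.feature_vs_time(df, "rmp_mV")
    welch_hits = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.0, 1.0, 20)
        welch_hits += stats.welch_t(a, b).p_value < alpha
    return {"regression_type1": reg_hits / n_sims,
            "welch_type1": welch_hits / n_sims}


# ---------------------------------------------------------------------------
# cohort drift recovery
# ---------------------------------------------------------------------------

#: Reduced per-neuron protocol for cohort-scale runs: three hyperpolarizing
#: steps, enough for RMP and the subthreshold IV fit.
COHORT_PROTOCOL = default_protocol(-150, -50, 50, onset_s=0.15, duration_s=0.4)


def drift_recovery(n_cohorts: int = 200, n_neurons: int = 100, seed: int = 0,
                   drift_mv_per_h: float = 0.1, rmp_sd_mv: float = 2.0,
                   sampling_rate: float = 10_000.0) -> dict:
    """Recover an RMP drift (mV/h) from full trace-level cohort simulations.

    Each cohort draws v_rest = β0 + drift·hours + N(0, sd) over 1–75 h,
    simulates the reduced subthreshold protocol per neuron, extracts features
    and regresses extracted RMP (and the drift-free steady-state R_N) on
    hours.  Returns the mean and spread of recovered slopes.
    """
    base = np.random.SeedSequence(seed)
    rmp_slopes, rn_slopes = [], []
    for child in base.spawn(n_cohorts):
        cohort_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = CohortSpec(
            n_neurons=n_neurons,
            features={
                "v_rest_mv": (-69.0, rmp_sd_mv),
                "r_input_mohm": (150.0, 20.0),
                "r_sag_mohm": (30.0, 8.0),
            },
            effects={"v_rest_mv": drift_mv_per_h},
            seed=cohort_seed,
        )
        recordings, _ = simulate_cohort(spec, COHORT_PROTOCOL, sampling_rate)
        rows = [extract_features(rec) for rec in recordings]
        df = pd.DataFrame({
            "hours_post_slicing": [r.hours_post_slicing for r in rows],
            "rmp_mV": [r.rmp_mv for r in rows],
            "rn_ss_MOhm": [r.rn_ss_mohm for r in rows],
        })
        rmp_slopes.append(stats.feature_vs_time(df, "rmp_mV").slope)
        rn_slopes.append(stats.feature_vs_time(df, "rn_ss_MOhm").slope)
    rmp_slopes = np.asarray(rmp_slopes)
    rn_slopes = np.asarray(rn_slopes)
    return {
        "true_slope": drift_mv_per_h,
        "mean_rmp_slope": float(np.mean(rmp_slopes)),
        "sem_rmp_slope": float(np.std(rmp_slopes, ddof=1) / np.sqrt(n_cohorts)),
        "mean_null_slope": float(np.mean(rn_slopes)),
        "sem_null_slope": float(np.std(rn_slopes, ddof=1) / np.sqrt(n_cohorts)),
        "n_cohorts": n_cohorts,
    }


# ---------------------------------------------------------------------------
# ΔF/F checks
# ---------------------------------------------------------------------------

def dff_worked_example() -> float:
    """ΔF/F of the analytic case F = 30, F0 = 20, FB = 10."""
    from .models import FluorescenceTrace

    rate = 100.0
    f = np.full(200, 20.0)
    f[50:] = 30.0
    trace = FluorescenceTrace(f=f, sampling_rate_hz=rate, roi_id="worked",
                              background_f=10.0)
    return float(compute_dff(trace, stim_onset_s=0.5).dff[-1])


def dff_roundtrip_rmse(seed: int = 0, n_traces: int = 20) -> dict:
    """RMSE of recovered vs true ΔF/F on noisy generator traces.

    Returns the worst trace RMSE and the bound 2·noise_sd/(F0 − FB).
    """
    rng = np.random.default_rng(seed)
    model = CalciumModel()  # noise_sd 1, f0-fb = 80
    worst = 0.0
    for k in range(n_traces):
        spikes = np.sort(rng.uniform(1.0, 8.0, rng.integers(1, 10)))
        trace, truth = simulate_fluorescence(spikes, model, 10.0,
                                             seed=rng)
        rec = compute_dff(trace)
        worst = max(worst, float(np.sqrt(np.mean((rec.dff - truth) ** 2))))
    bound = 2.0 * model.noise_sd / (model.f0_true - model.fb_true)
    return {"worst_rmse": worst, "bound": bound}


def stim_response_monotonicity(seed: int = 0,
                               freqs=(1.0, 5.0, 10.0, 25.0, 50.0)) -> dict:
    """Peak ΔF/F per bout frequency under linear summation."""
    model = CalciumModel()
    spacing = 6.0
    onsets = [2.0 + k * spacing for k in range(len(freqs))]
    spike_times = []
    for onset, f in zip(onsets, freqs):
        spike_times.extend(bout_spike_times(onset, f))
    trace, _ = simulate_fluorescence(sorted(spike_times), model,
                                     onsets[-1] + spacing, seed=seed,
                                     stim_onsets_s=onsets)
    curve = stim_response_curve(trace, list(zip(onsets, freqs)))
    peaks = [p for _, p in sorted(curve)]
    increasing = all(b > a for a, b in zip(peaks, peaks[1:]))
    return {"peaks": peaks, "strictly_increasing": increasing}


# ---------------------------------------------------------------------------
# QC fixture
# ---------------------------------------------------------------------------

def qc_fixture_check() -> dict:
    """Constructed 10-neuron cohort: 7 healthy, 3 violating the criteria."""
    rows = [FeatureRow(neuron_id=f"ok{k}", rmp_mv=-60.0 - k,
                       max_ap_peak_mv=5.0 + k) for k in range(7)]
    rows += [
        FeatureRow(neuron_id="bad_rmp", rmp_mv=-49.0, max_ap_peak_mv=20.0),
        FeatureRow(neuron_id="bad_overshoot", rmp_mv=-65.0, max_ap_peak_mv=-5.0),
        FeatureRow(neuron_id="bad_both", rmp_mv=-40.0, max_ap_peak_mv=-1.0),
    ]
    passing, log = stats.apply_inclusion_filter(rows)
    return {"n_pass": len(passing), "n_total": len(rows),
            "rejections": {e["neuron_id"]: e["reasons"] for e in log}}
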