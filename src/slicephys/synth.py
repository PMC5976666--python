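"""Forward simulators with exact ground truth.

The package's recordings of origin (human ex vivo cortical neurons) are not
publicly deposited, so every analysis stage is validated against synthetic
sweeps whose feature values are known by construction:

* passive sweeps from a closed-form two-exponential membrane response
  (fast charging component ``tau_m`` plus a slower opposing "sag" component
  ``tau_h``, emulating the Ih-mediated depolarizing sag of deep hyperpolarizing
  steps);
* spiking sweeps from an adaptive integrate-and-fire update with a spliced
  parametric AP waveform whose threshold, threshold-to-peak amplitude and
  half-width are analytic;
* GCaMP6s-like fluorescence built by linear summation of per-spike
  double-exponential transients.

Between spikes the integrate-and-fire system (leaky membrane + exponentially
decaying adaptation current) is linear, so it is advanced by its exact
closed-form solution evaluated on the sample grid; spikes are emitted at the
first grid sample at or above threshold, which keeps event logs grid-aligned
and bit-reproducible.

Measurement noise is additive white Gaussian on the recorded trace only;
spike timing and all ground-truth values are therefore independent of the
noise draw.  (No pink/synaptic noise, no bleaching or motion artifacts —
documented limitations.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    FluorescenceTrace,
    NeuronRecording,
    StepDescriptor,
    Sweep,
    ValidationError,
)

DEFAULT_SWEEP_RATE_HZ = 50_000.0
DEFAULT_FRAME_RATE_HZ = 30.0

#: Default sweep layout: 200 ms baseline, 1 s step, 200 ms tail.
DEFAULT_STEP = StepDescriptor(amplitude_pa=0.0, onset_s=0.2, duration_s=1.0)
DEFAULT_TAIL_S = 0.2


def default_protocol(start_pa: float = -150.0, stop_pa: float = 400.0,
                     increment_pa: float = 50.0,
                     onset_s: float = 0.2, duration_s: float = 1.0) -> list[StepDescriptor]:
    """The standard per-neuron step family: 1 s steps, −150 pA upward.

    With the defaults this is −150…+400 pA in 50 pA increments (12 sweeps),
    the subthreshold IV portion plus larger suprathreshold steps.
    """
    amps = np.arange(start_pa, stop_pa + 0.5 * increment_pa, increment_pa)
    return [StepDescriptor(float(a), onset_s, duration_s) for a in amps]


@dataclass(frozen=True)
class PassiveModel:
    """Subthreshold membrane model.

    ``r_input`` is the instantaneous (peak) resistance in MΩ; ``r_sag`` the
    slow opposing component, so the steady-state resistance is
    ``r_ss = r_input − r_sag``.  ``tau_m`` / ``tau_h`` are the fast and slow
    time constants in ms; ``noise_sd`` the measurement-noise SD in mV.
    """

    v_rest_mv: float = -69.0
    r_input_mohm: float = 150.0
    r_sag_mohm: float = 30.0
    tau_m_ms: float = 20.0
    tau_h_ms: float = 80.0
    noise_sd_mv: float = 0.2

    def __post_init__(self) -> None:
        if not (self.r_input_mohm > self.r_sag_mohm >= 0):
            raise ValidationError("need r_input > r_sag >= 0")
        if not (self.tau_h_ms > self.tau_m_ms > 0):
            raise ValidationError("need tau_h > tau_m > 0")
        if self.noise_sd_mv < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def r_ss_mohm(self) -> float:
        return self.r_input_mohm - self.r_sag_mohm


@dataclass(frozen=True)
class SpikeModel:
    """AP waveform and firing-dynamics parameters.

    The spliced waveform rises from ``threshold_true`` with initial slope
    ``upstroke_rate`` (piecewise-exponential rise saturating toward a 1.5×
    amplitude asymptote, truncated at the peak), then decays exponentially
    toward a −``ahp_depth`` afterhyperpolarization.  The fall time constant is
    solved analytically so the width at half threshold-to-peak amplitude is
    ``halfwidth_true`` exactly on the continuous waveform.

    ``adaptation_strength`` scales the per-spike adaptation-current increment
    (``adapt_increment_pa``); the increment decays with ``tau_w_ms``,
    producing graded spike-frequency accommodation.
    """

    threshold_true_mv: float = -40.0
    amplitude_true_mv: float = 80.0
    halfwidth_true_ms: float = 1.0
    upstroke_rate_mv_ms: float = 300.0
    adaptation_strength: float = 1.0
    refractory_ms: float = 2.0
    ahp_depth_mv: float = 12.0
    adapt_increment_pa: float = 25.0
    tau_w_ms: float = 250.0

    def __post_init__(self) -> None:
        if not self.amplitude_true_mv > 0:
            raise ValidationError("AP amplitude must be > 0")
        if not self.upstroke_rate_mv_ms > 20:
            raise ValidationError("upstroke_rate must exceed the 20 mV/ms detection slope")
        if self.adaptation_strength < 0:
            raise ValidationError("adaptation_strength must be >= 0")
        # rise-phase geometry: time from half-amplitude to peak must fit
        # inside the requested half-width, else no fall constant exists
        if self.halfwidth_true_ms <= self._rise_half_to_peak_ms():
            raise ValidationError(
                f"halfwidth_true {self.halfwidth_true_ms} ms infeasible: rise from "
                f"half-amplitude to peak alone takes {self._rise_half_to_peak_ms():.3f} ms; "
                "increase upstroke_rate or halfwidth"
            )

    # rise: u(t) = P (1 − e^{−t/tau_r}), P = 1.5 A, tau_r = P / upstroke
    @property
    def _asymptote_mv(self) -> float:
        return 1.5 * self.amplitude_true_mv

    @property
    def _tau_r_ms(self) -> float:
        return self._asymptote_mv / self.upstroke_rate_mv_ms

    @property
    def rise_time_ms(self) -> float:
        """Threshold-to-peak time of the continuous waveform."""
        return self._tau_r_ms * np.log(3.0)  # u = A at 1 − A/P = 1/3

    def _rise_half_to_peak_ms(self) -> float:
        return self._tau_r_ms * np.log(2.0)  # from u = A/2 to u = A

    @property
    def tau_f_ms(self) -> float:
        """Fall time constant solved so the half-width is exact."""
        a, d = self.amplitude_true_mv, self.ahp_depth_mv
        return (self.halfwidth_true_ms - self._rise_half_to_peak_ms()) / np.log(
            (a + d) / (a / 2.0 + d)
        )

    def overshoot_mv(self) -> float:
        return self.threshold_true_mv + self.amplitude_true_mv


@dataclass(frozen=True)
class CalciumModel:
    """Linear spike-to-fluorescence forward model (GCaMP6s-like defaults)."""

    amp_per_spike: float = 0.15
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.8
    f0_true: float = 100.0
    fb_true: float = 20.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_decay_s > self.tau_rise_s > 0):
            raise ValidationError("need tau_decay > tau_rise > 0")
        if not (self.f0_true > self.fb_true >= 0):
            raise ValidationError("need f0_true > fb_true >= 0")


# ---------------------------------------------------------------------------
# passive sweeps
# ---------------------------------------------------------------------------

def _passive_bracket(model: PassiveModel, t_ms: np.ndarray) -> np.ndarray:
    """Time-resolved effective resistance B(t) in MΩ: ΔV = I·B(t)/1000.

    B(t) = r_ss·(1 − e^{−t/τm}) + r_sag·(e^{−t/τh} − e^{−t/τm}); instantaneous
    component carries r_input = r_ss + r_sag, steady state r_ss.
    """
    gm = 1.0 - np.exp(-t_ms / model.tau_m_ms)
    sag = np.exp(-t_ms / model.tau_h_ms) - np.exp(-t_ms / model.tau_m_ms)
    return model.r_ss_mohm * gm + model.r_sag_mohm * sag


def passive_ground_truth(model: PassiveModel, step_duration_s: float = 1.0,
                         grid_ms: float = 0.01) -> dict:
    """Exact feature values of the closed-form passive response.

    ``rn_max`` is the extremum of the effective-resistance curve on a dense
    time grid; ``rn_ss = r_input − r_sag`` exactly.
    """
    t = np.arange(0.0, step_duration_s * 1e3 + grid_ms, grid_ms)
    rn_max = float(np.max(_passive_bracket(model, t)))
    rn_ss = model.r_ss_mohm
    return {
        "rmp": model.v_rest_mv,
        "rn_ss": rn_ss,
        "rn_max": rn_max,
        "sag_ratio": rn_max / rn_ss,
    }


def _noiseless_passive_trace(model: PassiveModel, step: StepDescriptor,
                             sampling_rate: float, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) / sampling_rate
    v = np.full(n_samples, model.v_rest_mv)
    in_step = (t >= step.onset_s) & (t < step.offset_s)
    t_ms = (t[in_step] - step.onset_s) * 1e3
    v[in_step] += step.amplitude_pa * _passive_bracket(model, t_ms) / 1000.0
    after = t >= step.offset_s
    if np.any(after):
        v_off = (
            model.v_rest_mv
            + step.amplitude_pa
            * _passive_bracket(model, np.array([step.duration_s * 1e3]))[0]
            / 1000.0
        )
        v[after] = model.v_rest_mv + (v_off - model.v_rest_mv) * np.exp(
            -(t[after] - step.offset_s) * 1e3 / model.tau_m_ms
        )
    return v


def simulate_passive_sweep(model: PassiveModel, step: StepDescriptor,
                           sampling_rate: float = DEFAULT_SWEEP_RATE_HZ,
                           seed: int | np.random.Generator = 0,
                           tail_s: float = DEFAULT_TAIL_S,
                           sweep_id: str = "sweep") -> tuple[Sweep, dict]:
    """Simulate one subthreshold sweep; return it with exact ground truth."""
    if not sampling_rate > 0:
        raise ValidationError("sampling_rate must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round((step.offset_s + tail_s) * sampling_rate))
    v = _noiseless_passive_trace(model, step, sampling_rate, n)
    if model.noise_sd_mv > 0:
        v = v + rng.normal(0.0, model.noise_sd_mv, size=n)
    sweep = Sweep(voltage_mv=v, sampling_rate_hz=sampling_rate, step=step, sweep_id=sweep_id)
    return sweep, passive_ground_truth(model, step.duration_s)


# ---------------------------------------------------------------------------
# AP template
# ---------------------------------------------------------------------------

def build_ap_template(spikes: SpikeModel, dt_ms: float) -> np.ndarray:
    """Sampled AP waveform relative to threshold (u[0] = 0 at threshold).

    Rise: saturating exponential, initial slope = upstroke_rate, truncated at
    the peak (u = amplitude).  Fall: exponential decay toward −ahp_depth,
    truncated at 90 % of the afterhyperpolarization depth.  The continuous
    waveform's width at half threshold-to-peak amplitude equals
    ``halfwidth_true`` exactly.
    """
    a = spikes.amplitude_true_mv
    p = spikes._asymptote_mv
    tau_r = spikes._tau_r_ms
    tau_f = spikes.tau_f_ms
    d = spikes.ahp_depth_mv
    t_rise = spikes.rise_time_ms
    t_fall = tau_f * np.log((a + d) / (0.1 * d))  # stop at u = −0.9 d
    total_ms = t_rise + t_fall
    if total_ms < spikes.refractory_ms:
        raise ValidationError(
            f"constructed AP waveform ({total_ms:.2f} ms) shorter than the "
            f"refractory period ({spikes.refractory_ms} ms): inconsistent model"
        )
    t = np.arange(0.0, total_ms, dt_ms)
    u = np.where(
        t <= t_rise,
        p * (1.0 - np.exp(-t / tau_r)),
        (a + d) * np.exp(-(t - t_rise) / tau_f) - d,
    )
    return u


# ---------------------------------------------------------------------------
# spiking sweeps (adaptive integrate-and-fire)
# ---------------------------------------------------------------------------

def _aif_segment(v0: float, w0: float, v_inf: float, r_ss: float,
                 tau_m_ms: float, tau_w_ms: float, t_ms: np.ndarray) -> np.ndarray:
    """Exact membrane solution from (v0, w0) under constant drive.

    dv/dt = (v_inf − r_ss·w(t)/1000 − v)/τm with w(t) = w0·e^{−t/τw}.
    """
    k = tau_w_ms / (tau_w_ms - tau_m_ms)
    em = np.exp(-t_ms / tau_m_ms)
    ew = np.exp(-t_ms / tau_w_ms)
    return v_inf + (v0 - v_inf) * em - (r_ss / 1000.0) * w0 * k * (ew - em)


def simulate_spiking_sweep(passive: PassiveModel, spikes: SpikeModel,
                           step: StepDescriptor,
                           sampling_rate: float = DEFAULT_SWEEP_RATE_HZ,
                           seed: int | np.random.Generator = 0,
                           tail_s: float = DEFAULT_TAIL_S,
                           sweep_id: str = "sweep") -> tuple[Sweep, list[dict]]:
    """Simulate a suprathreshold sweep; return it with its spike event log.

    The event log lists, per spike, the grid-aligned spike time and the true
    waveform parameters (threshold, amplitude, half-width); detection-side
    recovery is checked against it.
    """
    if not sampling_rate > 0:
        raise ValidationError("sampling_rate must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt_ms = 1e3 / sampling_rate
    n = int(round((step.offset_s + tail_s) * sampling_rate))
    v = np.full(n, passive.v_rest_mv)

    template = build_ap_template(spikes, dt_ms)
    n_tmpl = template.size
    v_reset = spikes.threshold_true_mv + template[-1]

    i_on = int(round(step.onset_s * sampling_rate))
    i_off = min(int(round(step.offset_s * sampling_rate)), n)
    v_inf = passive.v_rest_mv + step.amplitude_pa * passive.r_ss_mohm / 1000.0
    refractory_samples = max(1, int(round(spikes.refractory_ms / dt_ms)))

    event_log: list[dict] = []
    cursor = i_on
    v0, w0 = passive.v_rest_mv, 0.0
    b = spikes.adaptation_strength * spikes.adapt_increment_pa
    while cursor < i_off:
        t_rel = (np.arange(cursor, i_off) - cursor) * dt_ms
        seg = _aif_segment(v0, w0, v_inf, passive.r_ss_mohm,
                           passive.tau_m_ms, spikes.tau_w_ms, t_rel)
        crossed = seg >= spikes.threshold_true_mv
        if not np.any(crossed):
            v[cursor:i_off] = seg
            v0 = seg[-1]
            w0 = w0 * np.exp(-t_rel[-1] / spikes.tau_w_ms)
            cursor = i_off
            break
        hit = int(np.argmax(crossed))
        spike_idx = cursor + hit
        if event_log and (spike_idx - event_log[-1]["index"]) < refractory_samples:
            raise ValidationError("refractory violation in constructed spike train")
        v[cursor:spike_idx] = seg[:hit]
        end = min(spike_idx + n_tmpl, n)
        v[spike_idx:end] = spikes.threshold_true_mv + template[: end - spike_idx]
        event_log.append(
            {
                "index": spike_idx,
                "time_s": spike_idx / sampling_rate,
                "threshold_v_mv": spikes.threshold_true_mv,
                "amplitude_mv": spikes.amplitude_true_mv,
                "halfwidth_ms": spikes.halfwidth_true_ms,
            }
        )
        w_at_spike = w0 * np.exp(-hit * dt_ms / spikes.tau_w_ms) + b
        w0 = w_at_spike * np.exp(-n_tmpl * dt_ms / spikes.tau_w_ms)
        v0 = v_reset
        cursor = spike_idx + n_tmpl

    # post-step relaxation back to rest from wherever the step left off
    if i_off < n:
        start = max(i_off, cursor if cursor > i_off else i_off)
        start = min(start, n)
        v_off = v[start - 1] if start > 0 else passive.v_rest_mv
        t_rel = (np.arange(start, n) - (start - 1)) * dt_ms
        v[start:] = passive.v_rest_mv + (v_off - passive.v_rest_mv) * np.exp(
            -t_rel / passive.tau_m_ms
        )

    if passive.noise_sd_mv > 0:
        v = v + rng.normal(0.0, passive.noise_sd_mv, size=n)
    sweep = Sweep(voltage_mv=v, sampling_rate_hz=sampling_rate, step=step, sweep_id=sweep_id)
    return sweep, event_log


def _noiseless_spike_count(passive: PassiveModel, spikes: SpikeModel,
                           step: StepDescriptor, sampling_rate: float) -> int:
    quiet = PassiveModel(
        v_rest_mv=passive.v_rest_mv, r_input_mohm=passive.r_input_mohm,
        r_sag_mohm=passive.r_sag_mohm, tau_m_ms=passive.tau_m_ms,
        tau_h_ms=passive.tau_h_ms, noise_sd_mv=0.0,
    )
    _, log = simulate_spiking_sweep(quiet, spikes, step, sampling_rate, seed=0)
    return len(log)


def model_rheobase(passive: PassiveModel, spikes: SpikeModel,
                   protocol: Sequence[StepDescriptor],
                   sampling_rate: float = DEFAULT_SWEEP_RATE_HZ) -> float | None:
    """Smallest protocol amplitude eliciting ≥1 spike in the noiseless model."""
    for step in sorted(protocol, key=lambda s: s.amplitude_pa):
        if _noiseless_spike_count(passive, spikes, step, sampling_rate) >= 1:
            return step.amplitude_pa
    return None


def simulate_neuron(passive: PassiveModel, spikes: SpikeModel,
                    protocol: Sequence[StepDescriptor] | None = None,
                    sampling_rate: float = DEFAULT_SWEEP_RATE_HZ,
                    seed: int = 0,
                    neuron_id: str = "sim",
                    hours_post_slicing: float | None = None,
                    condition: dict | None = None,
                    cell_class: str = "unknown") -> tuple[NeuronRecording, dict]:
    """Run the full step protocol on one model neuron.

    Returns the recording and a ground-truth row containing the passive
    truths, the model rheobase (noiseless scan over protocol amplitudes) and
    the per-sweep spike event logs (``event_logs`` keyed by sweep_id).
    Deterministic given the seed.
    """
    if protocol is None:
        protocol = default_protocol()
    protocol = sorted(protocol, key=lambda s: s.amplitude_pa)
    rng = np.random.default_rng(seed)
    sweeps: list[Sweep] = []
    event_logs: dict[str, list[dict]] = {}
    rheo: float | None = None
    for k, step in enumerate(protocol):
        sid = f"{neuron_id}_s{k:02d}"
        n_spk = _noiseless_spike_count(passive, spikes, step, sampling_rate)
        if n_spk == 0:
            sweep, _ = simulate_passive_sweep(passive, step, sampling_rate, rng, sweep_id=sid)
            event_logs[sid] = []
        else:
            sweep, log = simulate_spiking_sweep(passive, spikes, step, sampling_rate,
                                                rng, sweep_id=sid)
            event_logs[sid] = log
            if rheo is None:
                rheo = step.amplitude_pa
        sweeps.append(sweep)
    truth = passive_ground_truth(passive, protocol[0].duration_s)
    truth.update(
        {
            "rheobase": rheo,
            "ap_threshold": spikes.threshold_true_mv,
            "ap_amplitude": spikes.amplitude_true_mv,
            "ap_halfwidth": spikes.halfwidth_true_ms,
            "event_logs": event_logs,
        }
    )
    rec = NeuronRecording(
        neuron_id=neuron_id, sweeps=sweeps,
        hours_post_slicing=hours_post_slicing,
        condition=condition or {}, cell_class=cell_class,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distributional recipe for a simulated cohort.

    ``features`` maps a model parameter to (mean, sd); ``effects`` maps a
    parameter to a linear drift per hour post-slicing, applied on top of the
    mean: value = mean + slope·hours + N(0, sd).  Hours are uniform over
    ``hours_range`` (the cohort design spans roughly 1–75 h post slicing).
    """

    n_neurons: int = 100
    hours_range: tuple[float, float] = (1.0, 75.0)
    features: dict = field(default_factory=lambda: {
        "v_rest_mv": (-69.0, 2.0),
        "r_input_mohm": (150.0, 20.0),
        "r_sag_mohm": (30.0, 8.0),
        "threshold_true_mv": (-40.0, 2.0),
        "amplitude_true_mv": (80.0, 5.0),
        "halfwidth_true_ms": (1.0, 0.1),
    })
    effects: dict = field(default_factory=dict)
    noise_sd_mv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValidationError("cohort needs n_neurons >= 1")
        for name, (mu, sd) in self.features.items():
            if sd < 0:
                raise ValidationError(f"feature {name}: sd must be >= 0")


_PARAM_BOUNDS = {
    "r_input_mohm": (40.0, None),
    "r_sag_mohm": (0.0, None),
    "amplitude_true_mv": (40.0, None),
    "halfwidth_true_ms": (0.6, 3.0),
}


def draw_cohort_parameters(spec: CohortSpec,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-neuron ground-truth parameter draws (the cohort's generative layer).

    Returns one row per neuron with hours_post_slicing and every model
    parameter after covariate effects; clipped to physical bounds.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo, hi = spec.hours_range
    hours = rng.uniform(lo, hi, size=spec.n_neurons)
    out = {"neuron_id": [f"n{i:04d}" for i in range(spec.n_neurons)],
           "hours_post_slicing": hours}
    for name, (mu, sd) in spec.features.items():
        slope = spec.effects.get(name, 0.0)
        vals = mu + slope * hours + rng.normal(0.0, sd, size=spec.n_neurons)
        bounds = _PARAM_BOUNDS.get(name)
        if bounds:
            vals = np.clip(vals, bounds[0], bounds[1])
        out[name] = vals
    df = pd.DataFrame(out)
    # keep r_sag strictly below r_input
    if "r_input_mohm" in df and "r_sag_mohm" in df:
        df["r_sag_mohm"] = np.minimum(df["r_sag_mohm"], 0.8 * df["r_input_mohm"])
    return df


def simulate_cohort(spec: CohortSpec,
                    protocol: Sequence[StepDescriptor] | None = None,
                    sampling_rate: float = DEFAULT_SWEEP_RATE_HZ,
                    spike_defaults: SpikeModel | None = None
                    ) -> tuple[list[NeuronRecording], pd.DataFrame]:
    """Simulate a full cohort; returns recordings plus the ground-truth table.

    The ground-truth table carries, per neuron, the drawn model parameters
    and the exact derived features (rn_ss, rn_max, sag_ratio).  Reproducible
    from ``spec.seed``.
    """
    params = draw_cohort_parameters(spec)
    base_spikes = spike_defaults or SpikeModel()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    recordings = []
    truths = []
    for i, row in params.iterrows():
        passive = PassiveModel(
            v_rest_mv=row["v_rest_mv"],
            r_input_mohm=row["r_input_mohm"],
            r_sag_mohm=row.get("r_sag_mohm", 0.0),
            noise_sd_mv=spec.noise_sd_mv,
        )
        spikes = SpikeModel(
            threshold_true_mv=row.get("threshold_true_mv", base_spikes.threshold_true_mv),
            amplitude_true_mv=row.get("amplitude_true_mv", base_spikes.amplitude_true_mv),
            halfwidth_true_ms=row.get("halfwidth_true_ms", base_spikes.halfwidth_true_ms),
            upstroke_rate_mv_ms=base_spikes.upstroke_rate_mv_ms,
            adaptation_strength=base_spikes.adaptation_strength,
        )
        rec, truth = simulate_neuron(
            passive, spikes, protocol, sampling_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            neuron_id=row["neuron_id"],
            hours_post_slicing=float(row["hours_post_slicing"]),
        )
        recordings.append(rec)
        truths.append(
            {
                "neuron_id": row["neuron_id"],
                "hours_post_slicing": row["hours_post_slicing"],
                "rmp_mV": truth["rmp"],
                "rn_ss_MOhm": truth["rn_ss"],
                "rn_max_MOhm": truth["rn_max"],
                "sag_ratio": truth["sag_ratio"],
                "rheobase_pA": truth["rheobase"],
                "ap_threshold_mV": truth["ap_threshold"],
                "ap_amplitude_mV": truth["ap_amplitude"],
                "ap_halfwidth_ms": truth["ap_halfwidth"],
            }
        )
    return recordings, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def calcium_kernel(t_s: np.ndarray, model: CalciumModel) -> np.ndarray:
    """Unit-spike ΔF/F kernel: (1 − e^{−t/τ_rise})·e^{−t/τ_decay} for t ≥ 0."""
    t = np.asarray(t_s, dtype=float)
    k = (1.0 - np.exp(-t / model.tau_rise_s)) * np.exp(-t / model.tau_decay_s)
    return np.where(t >= 0, k, 0.0)


def true_dff(spike_times_s: Sequence[float], model: CalciumModel,
             t_s: np.ndarray) -> np.ndarray:
    """Noiseless ΔF/F(t) by linear summation of per-spike transients."""
    dff = np.zeros_like(np.asarray(t_s, dtype=float))
    for ts in spike_times_s:
        dff += model.amp_per_spike * calcium_kernel(t_s - ts, model)
    return dff


def simulate_fluorescence(spike_times_s: Sequence[float], model: CalciumModel,
                          duration_s: float,
                          sampling_rate: float = DEFAULT_FRAME_RATE_HZ,
                          seed: int | np.random.Generator = 0,
                          roi_id: str = "roi",
                          stim_onsets_s: Sequence[float] = ()
                          ) -> tuple[FluorescenceTrace, np.ndarray]:
    """Simulate an ROI fluorescence trace driven by known spike times.

    F(t) = FB + (F0 − FB)·(1 + ΔF/F_true(t)) + noise; the noiseless
    ground-truth ΔF/F series is returned alongside.
    """
    if not duration_s > 0:
        raise ValidationError("duration must be > 0")
    spike_times_s = list(spike_times_s)
    if any(ts < 0 or ts > duration_s for ts in spike_times_s):
        raise ValidationError("spike_times must lie within the trace duration")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    dff = true_dff(spike_times_s, model, t)
    f = model.fb_true + (model.f0_true - model.fb_true) * (1.0 + dff)
    if model.noise_sd > 0:
        f = f + rng.normal(0.0, model.noise_sd, size=n)
    trace = FluorescenceTrace(
        f=f, sampling_rate_hz=sampling_rate, roi_id=roi_id,
        stim_onsets_s=stim_onsets_s, background_f=model.fb_true,
    )
    return trace, dff


def peak_dff_per_spike(model: CalciumModel, grid_s: float = 1e-4) -> float:
    """Dense-grid maximum of the single-spike transient (oracle helper)."""
    t = np.arange(0.0, 10.0 * model.tau_decay_s, grid_s)
    return float(model.amp_per_spike * np.max(calcium_kernel(t, model)))


def bout_spike_times(onset_s: float, freq_hz: float, duration_s: float = 1.0) -> list[float]:
    """Evenly spaced spike times of a stimulation bout at the given rate."""
    n = int(round(freq_hz * duration_s))
    if n <= 0:
        return []
    return [onset_s + k / freq_hz for k in range(n)]
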