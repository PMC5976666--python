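"""Action-potential detection, kinetics and spike-train statistics.

AP threshold is the voltage at the first sample where the first derivative of
the voltage (central differences on the raw trace, no smoothing) exceeds
20 mV/ms.  Amplitude is threshold-to-peak; half-width is the width at half
maximal amplitude with linear-interpolated level crossings.  Train statistics
follow the standard accommodation (last/first ISI) and CV (sample sd / mean
of all ISIs) definitions.
"""

from __future__ import annotations

import numpy as np

from .models import APEvent, NeuronRecording, Sweep, ValidationError

#: Default AP-threshold criterion, mV/ms.
DVDT_THRESH_MV_MS = 20.0

#: Minimum separation between accepted threshold crossings, ms.
REFRACTORY_MS = 2.0

#: Minimum threshold-to-peak excursion for a candidate crossing to count as
#: an AP, mV.  Separates genuine spikes from wideband-noise excursions of the
#: derivative; real APs here are 60+ mV.
MIN_HEIGHT_MV = 20.0

#: Single-AP selection window after step onset, s.
SINGLE_AP_WINDOW_S = (0.040, 0.050)

#: Train selection: target spike count 10 ± 3.
TRAIN_TARGET = 10
TRAIN_TOLERANCE = 3


def detect_aps(sweep: Sweep, dvdt_thresh: float = DVDT_THRESH_MV_MS,
               refractory_ms: float = REFRACTORY_MS,
               min_height_mv: float = MIN_HEIGHT_MV) -> list[APEvent]:
    """Detect action potentials in one sweep.

    A candidate event begins at the first sample of each upward dV/dt
    excursion past ``dvdt_thresh``; its peak is the voltage maximum up to the
    point where dV/dt first returns to ≤ 0.  Candidates are accepted when
    the threshold-to-peak excursion reaches ``min_height_mv``; accepted
    events are separated by the refractory gate and a new event cannot begin
    until the voltage has repolarized below the previous event's threshold.
    Returns an empty list when nothing crosses.
    """
    v = sweep.voltage_mv
    dt_ms = 1e3 / sweep.sampling_rate_hz
    dvdt = np.gradient(v, dt_ms)
    above = dvdt >= dvdt_thresh
    # upward crossings: first sample of each suprathreshold excursion
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if crossings.size == 0:
        return []

    refractory_n = max(1, int(round(refractory_ms / dt_ms)))
    events: list[APEvent] = []
    last_thr_idx = -10 * refractory_n
    repolarized_at = 0
    for i in crossings:
        if i < repolarized_at or (i - last_thr_idx) < refractory_n:
            continue
        # peak: local max before dV/dt returns below zero
        rest = np.flatnonzero(dvdt[i + 1:] <= 0)
        j = (i + 1 + rest[0]) if rest.size else (v.size - 1)
        peak_rel = int(np.argmax(v[i:j + 1]))
        peak_idx = i + peak_rel
        if v[peak_idx] - v[i] < min_height_mv:
            continue
        halfwidth = _halfwidth_ms(v, dt_ms, i, peak_idx)
        events.append(
            APEvent(
                threshold_time_s=i / sweep.sampling_rate_hz,
                threshold_v_mv=float(v[i]),
                peak_time_s=peak_idx / sweep.sampling_rate_hz,
                peak_v_mv=float(v[peak_idx]),
                amplitude_mv=float(v[peak_idx] - v[i]),
                halfwidth_ms=halfwidth,
            )
        )
        last_thr_idx = i
        # next event only after repolarization past this threshold voltage
        below = np.flatnonzero(v[peak_idx:] < v[i])
        repolarized_at = (peak_idx + below[0]) if below.size else v.size
    return events


def _halfwidth_ms(v: np.ndarray, dt_ms: float, thr_idx: int,
                  peak_idx: int) -> float | None:
    """Width at half threshold-to-peak amplitude, interpolated; None if truncated."""
    level = v[thr_idx] + 0.5 * (v[peak_idx] - v[thr_idx])
    # upward crossing: last sub-level sample before the peak
    pre = v[thr_idx:peak_idx + 1]
    below = np.flatnonzero(pre < level)
    if below.size == 0:
        up_t = thr_idx * dt_ms
    else:
        k = thr_idx + below[-1]
        frac = (level - v[k]) / (v[k + 1] - v[k])
        up_t = (k + frac) * dt_ms
    # downward crossing: first sub-level sample after the peak
    post = v[peak_idx:]
    under = np.flatnonzero(post < level)
    if under.size == 0:
        return None
    k = peak_idx + under[0] - 1
    frac = (v[k] - level) / (v[k] - v[k + 1])
    down_t = (k + frac) * dt_ms
    width = down_t - up_t
    return float(width) if width > 0 else None


def ap_kinetics(sweep: Sweep, event: APEvent) -> tuple[float, float | None]:
    """(amplitude mV, half-width ms) of a detected event.

    Half-width is None (flagged upstream) when the trace is truncated before
    the downward half-amplitude crossing.
    """
    dt_ms = 1e3 / sweep.sampling_rate_hz
    thr_idx = int(round(event.threshold_time_s * sweep.sampling_rate_hz))
    peak_idx = int(round(event.peak_time_s * sweep.sampling_rate_hz))
    amplitude = float(sweep.voltage_mv[peak_idx] - sweep.voltage_mv[thr_idx])
    return amplitude, _halfwidth_ms(sweep.voltage_mv, dt_ms, thr_idx, peak_idx)


def events_by_sweep(recording: NeuronRecording,
                    dvdt_thresh: float = DVDT_THRESH_MV_MS) -> dict[str, list[APEvent]]:
    """Detect APs on every sweep of a neuron; keyed by sweep_id."""
    return {s.sweep_id: detect_aps(s, dvdt_thresh) for s in recording.sweeps}


def rheobase(recording: NeuronRecording,
             events: dict[str, list[APEvent]] | None = None) -> float | None:
    """Smallest step amplitude whose sweep contains ≥ 1 AP; None if none spike."""
    events = events if events is not None else events_by_sweep(recording)
    for sweep in recording.sweeps:  # already amplitude-ascending
        if events.get(sweep.sweep_id):
            return sweep.step.amplitude_pa
    return None


def select_single_ap(recording: NeuronRecording,
                     events: dict[str, list[APEvent]] | None = None,
                     window_s: tuple[float, float] = SINGLE_AP_WINDOW_S
                     ) -> tuple[Sweep, APEvent, bool] | None:
    """Pick the AP used for kinetics.

    Preferred: among sweeps whose first AP threshold falls 40–50 ms after
    step onset, the one at the lowest step amplitude.  When no sweep
    qualifies, falls back to the first AP of the rheobase sweep and the
    returned flag is True (``kinetics_window_fallback``).  None when the
    neuron never spikes.
    """
    events = events if events is not None else events_by_sweep(recording)
    for sweep in recording.sweeps:
        evs = events.get(sweep.sweep_id)
        if not evs:
            continue
        latency = evs[0].threshold_time_s - sweep.step.onset_s
        if window_s[0] <= latency <= window_s[1]:
            return sweep, evs[0], False
    for sweep in recording.sweeps:
        evs = events.get(sweep.sweep_id)
        if evs:
            return sweep, evs[0], True
    return None


def select_train(recording: NeuronRecording,
                 events: dict[str, list[APEvent]] | None = None,
                 target: int = TRAIN_TARGET, tolerance: int = TRAIN_TOLERANCE
                 ) -> tuple[Sweep, list[APEvent]] | None:
    """Pick the spike train used for ISI statistics.

    Among sweeps with ``target ± tolerance`` APs, the one whose count is
    closest to the target; ties go to the lower step amplitude.  None when no
    sweep qualifies.
    """
    events = events if events is not None else events_by_sweep(recording)
    best: tuple[int, Sweep, list[APEvent]] | None = None
    for sweep in recording.sweeps:
        evs = events.get(sweep.sweep_id, [])
        n = len(evs)
        if abs(n - target) > tolerance:
            continue
        if best is None or abs(n - target) < best[0]:
            best = (abs(n - target), sweep, evs)
    return None if best is None else (best[1], best[2])


def _isis_ms(events: list[APEvent]) -> np.ndarray:
    if len(events) < 3:
        raise ValidationError(f"spike-train statistics need >= 3 APs, got {len(events)}")
    times = np.array([e.threshold_time_s for e in events])
    return np.diff(times) * 1e3


def sfa(events: list[APEvent]) -> float:
    """Spike-frequency accommodation: last inter-spike interval / first."""
    isis = _isis_ms(events)
    return float(isis[-1] / isis[0])


def cv_isi(events: list[APEvent]) -> float:
    """Coefficient of variation of all ISIs: sample sd (n−1) / mean."""
    isis = _isis_ms(events)
    return float(np.std(isis, ddof=1) / np.mean(isis))
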