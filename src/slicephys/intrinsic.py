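"""Subthreshold intrinsic membrane properties.

Resting membrane potential, current–voltage (IV) curves, maximum and
steady-state input resistance, and voltage sag.  All measurements are made
from the resting membrane potential; resistances follow the unit rule
R[MΩ] = 1000 · ΔV[mV] / I[pA].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import baseline_window
from .models import NeuronRecording, Sweep, ValidationError
from . import spikes as _spikes

#: IV points are taken from steps in this range (pA), the subthreshold family.
IV_CURRENT_RANGE_PA = (-150.0, 50.0)

#: Steady-state deflection window: final portion of the step, s.
SS_WINDOW_S = 0.100

#: Moving-average width used when locating the peak deflection, ms.  The
#: steady-state measure is taken on the raw trace.
MAX_SMOOTH_MS = 5.0

#: Linear-portion rule: drop the most hyperpolarized IV point while the
#: steady-state fit has R² below this and more than MIN_IV_POINTS remain.
LINEAR_R2_MIN = 0.98
MIN_IV_POINTS = 3


class SweepHasSpikesError(ValidationError):
    """A sweep offered for subthreshold analysis contains action potentials."""


@dataclass
class IVCurve:
    """IV points (one per subthreshold step) and their two linear fits.

    ``currents_pa``/``max_mv``/``ss_mv`` are the retained (linear-portion)
    points; ``dropped_currents_pa`` lists points removed by the linearity
    rule.  Fits are (slope mV/pA, intercept mV, R²).
    """

    currents_pa: np.ndarray
    max_mv: np.ndarray
    ss_mv: np.ndarray
    fit_max: tuple[float, float, float]
    fit_ss: tuple[float, float, float]
    dropped_currents_pa: tuple[float, ...] = ()


def measure_rmp(sweep: Sweep) -> float:
    """Resting membrane potential: mean voltage over the pre-step baseline."""
    start, end = baseline_window(sweep)
    i0, i1 = sweep.index_at(start), sweep.index_at(end)
    return float(np.mean(sweep.voltage_mv[i0:i1]))


def step_deflections(sweep: Sweep, rmp: float | None = None,
                     smooth_ms: float = MAX_SMOOTH_MS) -> tuple[float, float]:
    """Maximum and steady-state voltage deflections of a subthreshold step.

    The steady-state deflection is the mean of (V − RMP) over the final
    100 ms of the step.  The maximum deflection is the extremum of (V − RMP)
    within the step, taken in the direction of the step's sign; the extremum
    is located on a short moving-average of the trace so that wideband
    measurement noise cannot masquerade as the peak.

    Raises :class:`SweepHasSpikesError` when the sweep contains detected APs
    (such sweeps are excluded from the IV curve, never silently used).
    """
    if _spikes.detect_aps(sweep):
        raise SweepHasSpikesError(
            f"sweep {sweep.sweep_id}: action potentials within step; excluded from IV"
        )
    if rmp is None:
        rmp = measure_rmp(sweep)
    i_on = sweep.index_at(sweep.step.onset_s)
    i_off = sweep.index_at(sweep.step.offset_s)
    seg = sweep.voltage_mv[i_on:i_off] - rmp

    n_ss = max(1, int(round(SS_WINDOW_S * sweep.sampling_rate_hz)))
    ss = float(np.mean(seg[-n_ss:]))

    win = max(1, int(round(smooth_ms * 1e-3 * sweep.sampling_rate_hz)))
    if win > 1 and seg.size >= win:
        kernel = np.full(win, 1.0 / win)
        smooth = np.convolve(seg, kernel, mode="valid")
    else:
        smooth = seg
    if sweep.step.amplitude_pa >= 0:
        mx = float(np.max(smooth))
    else:
        mx = float(np.min(smooth))
    return mx, ss


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def build_iv_curve(recording: NeuronRecording,
                   current_range_pa: tuple[float, float] = IV_CURRENT_RANGE_PA,
                   r2_min: float = LINEAR_R2_MIN) -> IVCurve:
    """Assemble the subthreshold IV curve of a neuron and fit its linear portion.

    Uses all steps within the subthreshold current range that elicit no AP.
    The "linear portion" rule: fit all points; while the steady-state fit has
    R² < ``r2_min`` and more than three points remain, drop the most
    hyperpolarized point.  Both fits (max and steady state) use the same
    final subset.  Duplicate currents are averaged.
    """
    pts: dict[float, list[tuple[float, float]]] = {}
    for sweep in recording.sweeps:
        amp = sweep.step.amplitude_pa
        if not (current_range_pa[0] <= amp <= current_range_pa[1]):
            continue
        try:
            mx, ss = step_deflections(sweep)
        except SweepHasSpikesError:
            continue
        pts.setdefault(amp, []).append((mx, ss))
    if len(pts) < MIN_IV_POINTS:
        raise ValidationError(
            f"neuron {recording.neuron_id}: only {len(pts)} subthreshold IV points, "
            f"need >= {MIN_IV_POINTS}"
        )
    currents = np.array(sorted(pts))
    max_mv = np.array([np.mean([p[0] for p in pts[c]]) for c in currents])
    ss_mv = np.array([np.mean([p[1] for p in pts[c]]) for c in currents])
    return fit_iv_points(currents, max_mv, ss_mv, r2_min=r2_min)


def fit_iv_points(currents_pa, max_mv, ss_mv,
                  r2_min: float = LINEAR_R2_MIN) -> IVCurve:
    """Fit the linear portion of pre-assembled IV points (see build_iv_curve)."""
    currents = np.asarray(currents_pa, dtype=float)
    max_mv = np.asarray(max_mv, dtype=float)
    ss_mv = np.asarray(ss_mv, dtype=float)
    dropped: list[float] = []
    lo = 0
    while True:
        fit_ss = _linfit(currents[lo:], ss_mv[lo:])
        if fit_ss[2] >= r2_min or currents[lo:].size <= MIN_IV_POINTS:
            break
        dropped.append(float(currents[lo]))
        lo += 1
    fit_max = _linfit(currents[lo:], max_mv[lo:])
    return IVCurve(
        currents_pa=currents[lo:], max_mv=max_mv[lo:], ss_mv=ss_mv[lo:],
        fit_max=fit_max, fit_ss=fit_ss, dropped_currents_pa=tuple(dropped),
    )


def input_resistance(curve: IVCurve) -> tuple[float, float]:
    """(R_N max, R_N steady-state) in MΩ from the IV fits (slope × 1000)."""
    if curve.currents_pa.size < MIN_IV_POINTS:
        raise ValidationError(f"need >= {MIN_IV_POINTS} IV points")
    if np.ptp(curve.currents_pa) <= 0:
        raise ValidationError("zero current spread in IV curve")
    return 1000.0 * curve.fit_max[0], 1000.0 * curve.fit_ss[0]


def sag_ratio(rn_max: float, rn_ss: float) -> float:
    """Voltage sag: ratio of maximum to steady-state input resistance (≥ 1)."""
    if not rn_ss > 0:
        raise ValidationError(f"steady-state R_N must be > 0, got {rn_ss}")
    return rn_max / rn_ss
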