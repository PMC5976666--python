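"""Core data model for current-clamp sweeps, fluorescence traces and feature rows.

Units are fixed package-wide: membrane voltage in mV, injected current in pA,
input resistance in MΩ (R[MΩ] = 1000 · ΔV[mV] / I[pA]), AP kinetics in ms,
trace time in s.  All conversions happen at I/O boundaries.

Voltages are stored as recorded.  The liquid junction potential of the
recording solutions (−13 mV, by calculation) is never subtracted; it is kept
as a provenance constant only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Calculated liquid junction potential of the K-gluconate internal against
#: the recording aCSF, in mV.  Recorded voltages are NOT corrected for it.
JUNCTION_POTENTIAL_MV = -13.0

#: Minimum pre-step baseline a sweep must carry, in seconds.
MIN_BASELINE_S = 0.050

CONDITION_AXES = {
    "prep": ("acute", "culture"),
    "infection": ("infected", "uninfected"),
    "case": ("tumor", "epilepsy"),
}

CELL_CLASSES = ("pyramidal", "interneuron", "unknown")


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass(frozen=True)
class StepDescriptor:
    """One square current-injection step.

    amplitude_pa : signed step amplitude in pA (negative = hyperpolarizing)
    onset_s      : step onset, seconds from sweep start
    duration_s   : step duration in seconds (protocol standard: 1 s)
    """

    amplitude_pa: float
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError(f"step duration must be > 0, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValidationError(f"step onset must be >= 0, got {self.onset_s}")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Sweep:
    """A single current-clamp trial: V(t) plus its current-step descriptor."""

    voltage_mv: np.ndarray
    sampling_rate_hz: float
    step: StepDescriptor
    sweep_id: str

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.voltage_mv.ndim != 1 or self.voltage_mv.size < 2:
            raise ValidationError(f"sweep {self.sweep_id}: voltage must be a 1-D series")
        if not self.sampling_rate_hz > 0:
            raise ValidationError(f"sweep {self.sweep_id}: sampling_rate must be > 0")
        if not np.all(np.isfinite(self.voltage_mv)):
            raise ValidationError(f"sweep {self.sweep_id}: non-finite voltage sample")
        if self.step.onset_s < MIN_BASELINE_S:
            raise ValidationError(
                f"sweep {self.sweep_id}: needs >= {MIN_BASELINE_S*1e3:.0f} ms of "
                f"pre-step baseline, step onset at {self.step.onset_s} s"
            )
        if self.step.offset_s > self.duration_s + 1e-9:
            raise ValidationError(
                f"sweep {self.sweep_id}: step extends past end of sweep "
                f"({self.step.offset_s:.4f} s > {self.duration_s:.4f} s)"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return int(self.voltage_mv.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def index_at(self, t: float) -> int:
        """Sample index of time t (rounded to nearest grid point, clipped)."""
        return int(np.clip(round(t * self.sampling_rate_hz), 0, self.n_samples - 1))


def _validate_condition(condition: dict) -> dict:
    out = {}
    for key, value in (condition or {}).items():
        if key not in CONDITION_AXES:
            raise ValidationError(f"unknown condition axis {key!r}")
        if value not in CONDITION_AXES[key]:
            raise ValidationError(f"condition {key}={value!r} not in {CONDITION_AXES[key]}")
        out[key] = value
    return out


@dataclass
class NeuronRecording:
    """All sweeps of one neuron plus cohort metadata.

    Sweeps are kept sorted by step amplitude ascending (ties broken by
    sweep_id) and must share a sampling rate.
    """

    neuron_id: str
    sweeps: list[Sweep]
    hours_post_slicing: float | None = None
    condition: dict = field(default_factory=dict)
    cell_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValidationError(f"neuron {self.neuron_id}: no sweeps")
        ids = [s.sweep_id for s in self.sweeps]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"neuron {self.neuron_id}: duplicate sweep_ids")
        rates = {s.sampling_rate_hz for s in self.sweeps}
        if len(rates) != 1:
            raise ValidationError(
                f"neuron {self.neuron_id}: inconsistent sampling rates {sorted(rates)}"
            )
        if self.hours_post_slicing is not None and self.hours_post_slicing < 0:
            raise ValidationError(f"neuron {self.neuron_id}: hours_post_slicing < 0")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"neuron {self.neuron_id}: cell_class {self.cell_class!r} "
                f"not in {CELL_CLASSES}"
            )
        self.condition = _validate_condition(self.condition)
        self.sweeps = sorted(self.sweeps, key=lambda s: (s.step.amplitude_pa, s.sweep_id))

    @property
    def sampling_rate_hz(self) -> float:
        return self.sweeps[0].sampling_rate_hz


@dataclass
class FluorescenceTrace:
    """Raw fluorescence F(t) of one ROI, with stimulus timing and background.

    background_f is the scalar F_B measured from a region with minimal signal
    (background-ROI selection itself is outside this package: backgrounds are
    inputs).
    """

    f: np.ndarray
    sampling_rate_hz: float
    roi_id: str
    stim_onsets_s: Sequence[float] = ()
    background_f: float = 0.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size < 2:
            raise ValidationError(f"roi {self.roi_id}: f must be a 1-D series")
        if not self.sampling_rate_hz > 0:
            raise ValidationError(f"roi {self.roi_id}: sampling_rate must be > 0")
        if not np.all(np.isfinite(self.f)):
            raise ValidationError(f"roi {self.roi_id}: non-finite fluorescence sample")
        onsets = np.asarray(list(self.stim_onsets_s), dtype=float)
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValidationError(f"roi {self.roi_id}: stim_onsets not strictly increasing")
            if onsets[0] < 0 or onsets[-1] > self.duration_s:
                raise ValidationError(f"roi {self.roi_id}: stim_onsets outside trace")
        self.stim_onsets_s = tuple(onsets.tolist())

    @property
    def duration_s(self) -> float:
        return self.f.size / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.f.size) / self.sampling_rate_hz


@dataclass(frozen=True)
class APEvent:
    """One detected action potential.

    Amplitude is threshold-to-peak; half-width is the width at half-maximal
    amplitude (linear-interpolated level crossings).  half-width is None when
    the trace is truncated before the downward crossing (flagged upstream).
    """

    threshold_time_s: float
    threshold_v_mv: float
    peak_time_s: float
    peak_v_mv: float
    amplitude_mv: float
    halfwidth_ms: float | None

    def __post_init__(self) -> None:
        if not self.peak_time_s > self.threshold_time_s:
            raise ValidationError("AP peak must follow its threshold crossing")
        if not self.amplitude_mv > 0:
            raise ValidationError("AP amplitude must be > 0")
        if self.halfwidth_ms is not None and not self.halfwidth_ms > 0:
            raise ValidationError("AP half-width must be > 0 when present")


@dataclass
class FeatureRow:
    """Per-neuron feature vector, one row of the cohort feature table.

    Absent features (no qualifying sweep/train) are None and serialize to the
    "NA" sentinel.  `max_ap_peak_mv` is the most depolarized AP peak across
    all sweeps, the quantity the overshoot inclusion criterion tests.
    """

    neuron_id: str
    rmp_mv: float | None = None
    rn_max_mohm: float | None = None
    rn_ss_mohm: float | None = None
    sag_ratio: float | None = None
    rheobase_pa: float | None = None
    ap_threshold_mv: float | None = None
    ap_amplitude_mv: float | None = None
    ap_halfwidth_ms: float | None = None
    sfa: float | None = None
    cv_isi: float | None = None
    max_ap_peak_mv: float | None = None
    qc_pass: bool | None = None
    hours_post_slicing: float | None = None
    condition: dict = field(default_factory=dict)
    cell_class: str = "unknown"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.condition = _validate_condition(self.condition)
        if self.sag_ratio is not None and self.rn_max_mohm is not None \
                and self.rn_ss_mohm is not None and self.sag_ratio < 1.0 - 1e-9:
            raise ValidationError(
                f"neuron {self.neuron_id}: sag_ratio {self.sag_ratio} < 1 with "
                "both R_N values defined"
            )
        if self.ap_halfwidth_ms is not None and not self.ap_halfwidth_ms > 0:
            raise ValidationError(f"neuron {self.neuron_id}: ap_halfwidth must be > 0")
        if self.ap_amplitude_mv is not None and not self.ap_amplitude_mv > 0:
            raise ValidationError(f"neuron {self.neuron_id}: ap_amplitude must be > 0")


#: Canonical feature-table column order (units encoded in column names).
FEATURE_COLUMNS = (
    "neuron_id",
    "rmp_mV",
    "rn_max_MOhm",
    "rn_ss_MOhm",
    "sag_ratio",
    "rheobase_pA",
    "ap_threshold_mV",
    "ap_amplitude_mV",
    "ap_halfwidth_ms",
    "sfa",
    "cv_isi",
    "max_ap_peak_mV",
    "qc_pass",
    "hours_post_slicing",
    "prep",
    "infection",
    "case",
    "cell_class",
    "flags",
)


@dataclass
class DffTrace:
    """Normalized calcium signal ΔF/F(t) = (F(t) − F0)/(F0 − FB) of one ROI."""

    dff: np.ndarray
    roi_id: str
    f0: float
    fb: float
    f0_window_s: tuple[float, float]
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if not self.f0 > self.fb:
            raise ValidationError(
                f"roi {self.roi_id}: F0 ({self.f0}) must exceed background FB ({self.fb})"
            )
        if not np.all(np.isfinite(self.dff)):
            raise ValidationError(f"roi {self.roi_id}: non-finite dF/F sample")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.dff.size) / self.sampling_rate_hz
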