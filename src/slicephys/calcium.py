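"""ΔF/F computation and calcium-transient quantification.

ΔF/F(t) = (F(t) − F0)/(F0 − FB), with F0 the mean fluorescence over the
200 ms window ending at stimulus onset (or the first 200 ms of the trace when
no stimulus is given) and FB a per-trace scalar background measured from a
region with minimal signal.
"""

from __future__ import annotations

import numpy as np

from .models import DffTrace, FluorescenceTrace, ValidationError

#: Baseline (F0) window length, s: the "~200 ms before stimulation" realized
#: as exactly 200 ms for determinism.
F0_WINDOW_S = 0.200

#: Stimulation-bout length used in the stimulus–response protocol, s.
BOUT_DURATION_S = 1.0

#: Post-bout window over which the peak response is sought, s (≈3 GCaMP6s
#: decay constants past bout end).
POST_BOUT_WINDOW_S = 2.4


def compute_dff(trace: FluorescenceTrace, stim_onset_s: float | None = None,
                f0_window_s: float = F0_WINDOW_S) -> DffTrace:
    """Normalize a raw fluorescence trace to ΔF/F.

    With a stimulus onset, F0 is the mean F over the ``f0_window_s`` ending
    at that onset (≥ that much pre-stimulus data is required); otherwise the
    first ``f0_window_s`` of the trace is used.  Raises when F0 ≤ FB (a
    non-physical normalization).
    """
    rate = trace.sampling_rate_hz
    n_win = max(1, int(round(f0_window_s * rate)))
    if stim_onset_s is None:
        i0, i1 = 0, min(n_win, trace.f.size)
        window = (0.0, i1 / rate)
    else:
        i1 = int(round(stim_onset_s * rate))
        i0 = i1 - n_win
        if i0 < 0:
            raise ValidationError(
                f"roi {trace.roi_id}: needs >= {f0_window_s*1e3:.0f} ms of "
                f"pre-stimulus frames before onset at {stim_onset_s} s"
            )
        window = (i0 / rate, stim_onset_s)
    f0 = float(np.mean(trace.f[i0:i1]))
    fb = float(trace.background_f)
    if not f0 > fb:
        raise ValidationError(
            f"roi {trace.roi_id}: baseline F0 ({f0:.3g}) must exceed background "
            f"FB ({fb:.3g})"
        )
    dff = (trace.f - f0) / (f0 - fb)
    return DffTrace(dff=dff, roi_id=trace.roi_id, f0=f0, fb=fb,
                    f0_window_s=window, sampling_rate_hz=rate)


def stim_response_curve(trace: FluorescenceTrace,
                        bouts: list[tuple[float, float]],
                        bout_duration_s: float = BOUT_DURATION_S,
                        post_window_s: float = POST_BOUT_WINDOW_S
                        ) -> list[tuple[float, float]]:
    """Peak ΔF/F per stimulation bout, as (frequency Hz, peak ΔF/F) pairs.

    ``bouts`` are (onset s, frequency Hz) pairs driving firing over
    ``bout_duration_s``; they must not overlap.  The baseline is recomputed
    per bout (F0 window ending at that bout's onset) and the peak is taken
    from bout onset through ``post_window_s`` past bout end, covering the
    slow indicator decay.
    """
    bouts = sorted(bouts)
    for (o1, _), (o2, _) in zip(bouts, bouts[1:]):
        if o2 < o1 + bout_duration_s:
            raise ValidationError(f"bouts at {o1} s and {o2} s overlap")
    rate = trace.sampling_rate_hz
    out = []
    for onset, freq in bouts:
        dff = compute_dff(trace, stim_onset_s=onset)
        i0 = int(round(onset * rate))
        i1 = min(int(round((onset + bout_duration_s + post_window_s) * rate)),
                 dff.dff.size)
        out.append((freq, float(np.max(dff.dff[i0:i1]))))
    return out


def detect_transients(dff: DffTrace, k: float = 3.0, min_dur_s: float = 0.2,
                      merge_gap_s: float = 0.1
                      ) -> list[tuple[float, float, float]]:
    """Threshold-crossing transient detection on a ΔF/F trace.

    Events are runs where ΔF/F exceeds ``k`` × a robust noise estimate
    (1.4826·MAD about the median) for at least ``min_dur_s``; runs separated
    by gaps shorter than ``merge_gap_s`` are merged.  Returns
    (onset s, peak time s, peak ΔF/F) per event.  These parameters go beyond
    the source analysis and are configurable.
    """
    x = dff.dff
    rate = dff.sampling_rate_hz
    med = np.median(x)
    noise = 1.4826 * np.median(np.abs(x - med))
    mask = x > med + k * noise
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = [(int(seg[0]), int(seg[-1])) for seg in np.split(idx, splits + 1)]
    # merge runs separated by < merge_gap_s
    merged = [runs[0]]
    gap_n = merge_gap_s * rate
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap_n:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_n = min_dur_s * rate
    events = []
    for s, e in merged:
        if (e - s + 1) < min_n:
            continue
        peak_rel = int(np.argmax(x[s:e + 1]))
        events.append((s / rate, (s + peak_rel) / rate, float(x[s + peak_rel])))
    return events
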