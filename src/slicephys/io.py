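"""Dataset and feature-table I/O.

Two on-disk dialects are supported:

* **container** — one HDF5 file, one group per neuron:
  ``/neurons/<id>/voltage`` (sweeps × samples, mV, float64),
  ``/neurons/<id>/steps`` (sweeps × 3: amplitude pA, onset s, duration s),
  group attributes ``sampling_rate_hz``, ``sweep_ids``, ``hours_post_slicing``
  (absent attribute = unknown), ``condition`` (JSON string), ``cell_class``.

* **tabular** — a directory per neuron holding one two-column delimited text
  file per sweep (``time_s<TAB>voltage_mV``) plus a ``metadata.json`` sidecar
  with the step descriptors and neuron metadata.  Intended for small
  plain-text fixtures; round-trips float64 exactly via 17-significant-digit
  formatting.

Feature tables are CSV with a fixed, documented column order
(:data:`slicephys.models.FEATURE_COLUMNS`), units in the header names, and a
single sentinel ``NA`` for absent values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .models import (
    FEATURE_COLUMNS,
    FeatureRow,
    NeuronRecording,
    StepDescriptor,
    Sweep,
    ValidationError,
)

logger = logging.getLogger(__name__)

NA_SENTINEL = "NA"

#: Preferred / minimum pre-step window used for RMP and baseline references, s.
BASELINE_WINDOW_S = 0.100
MIN_BASELINE_WINDOW_S = 0.050


class ParseError(ValueError):
    """A dataset file could not be parsed."""


def baseline_window(sweep: Sweep) -> tuple[float, float]:
    """Pre-step interval used for RMP and all baseline references.

    The window ends at step onset and is 100 ms long when that much pre-step
    data exists; with 50–100 ms available it falls back to the 50 ms minimum;
    with less than 50 ms the sweep is unusable and an error is raised.
    """
    onset = sweep.step.onset_s
    if onset >= BASELINE_WINDOW_S:
        return (onset - BASELINE_WINDOW_S, onset)
    if onset >= MIN_BASELINE_WINDOW_S:
        return (onset - MIN_BASELINE_WINDOW_S, onset)
    raise ValidationError(
        f"sweep {sweep.sweep_id}: only {onset*1e3:.0f} ms of pre-step baseline, "
        f"need >= {MIN_BASELINE_WINDOW_S*1e3:.0f} ms"
    )


# ---------------------------------------------------------------------------
# container (HDF5) dialect
# ---------------------------------------------------------------------------

def _write_neuron_group(group: h5py.Group, rec: NeuronRecording) -> None:
    voltage = np.stack([s.voltage_mv for s in rec.sweeps])
    steps = np.array(
        [[s.step.amplitude_pa, s.step.onset_s, s.step.duration_s] for s in rec.sweeps]
    )
    group.create_dataset("voltage", data=voltage)
    group.create_dataset("steps", data=steps)
    group.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
    group.attrs["sweep_ids"] = [s.sweep_id for s in rec.sweeps]
    if rec.hours_post_slicing is not None:
        group.attrs["hours_post_slicing"] = rec.hours_post_slicing
    group.attrs["condition"] = json.dumps(rec.condition, sort_keys=True)
    group.attrs["cell_class"] = rec.cell_class


def _read_neuron_group(neuron_id: str, group: h5py.Group) -> NeuronRecording:
    try:
        voltage = np.asarray(group["voltage"])
        steps = np.asarray(group["steps"])
        rate = float(group.attrs["sampling_rate_hz"])
        sweep_ids = [
            s.decode() if isinstance(s, bytes) else str(s) for s in group.attrs["sweep_ids"]
        ]
    except KeyError as exc:
        raise ParseError(f"neuron {neuron_id}: missing dataset/attribute {exc}") from exc
    if voltage.shape[0] != steps.shape[0] or voltage.shape[0] != len(sweep_ids):
        raise ParseError(f"neuron {neuron_id}: sweep count mismatch between arrays")
    sweeps = [
        Sweep(
            voltage_mv=voltage[i],
            sampling_rate_hz=rate,
            step=StepDescriptor(*steps[i]),
            sweep_id=sweep_ids[i],
        )
        for i in range(voltage.shape[0])
    ]
    hours = group.attrs.get("hours_post_slicing")
    condition = json.loads(group.attrs.get("condition", "{}"))
    cell_class = group.attrs.get("cell_class", "unknown")
    if isinstance(cell_class, bytes):
        cell_class = cell_class.decode()
    return NeuronRecording(
        neuron_id=neuron_id,
        sweeps=sweeps,
        hours_post_slicing=None if hours is None else float(hours),
        condition=condition,
        cell_class=str(cell_class),
    )


# ---------------------------------------------------------------------------
# tabular (plain-text fixture) dialect
# ---------------------------------------------------------------------------

def _write_neuron_dir(root: Path, rec: NeuronRecording) -> None:
    ndir = root / rec.neuron_id
    ndir.mkdir(parents=True, exist_ok=True)
    meta = {
        "neuron_id": rec.neuron_id,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "hours_post_slicing": rec.hours_post_slicing,
        "condition": rec.condition,
        "cell_class": rec.cell_class,
        "sweeps": [
            {
                "sweep_id": s.sweep_id,
                "amplitude_pa": s.step.amplitude_pa,
                "onset_s": s.step.onset_s,
                "duration_s": s.step.duration_s,
            }
            for s in rec.sweeps
        ],
    }
    (ndir / "metadata.json").write_text(json.dumps(meta, indent=1))
    for s in rec.sweeps:
        lines = ["time_s\tvoltage_mV"]
        t = s.time_s
        v = s.voltage_mv
        lines.extend(f"{t[i]:.17g}\t{v[i]:.17g}" for i in range(s.n_samples))
        (ndir / f"{s.sweep_id}.tsv").write_text("\n".join(lines) + "\n")


def _read_neuron_dir(ndir: Path) -> NeuronRecording:
    meta_path = ndir / "metadata.json"
    if not meta_path.exists():
        raise ParseError(f"{ndir}: missing metadata.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{meta_path}: invalid JSON ({exc})") from exc
    rate = float(meta["sampling_rate_hz"])
    sweeps = []
    for entry in meta["sweeps"]:
        sid = entry["sweep_id"]
        path = ndir / f"{sid}.tsv"
        if not path.exists():
            raise ParseError(f"sweep {sid}: file {path} missing")
        try:
            data = np.loadtxt(path, delimiter="\t", skiprows=1)
        except ValueError as exc:
            raise ParseError(f"sweep {sid}: malformed table in {path} ({exc})") from exc
        if data.ndim != 2 or data.shape[1] != 2:
            raise ParseError(f"sweep {sid}: expected two columns in {path}")
        sweeps.append(
            Sweep(
                voltage_mv=data[:, 1],
                sampling_rate_hz=rate,
                step=StepDescriptor(
                    entry["amplitude_pa"], entry["onset_s"], entry["duration_s"]
                ),
                sweep_id=sid,
            )
        )
    return NeuronRecording(
        neuron_id=meta["neuron_id"],
        sweeps=sweeps,
        hours_post_slicing=meta.get("hours_post_slicing"),
        condition=meta.get("condition") or {},
        cell_class=meta.get("cell_class", "unknown"),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_dataset(recordings: Iterable[NeuronRecording], path: str | Path,
                  format: str = "container") -> None:
    """Write recordings to `path` in the given dialect.

    ``container`` writes a single HDF5 file; ``tabular`` writes a directory
    tree of delimited text files (for plain-text fixtures).
    """
    path = Path(path)
    recordings = list(recordings)
    if format == "container":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as fh:
            neurons = fh.create_group("neurons")
            for rec in recordings:
                _write_neuron_group(neurons.create_group(rec.neuron_id), rec)
    elif format == "tabular":
        path.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            _write_neuron_dir(path, rec)
    else:
        raise ValueError(f"unknown dataset format {format!r}")


def load_dataset(path: str | Path, format: str = "auto") -> list[NeuronRecording]:
    """Load a dataset written by :func:`write_dataset`.

    ``auto`` infers the dialect: an HDF5 file is ``container``, a directory is
    ``tabular``.  Every sweep is validated on load; inconsistent sampling
    rates or non-finite samples raise, naming the offending sweep.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "tabular" if path.is_dir() else "container"
    if format == "container":
        with h5py.File(path, "r") as fh:
            if "neurons" not in fh:
                raise ParseError(f"{path}: no /neurons group")
            recs = [
                _read_neuron_group(nid, fh["neurons"][nid])
                for nid in sorted(fh["neurons"])
            ]
    elif format == "tabular":
        ndirs = sorted(p for p in path.iterdir() if p.is_dir())
        recs = [_read_neuron_dir(d) for d in ndirs]
    else:
        raise ValueError(f"unknown dataset format {format!r}")
    if not recs:
        logger.warning("dataset %s is empty", path)
    return recs


def _row_to_record(row: FeatureRow) -> dict:
    return {
        "neuron_id": row.neuron_id,
        "rmp_mV": row.rmp_mv,
        "rn_max_MOhm": row.rn_max_mohm,
        "rn_ss_MOhm": row.rn_ss_mohm,
        "sag_ratio": row.sag_ratio,
        "rheobase_pA": row.rheobase_pa,
        "ap_threshold_mV": row.ap_threshold_mv,
        "ap_amplitude_mV": row.ap_amplitude_mv,
        "ap_halfwidth_ms": row.ap_halfwidth_ms,
        "sfa": row.sfa,
        "cv_isi": row.cv_isi,
        "max_ap_peak_mV": row.max_ap_peak_mv,
        "qc_pass": row.qc_pass,
        "hours_post_slicing": row.hours_post_slicing,
        "prep": row.condition.get("prep"),
        "infection": row.condition.get("infection"),
        "case": row.condition.get("case"),
        "cell_class": row.cell_class,
        "flags": ";".join(row.flags) if row.flags else "",
    }


def feature_frame(rows: Iterable[FeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame in canonical column order."""
    rows = list(rows)
    if not rows:
        raise ValueError("no feature rows")
    return pd.DataFrame([_row_to_record(r) for r in rows], columns=list(FEATURE_COLUMNS))


def write_feature_table(rows: Iterable[FeatureRow] | pd.DataFrame,
                        path: str | Path) -> None:
    """Write the per-neuron feature table as CSV (UTF-8, '.' decimal, NA sentinel)."""
    df = rows if isinstance(rows, pd.DataFrame) else feature_frame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=NA_SENTINEL, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Load a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, na_values=[NA_SENTINEL], keep_default_na=False)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing feature columns {sorted(missing)}")
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
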