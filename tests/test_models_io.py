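"""Data-model invariants, baseline window, and dataset/feature-table I/O."""

import logging
from types import SimpleNamespace

import numpy as np
import pytest

from slicephys import (
    FeatureRow,
    NeuronRecording,
    StepDescriptor,
    Sweep,
    ValidationError,
    baseline_window,
    load_dataset,
    read_feature_table,
    write_dataset,
    write_feature_table,
)
from slicephys.io import feature_frame

from conftest import flat_sweep, make_sweep


class TestInvariants:
    def test_step_descriptor_rejects_bad_geometry(self):
        with pytest.raises(ValidationError):
            StepDescriptor(100.0, 0.2, 0.0)
        with pytest.raises(ValidationError):
            StepDescriptor(100.0, -0.1, 1.0)

    def test_sweep_rejects_nan_voltage(self):
        v = np.full(70_000, -70.0)
        v[123] = np.nan
        with pytest.raises(ValidationError, match="sw0"):
            make_sweep(v)

    def test_sweep_requires_min_baseline(self):
        with pytest.raises(ValidationError, match="baseline"):
            make_sweep(np.full(60_000, -70.0), onset=0.03)

    def test_sweep_step_must_fit(self):
        with pytest.raises(ValidationError):
            make_sweep(np.full(10_000, -70.0), onset=0.2, duration=1.0, rate=10_000.0)

    def test_recording_rejects_mixed_rates_and_duplicate_ids(self):
        s1 = flat_sweep(sweep_id="a")
        s2 = flat_sweep(rate=25_000.0, n=35_000, sweep_id="b")
        with pytest.raises(ValidationError, match="sampling rates"):
            NeuronRecording(neuron_id="n", sweeps=[s1, s2])
        with pytest.raises(ValidationError, match="duplicate"):
            NeuronRecording(neuron_id="n", sweeps=[s1, flat_sweep(sweep_id="a")])

    def test_recording_sorts_sweeps_by_amplitude(self):
        sweeps = [flat_sweep(amplitude=a, sweep_id=f"s{a:+.0f}")
                  for a in (50.0, -150.0, 0.0)]
        rec = NeuronRecording(neuron_id="n", sweeps=sweeps)
        assert [s.step.amplitude_pa for s in rec.sweeps] == [-150.0, 0.0, 50.0]

    def test_condition_labels_validated(self):
        with pytest.raises(ValidationError):
            NeuronRecording(neuron_id="n", sweeps=[flat_sweep()],
                            condition={"prep": "frozen"})

    def test_feature_row_rejects_sub_unity_sag(self):
        with pytest.raises(ValidationError, match="sag"):
            FeatureRow(neuron_id="n", rn_max_mohm=90.0, rn_ss_mohm=100.0,
                       sag_ratio=0.9)


class TestBaselineWindow:
    def test_default_100ms_window(self):
        sweep = flat_sweep()
        assert baseline_window(sweep) == pytest.approx((0.1, 0.2))

    def test_clipped_to_50ms_when_short(self):
        sweep = make_sweep(np.full(60_000, -70.0), onset=0.06)
        assert baseline_window(sweep) == pytest.approx((0.01, 0.06))

    def test_insufficient_baseline_errors(self):
        fake = SimpleNamespace(step=SimpleNamespace(onset_s=0.03), sweep_id="x")
        with pytest.raises(ValidationError):
            baseline_window(fake)


@pytest.mark.parametrize("fmt", ["container", "tabular"])
def test_dataset_round_trip_is_exact(tmp_path, fmt):
    rng = np.random.default_rng(0)
    sweeps = [
        make_sweep(-70.0 + rng.normal(0, 1, 2_000), rate=2_000.0,
                   amplitude=a, onset=0.1, duration=0.5, sweep_id=f"s{k}")
        for k, a in enumerate((-150.0, -50.0, 50.0))
    ]
    rec = NeuronRecording(neuron_id="n01", sweeps=sweeps, hours_post_slicing=12.5,
                          condition={"prep": "acute", "case": "tumor"},
                          cell_class="pyramidal")
    path = tmp_path / ("ds.h5" if fmt == "container" else "ds")
    write_dataset([rec], path, format=fmt)
    (back,) = load_dataset(path)
    assert back.neuron_id == rec.neuron_id
    assert back.hours_post_slicing == rec.hours_post_slicing
    assert back.condition == rec.condition
    assert back.cell_class == rec.cell_class
    for a, b in zip(rec.sweeps, back.sweeps):
        assert a.sweep_id == b.sweep_id
        assert a.step == b.step
        assert a.sampling_rate_hz == b.sampling_rate_hz
        np.testing.assert_array_equal(a.voltage_mv, b.voltage_mv)


def test_empty_directory_loads_empty_with_warning(tmp_path, caplog):
    (tmp_path / "empty").mkdir()
    with caplog.at_level(logging.WARNING, logger="slicephys.io"):
        recs = load_dataset(tmp_path / "empty")
    assert recs == []
    assert any("empty" in r.message for r in caplog.records)


def test_corrupt_sweep_file_names_the_sweep(tmp_path):
    rec = NeuronRecording(neuron_id="n01",
                          sweeps=[make_sweep(np.full(1_000, -70.0), rate=1_000.0,
                                             onset=0.1, duration=0.5)])
    write_dataset([rec], tmp_path / "ds", format="tabular")
    target = tmp_path / "ds" / "n01" / "sw0.tsv"
    lines = target.read_text().splitlines()
    lines[500] = "0.5\tnan"
    target.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValidationError, match="sw0"):
        load_dataset(tmp_path / "ds")


class TestFeatureTable:
    def rows(self):
        return [
            FeatureRow(neuron_id="a", rmp_mv=-69.123456789, rn_ss_mohm=120.0,
                       rn_max_mohm=130.0, sag_ratio=130.0 / 120.0,
                       rheobase_pa=250.0, max_ap_peak_mv=35.0, qc_pass=True,
                       hours_post_slicing=3.25, condition={"prep": "acute"}),
            FeatureRow(neuron_id="b", rmp_mv=-55.0, rheobase_pa=None,
                       qc_pass=False, flags=("no_aps",)),
            FeatureRow(neuron_id="c", rmp_mv=-60.0, sfa=1.5, cv_isi=0.2),
        ]

    def test_three_rows_plus_header(self, tmp_path):
        path = tmp_path / "features.csv"
        write_feature_table(self.rows(), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4
        assert lines[0].startswith("neuron_id,rmp_mV,")

    def test_absent_value_uses_na_sentinel(self, tmp_path):
        path = tmp_path / "features.csv"
        write_feature_table(self.rows(), path)
        df = read_feature_table(path)
        assert np.isnan(df.loc[df.neuron_id == "b", "rheobase_pA"].item())
        row_b = path.read_text().splitlines()[2]
        assert ",NA," in row_b

    def test_round_trip_full_precision(self, tmp_path):
        path = tmp_path / "features.csv"
        original = feature_frame(self.rows())
        write_feature_table(self.rows(), path)
        back = read_feature_table(path)
        for col in ("rmp_mV", "rn_ss_MOhm", "sag_ratio", "hours_post_slicing"):
            np.testing.assert_array_equal(
                back[col].to_numpy(), original[col].astype(float).to_numpy()
            )

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            feature_frame([])
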