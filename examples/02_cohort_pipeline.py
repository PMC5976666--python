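"""Run the full cohort pipeline on a simulated acute-vs-cultured contrast.

Two groups of neurons with realistic between-cell variability are simulated
that differ only in mean resting potential (−72 mV acutely vs −62 mV after
culture, a depolarizing shift like that seen across days in vitro), written
to an HDF5 dataset, and pushed through extraction, the inclusion filter and
the statistical battery.
"""

import tempfile
from pathlib import Path

import numpy as np

from slicephys import (
    PassiveModel,
    SpikeModel,
    run_pipeline,
    simulate_neuron,
    write_dataset,
)
from slicephys.synth import default_protocol

protocol = default_protocol()
rng = np.random.default_rng(0)
recordings = []
for k in range(12):
    acute = k < 6
    pm = PassiveModel(
        v_rest_mv=(-72.0 if acute else -62.0) + rng.normal(0, 2.0),
        r_input_mohm=rng.uniform(120.0, 180.0),
        r_sag_mohm=rng.uniform(15.0, 45.0),
    )
    sm = SpikeModel(
        threshold_true_mv=rng.normal(-40.0, 1.5),
        amplitude_true_mv=rng.normal(80.0, 4.0),
        halfwidth_true_ms=rng.normal(1.0, 0.08),
        adaptation_strength=rng.uniform(0.8, 1.4),
    )
    rec, _ = simulate_neuron(
        pm, sm, protocol, sampling_rate=10_000.0, seed=k,
        neuron_id=f"n{k:02d}",
        hours_post_slicing=float(rng.uniform(1, 12) if acute
                                 else rng.uniform(30, 75)),
        condition={"prep": "acute" if acute else "culture"},
        cell_class="pyramidal")
    recordings.append(rec)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cohort.h5"
    write_dataset(recordings, path)
    report = run_pipeline(path, out_dir=Path(tmp) / "out")

print(f"{report['n_pass_qc']}/{report['n_neurons']} neurons pass the "
      "inclusion filter (RMP < -50 mV, AP overshoot > 0 mV)\n")
prep = next(c for c in report["group_comparisons"]
            if c["contrast"]["column"] == "prep")
print(f"{'feature':<18}{'acute mean':>12}{'culture mean':>14}{'Welch p':>10}")
for r in prep["results"]:
    print(f"{r['feature']:<18}{r['location'][0]:>12.2f}"
          f"{r['location'][1]:>14.2f}{r['p_value']:>10.3g}")

print("\nrmp_mV separates the groups, and rheobase follows it mechanically:")
print("a depolarized cell sits closer to spike threshold and needs less")
print("current to fire.  The remaining features scatter around shared")
print("distributions.  p-values are raw: the battery applies no")
print("multiple-testing correction.")
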