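#!/usr/bin/env python
"""Spike-in calibration recovers global depletion; naive scaling does not.

For each depletion scenario, compare the treated : untreated ratio of the
median calibrated 100-kb-window signal under (a) alpha-scaled spike-in
downsampling factors and (b) naive total-fragment-count scaling, against the
planted genome-wide blanket scale.  The headline contrast: a uniform 5-fold
genome-wide loss is recovered by spike-in calibration (ratio ~0.2) but is
almost invisible to naive normalization (ratio ~0.9), because scaling away
total counts also scales away a uniform true change.

Writes results/calibration_recovery.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from spikecal import io
from spikecal import simulate as sim
from spikecal import workflows as wf

SCENARIOS = {
    "null": sim.Scenario("null"),
    "blanket_loss": sim.Scenario("blanket_loss", blanket_scale=0.2),
    "half_blanket_loss": sim.Scenario("half_blanket_loss", blanket_scale=0.5),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path,
                        default=Path("results/calibration_recovery.tsv"))
    args = parser.parse_args()

    cfg = sim.SimConfig(seed=args.seed)
    rows = []
    for name, scen in SCENARIOS.items():
        res = sim.simulate_chip_experiment(cfg, scen)
        rows.append({
            "scenario": name,
            "planted_blanket_scale": scen.blanket_scale,
            "spike_calibrated_ratio": wf.genome_window_ratio(
                res, normalization="spike"),
            "naive_total_count_ratio": wf.genome_window_ratio(
                res, normalization="naive"),
        })
    table = pd.DataFrame(rows)
    io.write_tsv(table, args.out, seed=args.seed)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    blanket = table.set_index("scenario").loc["blanket_loss"]
    print(
        f"\n5-fold uniform depletion: spike-in calibration reports "
        f"{blanket['spike_calibrated_ratio']:.3f} (planted 0.2); naive "
        f"normalization reports {blanket['naive_total_count_ratio']:.3f} "
        "and misses it.")


if __name__ == "__main__":
    main()
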