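#!/usr/bin/env python
"""Spike-in-anchored differential expression on simulated RNA data.

Three runs of the NB Wald test over a simulated calibrated nuclear RNA-seq
experiment (800 genes, 30% Polycomb targets, triplicates):

  1. null scenario — error control: almost nothing should be called;
  2. 4-fold derepression of Polycomb-target genes with spike-in-anchored
     size factors — recovery: target log2FC centers on 2, non-targets on 0;
  3. the same counts with naive total-count size factors — the global
     expression gain leaks into non-targets as an apparent down-shift.

Writes results/differential_rna.tsv (per-gene results of run 2) and
results/differential_summary.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spikecal import differential as de
from spikecal import io
from spikecal import simulate as sim
from spikecal.calibration import spikein_size_factors


def run_test(res, size_factors):
    cond = {lib.sample_id: lib.condition for lib in res.libraries}
    out = de.nb_wald_test(res.counts, size_factors, cond)
    return de.significance_call(out, mode="rna")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    genes = sim.make_gene_table(800, pcg_fraction=0.3, seed=args.seed)
    is_target = (genes.set_index("gene_id")["gene_class"] == "PcG_target")

    rows = []

    null = sim.simulate_rna_experiment(genes, sim.RnaScenario("null"),
                                       seed=args.seed)
    sf = spikein_size_factors(null.spike_counts,
                              {l.sample_id: l.mixing_ratio
                               for l in null.libraries})
    res0 = run_test(null, sf)
    rows.append({
        "run": "null_spike_anchored",
        "frac_called": float((res0["significant_up"]
                              | res0["significant_down"]).mean()),
        "target_log2fc": float(res0.loc[is_target.reindex(
            res0["feature_id"]).to_numpy(), "log2FC"].mean()),
        "nontarget_log2fc": float(res0.loc[~is_target.reindex(
            res0["feature_id"]).to_numpy(), "log2FC"].mean()),
    })

    scen = sim.RnaScenario("derepression", {"PcG_target": 4.0})
    derep = sim.simulate_rna_experiment(genes, scen, seed=args.seed)
    sf_spike = spikein_size_factors(derep.spike_counts,
                                    {l.sample_id: l.mixing_ratio
                                     for l in derep.libraries})
    res_spike = run_test(derep, sf_spike)
    mask = is_target.reindex(res_spike["feature_id"]).to_numpy()
    rows.append({
        "run": "derepression_spike_anchored",
        "frac_called": float((res_spike["significant_up"]
                              | res_spike["significant_down"]).mean()),
        "target_log2fc": float(res_spike.loc[mask, "log2FC"].mean()),
        "nontarget_log2fc": float(res_spike.loc[~mask, "log2FC"].mean()),
    })

    sf_naive = de.total_count_size_factors(derep.counts)
    res_naive = run_test(derep, sf_naive)
    rows.append({
        "run": "derepression_naive_totals",
        "frac_called": float((res_naive["significant_up"]
                              | res_naive["significant_down"]).mean()),
        "target_log2fc": float(res_naive.loc[mask, "log2FC"].mean()),
        "nontarget_log2fc": float(res_naive.loc[~mask, "log2FC"].mean()),
    })

    summary = pd.DataFrame(rows)
    io.write_tsv(res_spike, args.outdir / "differential_rna.tsv",
                 seed=args.seed)
    io.write_tsv(de.ma_table(res_spike), args.outdir / "differential_ma.tsv",
                 seed=args.seed)
    io.write_tsv(summary, args.outdir / "differential_summary.tsv",
                 seed=args.seed)
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    power = float(res_spike.loc[mask, "significant_up"].mean())
    print(f"\nPlanted 4-fold derepression of targets: mean log2FC "
          f"{summary.loc[1, 'target_log2fc']:.3f} (planted 2.0), power "
          f"{power:.3f}; naive totals shift non-targets to "
          f"{summary.loc[2, 'nontarget_log2fc']:.3f} log2 units.")


if __name__ == "__main__":
    main()
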