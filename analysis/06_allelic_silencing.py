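#!/usr/bin/env python
"""Allele-specific silencing gradient from a two-haplotype chromosome.

Simulates induction of chromosome-wide silencing spreading from an
integration site (maximal silencing 0.9, exponential decay length 20 Mb,
200 genes), assigns histone-mark reads to haplotypes from their SNP
observations, and quantifies:

  * the per-allele binned mark density (elevated on the silenced allele
    near the integration site);
  * the silencing gradient: Spearman correlation between per-gene repression
    magnitude |log2FC| and distance from the site (strongly negative), with
    a no-silencing control (near zero).

Writes results/allelic_profile.tsv, results/allelic_gradient.json.
"""

import argparse
from pathlib import Path

from spikecal import allelic as al
from spikecal import io
from spikecal import simulate as sim


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    res = sim.simulate_allelic_silencing(seed=args.seed)
    verdicts = al.assign_alleles(res.mark_reads, res.snp_obs)
    profile, qc = al.allelic_profile(res.mark_reads, verdicts,
                                     {"chrX": 100_000_000},
                                     bin_width=2_000_000)
    io.write_tsv(profile, args.outdir / "allelic_profile.tsv", seed=args.seed)
    print("read assignment fractions: "
          + ", ".join(f"{k}={v:.3f}" for k, v in qc.items()))

    site = res.truth.silencing_params["integration_position"]
    near = profile[(profile["start"] >= site - 10e6)
                   & (profile["end"] <= site + 10e6)]
    far = profile[profile["end"] <= 10e6]
    print(f"silenced:active mark-density ratio near site "
          f"{near['allele2'].mean() / near['allele1'].mean():.2f}, "
          f"far {far['allele2'].mean() / far['allele1'].mean():.2f}")

    lfc = al.allelic_expression_lfc(res.expr_counts)
    grad = al.silencing_gradient(lfc, res.genes["distance"])

    null = sim.simulate_allelic_silencing(max_silencing=0.0, seed=args.seed)
    grad0 = al.silencing_gradient(al.allelic_expression_lfc(null.expr_counts),
                                  null.genes["distance"])
    io.write_json({"induced": grad, "no_silencing_control": grad0},
                  args.outdir / "allelic_gradient.json", seed=args.seed)
    print(f"silencing gradient: rho {grad['rho']:.3f} over {grad['n']} genes "
          f"(no-silencing control rho {grad0['rho']:.3f})")


if __name__ == "__main__":
    main()
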