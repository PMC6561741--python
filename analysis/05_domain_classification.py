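#!/usr/bin/env python
"""Classify Polycomb chromatin domains from planted binding profiles.

k-means (k = 3) over concatenated PRC1 + PRC2 binding profiles around peak
centers, merging the two high-signal clusters into the classical-domain set,
evaluated against the planted cluster structure (adjusted Rand index and
exact recovery of the high-signal membership).  Also demonstrates the gene
tri-partition and chained sensitivity classes on a synthetic annotation.

Writes results/domain_classification.tsv and results/gene_classes.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from spikecal import domains as dom
from spikecal import io
from spikecal import simulate as sim


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    ring, suz, labels, high = sim.simulate_domain_profiles(
        n_peaks=300, separation=5.0, seed=args.seed)
    dc = dom.classify_polycomb_domains(ring, suz, k=3, seed=args.seed)
    ari = adjusted_rand_score(labels, dc.labels)
    exact = bool((dc.merged_high_mask == high).all())

    table = pd.DataFrame({
        "peak": np.arange(len(labels)),
        "planted_cluster": labels,
        "kmeans_cluster": dc.labels,
        "in_merged_domain_set": dc.merged_high_mask,
    })
    io.write_tsv(table, args.outdir / "domain_classification.tsv",
                 seed=args.seed)
    print(f"k-means vs planted clusters: ARI {ari:.3f}; merged high-signal "
          f"set recovered exactly: {exact} "
          f"({int(dc.merged_high_mask.sum())}/{len(labels)} peaks)")

    # gene tri-partition on a synthetic annotation built around the peaks
    rng = np.random.default_rng(args.seed)
    genes = pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(600)],
        "chrom": rng.choice(["c1", "c2"], 600),
        "tss": rng.integers(5_000, 995_000, 600),
    })

    def rand_set(n):
        s = rng.integers(0, 990_000, n)
        return pd.DataFrame({"chrom": rng.choice(["c1", "c2"], n),
                             "start": s, "end": s + 4_000})

    cls = dom.classify_genes(genes, rand_set(80), rand_set(60), rand_set(60))
    genes["gene_class"] = cls.to_numpy()
    io.write_tsv(genes, args.outdir / "gene_classes.tsv", seed=args.seed)
    counts = cls.value_counts()
    print("gene tri-partition:",
          ", ".join(f"{k}={counts.get(k, 0)}" for k in dom.GENE_CLASSES),
          f"(total {counts.sum()} of {len(genes)}; exhaustive and disjoint)")


if __name__ == "__main__":
    main()
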