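"""Polycomb chromatin-domain and gene classification.

Classical Polycomb chromatin domains are found by k-means clustering of
binned PRC1 (RING1B) and PRC2 (SUZ12) binding profiles around peak centers:
with k = 3, the two clusters with the highest combined signal are merged
into the domain set.  Genes are tri-partitioned by promoter overlap
(PcG-occupied / non-PcG with a non-methylated CpG island / non-NMI), PRC1
target genes are the PcG-occupied genes significantly derepressed upon
pan-PRC1 removal, and sensitivity classes are the chained-exclusion sets of
genes derepressed in progressively larger knockout combinations.

The two-pool summary reduces a peak-level and a genome-window signal matrix
to per-sample medians of punctate and blanket density on a common scale
anchored at the untreated punctate median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import SignalMatrix, overlaps_any

GENE_CLASSES = ("PcG_occupied", "nonPcG_NMI", "nonNMI")


@dataclass
class DomainClassification:
    labels: np.ndarray          # cluster label per peak, 0..k-1
    merged_high_mask: np.ndarray  # True for peaks in the merged high set
    cluster_order: np.ndarray   # clusters ranked by mean combined signal, desc
    k: int
    seed: int


def classify_polycomb_domains(ring1b_profile: np.ndarray,
                              suz12_profile: np.ndarray,
                              k: int = 3, seed: int = 0,
                              n_high: int = 2) -> DomainClassification:
    """k-means over concatenated, per-column-standardized binding profiles.

    Clusters are ranked by their mean combined (RING1B + SUZ12) raw signal;
    the top ``n_high`` clusters form the merged classical-domain set.
    Deterministic given ``seed`` (k-means++ with 50 restarts, best inertia).
    """
    ring1b_profile = np.asarray(ring1b_profile, float)
    suz12_profile = np.asarray(suz12_profile, float)
    if ring1b_profile.shape[0] != suz12_profile.shape[0]:
        raise ValueError("profile matrices must be row-aligned to one peak set")
    n = ring1b_profile.shape[0]
    if n < k:
        raise ValueError(f"fewer peaks ({n}) than clusters ({k})")
    feats = np.hstack([ring1b_profile, suz12_profile])
    if np.all(feats == feats[0]):
        raise ValueError("degenerate input: all profile rows are identical")
    sd = feats.std(axis=0)
    std = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(std)
    labels = km.labels_
    combined = (ring1b_profile.mean(axis=1) + suz12_profile.mean(axis=1)) / 2
    cluster_means = np.array([combined[labels == c].mean() for c in range(k)])
    order = np.argsort(-cluster_means)
    merged = np.isin(labels, order[:n_high])
    return DomainClassification(labels=labels, merged_high_mask=merged,
                                cluster_order=order, k=k, seed=seed)


def _tss_windows(genes: pd.DataFrame, window: int = 2500) -> pd.DataFrame:
    """Promoter windows [TSS - window, TSS + window), clipped at zero."""
    return pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": np.maximum(genes["tss"].to_numpy(np.int64) - window, 0),
        "end": genes["tss"].to_numpy(np.int64) + window,
    })


def classify_genes(genes: pd.DataFrame, nmi_intervals: pd.DataFrame,
                   ring1b_peaks: pd.DataFrame, suz12_peaks: pd.DataFrame,
                   window: int = 2500) -> pd.Series:
    """Exhaustive, disjoint tri-partition of genes by promoter overlap.

    PcG_occupied: the TSS window overlaps (>= 1 bp) both a RING1B and a
    SUZ12 peak; else nonPcG_NMI if it overlaps a non-methylated CpG island;
    else nonNMI.
    """
    tss = _tss_windows(genes, window)
    ring = overlaps_any(tss, ring1b_peaks)
    suz = overlaps_any(tss, suz12_peaks)
    nmi = overlaps_any(tss, nmi_intervals)
    cls = np.where(ring & suz, "PcG_occupied",
                   np.where(nmi, "nonPcG_NMI", "nonNMI"))
    return pd.Series(cls, index=genes["gene_id"].to_numpy(), name="gene_class")


def select_prc1_targets(pcg_genes, diff_result: pd.DataFrame) -> list:
    """PcG-occupied genes significantly derepressed upon pan-PRC1 removal."""
    pcg = list(pcg_genes)
    known = set(diff_result["feature_id"])
    missing = [g for g in pcg if g not in known]
    if missing:
        warnings.warn(f"{len(missing)} PcG-occupied genes absent from the "
                      "differential result were excluded", stacklevel=2)
    up = set(diff_result.loc[diff_result["significant_up"], "feature_id"])
    return [g for g in pcg if g in up]


def sensitivity_classes(diff_pcgf1: pd.DataFrame, diff_pcgf135: pd.DataFrame,
                        diff_pcgf1356: pd.DataFrame) -> dict:
    """Chained-exclusion sensitivity classes over one gene universe.

    PCGF1-sensitive = up in the PCGF1 knockout; PCGF1/3/5-sensitive = up in
    the triple knockout minus the first class; PCGF1/3/5/6-sensitive = up in
    the quadruple knockout minus both.  Pairwise disjoint by construction.
    """
    def up(d):
        return set(d.loc[d["significant_up"], "feature_id"])

    c1 = up(diff_pcgf1)
    c135 = up(diff_pcgf135) - c1
    c1356 = up(diff_pcgf1356) - c1 - up(diff_pcgf135)
    return {"PCGF1": c1, "PCGF135": c135, "PCGF1356": c1356}


def two_pool_summary(peak_matrix: SignalMatrix, window_matrix: SignalMatrix,
                     untreated: str) -> pd.DataFrame:
    """Per-sample punctate and blanket medians on the normalized scale.

    Both matrices are converted to per-kb densities and divided by the
    untreated sample's median peak density, so the untreated punctate median
    is exactly 1 and blanket medians are expressed on the same scale.
    """
    peak_kb = peak_matrix.per_kb()
    win_kb = window_matrix.per_kb()
    if untreated not in peak_kb.samples:
        raise ValueError(f"untreated sample {untreated!r} not in matrix")
    ref = float(np.median(peak_kb.column(untreated)))
    if ref <= 0:
        raise ValueError("untreated punctate median is zero; cannot normalize")
    rows = []
    for sid in peak_kb.samples:
        rows.append({
            "sample_id": sid,
            "punctate_median": float(np.median(peak_kb.column(sid))) / ref,
            "blanket_median": float(np.median(win_kb.column(sid))) / ref,
        })
    return pd.DataFrame(rows)
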