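"""Spike-in-anchored negative-binomial differential testing.

A simplified NB Wald test over a two-condition count matrix: per-feature
method-of-moments dispersion moderated toward the across-feature median,
delta-method standard errors on the log2 fold change, two-sided Wald
p-values, and Benjamini-Hochberg adjustment.  Size factors are supplied by
the caller — spike-in-anchored factors from control intervals when the
comparison must be robust to global signal shifts, or naive total-count
factors when demonstrating the artifact such shifts cause.

Significance uses the thresholds adj. p < 0.05 (ChIP mode) and additionally
fold change > 1.5 (RNA mode).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PHI_FLOOR = 1e-8

RESULT_COLUMNS = ["feature_id", "base_mean", "log2FC", "se", "p", "padj",
                  "significant_up", "significant_down"]


def total_count_size_factors(counts: pd.DataFrame) -> dict:
    """Naive library-size factors: column total / geometric mean of totals."""
    totals = counts.sum(axis=0).to_numpy(float)
    return dict(zip(counts.columns,
                    totals / np.exp(np.mean(np.log(totals)))))


def estimate_dispersion(counts: pd.DataFrame, size_factors: Mapping[str, float],
                        condition: Mapping[str, str],
                        phi_floor: float = PHI_FLOOR,
                        prior_df: float = 5.0) -> np.ndarray:
    """Per-feature NB dispersion, method of moments with median moderation.

    Normalized counts are pooled within condition; the raw estimate is
    ``max(phi_floor, (s2 - m) / m**2)`` combined across conditions weighted
    by residual degrees of freedom, then shrunk toward the across-feature
    median with weight ``prior_df`` pseudo-degrees of freedom.  With only a
    handful of replicates the raw estimate is wildly variable (and truncates
    at the floor whenever the sample variance falls below the mean), so
    moderation is what keeps the downstream Wald test calibrated.
    """
    groups = {}
    for sid in counts.columns:
        groups.setdefault(condition[sid], []).append(sid)
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("dispersion estimation needs >= 2 replicates per "
                         "condition; supply dispersions explicitly otherwise")
    sf = np.array([size_factors[s] for s in counts.columns], float)
    norm = counts.to_numpy(float) / sf

    num = np.zeros(len(counts))
    df_total = 0.0
    for sids in groups.values():
        idx = [counts.columns.get_loc(s) for s in sids]
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (s2 - m) / m ** 2
        phi = np.where(np.isfinite(phi), phi, 0.0)
        df = len(sids) - 1
        num += df * phi
        df_total += df
    raw = np.maximum(num / df_total, phi_floor)
    med = float(np.median(raw))
    w = df_total / (df_total + prior_df)
    return np.maximum(w * raw + (1 - w) * max(med, phi_floor), phi_floor)


def nb_wald_test(counts: pd.DataFrame, size_factors: Mapping[str, float],
                 condition: Mapping[str, str], dispersions=None,
                 treated: str = "treated", untreated: str = "untreated",
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-feature Wald test of treated vs. untreated normalized means.

    log2FC = log2((mean_t + c) / (mean_u + c)) on size-factor-normalized
    counts; SE from the NB delta method (var of a normalized group mean is
    (m + phi * m**2) / n).  Features with all-zero counts are excluded from
    testing and reported with NA statistics.
    """
    samples = list(counts.columns)
    t_cols = [s for s in samples if condition[s] == treated]
    u_cols = [s for s in samples if condition[s] == untreated]
    if len(t_cols) < 2 or len(u_cols) < 2:
        raise ValueError("need >= 2 replicates in each condition")
    sf = {s: size_factors[s] for s in samples}
    if any(v <= 0 for v in sf.values()):
        raise ValueError("size factors must be > 0")
    norm = counts.to_numpy(float) / np.array([sf[s] for s in samples])
    norm_df = pd.DataFrame(norm, index=counts.index, columns=samples)

    base_mean = norm_df.mean(axis=1).to_numpy()
    m_t = norm_df[t_cols].mean(axis=1).to_numpy()
    m_u = norm_df[u_cols].mean(axis=1).to_numpy()
    tested = counts.sum(axis=1).to_numpy() > 0

    if dispersions is None:
        phi = estimate_dispersion(counts, sf, condition)
    else:
        phi = np.broadcast_to(np.asarray(dispersions, float),
                              (len(counts),)).copy()

    c = pseudocount
    log2fc = np.log2(m_t + c) - np.log2(m_u + c)
    var_t = (m_t + phi * m_t ** 2) / len(t_cols) / (m_t + c) ** 2
    var_u = (m_u + phi * m_u ** 2) / len(u_cols) / (m_u + c) ** 2
    se = np.sqrt(var_t + var_u) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, 1.0)

    padj = np.full(len(counts), np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame({
        "feature_id": counts.index.astype(str),
        "base_mean": base_mean,
        "log2FC": np.where(tested, log2fc, np.nan),
        "se": np.where(tested, se, np.nan),
        "p": np.where(tested, p, np.nan),
        "padj": padj,
    })
    out["significant_up"] = False
    out["significant_down"] = False
    return significance_call(out, mode="chip")


def significance_call(results: pd.DataFrame, padj_cut: float = 0.05,
                      mode: str = "chip",
                      fc_cut: float | None = None) -> pd.DataFrame:
    """Apply the significance thresholds and set the up/down flags.

    ChIP mode: adj. p < padj_cut.  RNA mode: additionally requires fold
    change > fc_cut (default 1.5) in the called direction.
    """
    if mode not in ("chip", "rna"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "rna" and fc_cut is None:
        fc_cut = 1.5
    out = results.copy()
    ok = out["padj"].to_numpy() < padj_cut
    fc = 2.0 ** out["log2FC"].to_numpy()
    up = ok & (out["log2FC"].to_numpy() > 0)
    down = ok & (out["log2FC"].to_numpy() < 0)
    if mode == "rna":
        up &= fc > fc_cut
        down &= fc < 1.0 / fc_cut
    out["significant_up"] = np.where(np.isnan(out["padj"]), False, up)
    out["significant_down"] = np.where(np.isnan(out["padj"]), False, down)
    return out


def ma_table(results: pd.DataFrame) -> pd.DataFrame:
    """(mean, log2FC, flag) projection ordered by mean, for MA plotting."""
    tested = results.dropna(subset=["p"])
    out = tested[["feature_id", "base_mean", "log2FC"]].copy()
    out["significant"] = (tested["significant_up"]
                          | tested["significant_down"]).to_numpy()
    return out.sort_values("base_mean").reset_index(drop=True)
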