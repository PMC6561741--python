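"""Replicate concordance gating and merging.

Replicates are compared by pairwise Pearson correlation of log2(x + 1)
per-interval densities over regions of interest; a group passes iff the
minimum pairwise correlation exceeds the threshold (default 0.9).  Passing
replicates are merged by elementwise summation for downstream quantitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReplicateGroup:
    sample_ids: list
    correlations: pd.DataFrame  # symmetric, unit diagonal
    min_r: float
    passed: bool
    threshold: float
    message: str = ""


def replicate_concordance(values: pd.DataFrame, threshold: float = 0.9
                          ) -> ReplicateGroup:
    """Pairwise Pearson on log2(x + 1) signal over regions of interest."""
    samples = list(values.columns)
    if len(samples) < 2:
        raise ValueError("concordance needs >= 2 replicates")
    logv = np.log2(values.to_numpy(float) + 1.0)
    sds = logv.std(axis=0)
    if np.any(sds == 0):
        bad = [s for s, sd in zip(samples, sds) if sd == 0]
        corr = pd.DataFrame(np.eye(len(samples)), index=samples,
                            columns=samples)
        return ReplicateGroup(samples, corr, float("nan"), False, threshold,
                              message=f"zero-variance sample(s): {bad}; "
                                      "correlation undefined")
    corr = pd.DataFrame(np.corrcoef(logv, rowvar=False), index=samples,
                        columns=samples)
    off = corr.to_numpy()[~np.eye(len(samples), dtype=bool)]
    min_r = float(off.min())
    return ReplicateGroup(samples, corr, min_r, min_r > threshold, threshold)


def merge_replicates(counts: pd.DataFrame, group: ReplicateGroup,
                     override: bool = False) -> pd.Series:
    """Elementwise sum of replicate counts for a passing group."""
    if not group.passed and not override:
        raise ValueError(
            "refusing to merge a replicate group that failed concordance "
            f"(min r = {group.min_r:.3f} <= {group.threshold}); "
            "pass override=True to force. " + group.message)
    return counts[group.sample_ids].sum(axis=1)


def merge_library_totals(libraries) -> dict:
    """Summed genome-split totals of merged member libraries."""
    return {
        "n_target": sum(lib.n_target for lib in libraries),
        "n_spike": sum(lib.n_spike for lib in libraries),
        "control_n_target": sum(lib.control_n_target for lib in libraries),
        "control_n_spike": sum(lib.control_n_spike for lib in libraries),
    }
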