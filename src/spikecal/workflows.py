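"""High-level analyses composing the pipeline stages.

These are the quantitation recipes the analysis drivers, tests, and the
acceptance script share: genome-wide window recovery of a global depletion
under spike-in versus naive normalization, and the two-pool (punctate /
blanket) decomposition of a simulated experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import calibrate_group
from .domains import two_pool_summary
from .intervals import SignalMatrix, make_windows, sum_into_windows
from .simulate import ChipSimResult


def _condition_means(values: dict, sample_ids, reducer=np.mean) -> dict:
    out = {}
    for cond in ("untreated", "treated"):
        cols = [s for s in sample_ids if s.startswith(cond)]
        out[cond] = reducer([values[s] for s in cols])
    return out


def genome_window_ratio(result: ChipSimResult, window: int = 100_000,
                        normalization: str = "spike") -> float:
    """Treated : untreated ratio of median genome-window signal.

    ``normalization="spike"`` applies alpha-scaled spike-in downsampling
    factors; ``"naive"`` divides each sample by its total target-genome
    fragment count — the comparison that motivates spike-in calibration: a
    uniform genome-wide depletion is invisible to total-count scaling.
    """
    windows = make_windows(result.config.target_chrom_sizes, window)
    sids = result.sample_ids
    sm = sum_into_windows(result.counts, sids, windows)
    if normalization == "spike":
        factors = calibrate_group(result.libraries).scaled_factor
    elif normalization == "naive":
        factors = {lib.sample_id: 1.0 / lib.n_target
                   for lib in result.libraries}
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    medians = {sid: float(np.median(sm.column(sid) * factors[sid]))
               for sid in sids}
    cond = _condition_means(medians, sids)
    return cond["treated"] / cond["untreated"]


def two_pool_from_sim(result: ChipSimResult, window: int = 100_000,
                      merge_replicates: bool = True) -> pd.DataFrame:
    """Punctate / blanket medians of a simulated experiment, calibrated.

    Replicate counts are merged per condition (after calibration their sum
    equals the calibrated sum of the pooled library), peak-level and
    100-kb-window matrices are formed, and the two-pool summary is anchored
    at the untreated punctate median.
    """
    factors = calibrate_group(result.libraries).scaled_factor
    sids = result.sample_ids
    calibrated = {s: result.counts[s].to_numpy(float) * factors[s]
                  for s in sids}
    if merge_replicates:
        samples = ["untreated", "treated"]
        mat = {c: np.sum([calibrated[s] for s in sids if s.startswith(c)],
                         axis=0) for c in samples}
    else:
        samples = sids
        mat = calibrated
    frame = result.counts.copy()
    for s in samples:
        frame[s] = mat[s]

    peaks = frame.loc[frame["is_peak"]].reset_index(drop=True)
    peak_matrix = SignalMatrix(peaks[["chrom", "start", "end"]], samples,
                               peaks[samples].to_numpy(float))
    windows = make_windows(result.config.target_chrom_sizes, window)
    window_matrix = sum_into_windows(frame, samples, windows)
    untreated = "untreated" if merge_replicates else \
        [s for s in samples if s.startswith("untreated")][0]
    return two_pool_summary(peak_matrix, window_matrix, untreated)


def pool_change(summary: pd.DataFrame, pool: str,
                treated: str = "treated",
                untreated: str = "untreated") -> float:
    """Fold change (max/min) of one pool's median between conditions."""
    col = f"{pool}_median"
    s = summary.set_index("sample_id")[col]
    hi, lo = max(s[treated], s[untreated]), min(s[treated], s[untreated])
    return float(hi / lo)
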