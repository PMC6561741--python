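"""Genomic interval arithmetic and calibrated signal quantitation.

Coordinates are 0-based, half-open throughout (BED convention).  Interval
sets are plain DataFrames with at least ``chrom``, ``start``, ``end``
columns; fragments are DataFrames with ``chrom`` and ``pos`` (midpoint)
columns.  Overlap for consensus/blacklist/retained-signal filtering is >= 1 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def _as_interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame lacks columns {missing}")
    if len(df) and not (df["start"] < df["end"]).all():
        raise ValueError("intervals must satisfy start < end")
    return df


@dataclass
class SignalMatrix:
    """Per-interval x per-sample signal with normalization provenance.

    ``normalization`` records how ``values`` were derived:
    raw | per_kb | untreated_median_1 | center_1.
    """

    intervals: pd.DataFrame
    samples: list[str]
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.intervals), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.intervals)} intervals x {len(self.samples)} samples"
            )

    def per_kb(self) -> "SignalMatrix":
        """Divide each row by its interval length in kb."""
        kb = (self.intervals["end"] - self.intervals["start"]).to_numpy() / 1000.0
        return SignalMatrix(self.intervals, list(self.samples),
                            self.values / kb[:, None], normalization="per_kb")

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]

    def to_frame(self) -> pd.DataFrame:
        out = self.intervals[BED_COLUMNS].reset_index(drop=True).copy()
        for j, s in enumerate(self.samples):
            out[s] = self.values[:, j]
        return out


def make_windows(chrom_sizes: Mapping[str, int], width: int) -> pd.DataFrame:
    """Tile each chromosome with consecutive fixed-width windows.

    The last window of a chromosome is truncated at the chromosome end, so
    the union of windows covers the genome exactly once and the window count
    is sum(ceil(L / width)) over chromosomes.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    chroms, starts, ends = [], [], []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"{chrom}: chromosome length must be > 0")
        edges = np.arange(0, size + width, width)
        edges[-1] = min(edges[-1], size)
        s = edges[:-1]
        e = np.minimum(edges[1:], size)
        keep = s < e
        chroms.extend([chrom] * int(keep.sum()))
        starts.extend(s[keep])
        ends.extend(e[keep])
    return pd.DataFrame({"chrom": chroms,
                         "start": np.asarray(starts, np.int64),
                         "end": np.asarray(ends, np.int64)})


def count_in_intervals(fragments: pd.DataFrame, intervals: pd.DataFrame,
                       return_unassigned: bool = False):
    """Count fragment midpoints per interval (half-open containment).

    Each fragment is assigned to at most one interval: per chromosome the
    intervals are sorted by start and the fragment falls into the rightmost
    interval starting at or before its midpoint, provided the midpoint lies
    before that interval's end.  Intervals are assumed non-overlapping within
    a chromosome (true for windows and merged peak sets).  Fragments on
    chromosomes absent from the interval set are counted as unassigned with
    a warning.
    """
    intervals = _as_interval_frame(intervals)
    counts = np.zeros(len(intervals), np.int64)
    unassigned = 0
    interval_chroms = set(intervals["chrom"].unique())
    for chrom, frag in fragments.groupby("chrom", sort=False):
        if chrom not in interval_chroms:
            unassigned += len(frag)
            warnings.warn(f"{len(frag)} fragments on unknown chromosome {chrom!r} "
                          "left unassigned", stacklevel=2)
            continue
        sub = intervals.index[intervals["chrom"] == chrom]
        starts = intervals.loc[sub, "start"].to_numpy()
        ends = intervals.loc[sub, "end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        pos = frag["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        unassigned += int((~ok).sum())
        hit = np.bincount(idx[ok], minlength=len(sub))
        counts[sub[order]] += hit
    if return_unassigned:
        return counts, unassigned
    return counts


def sum_into_windows(interval_counts: pd.DataFrame, sample_columns,
                     windows: pd.DataFrame) -> "SignalMatrix":
    """Aggregate per-interval counts into windows by interval midpoint.

    Each source interval contributes its whole count to the window containing
    its midpoint (the window partition is non-overlapping), so total counts
    are conserved for genome-covering window sets.
    """
    windows = _as_interval_frame(windows)
    mids = ((interval_counts["start"] + interval_counts["end"]) // 2)
    values = np.zeros((len(windows), len(sample_columns)))
    for chrom, sub in interval_counts.groupby("chrom", sort=False):
        sel = windows.index[windows["chrom"] == chrom]
        if len(sel) == 0:
            continue
        starts = windows.loc[sel, "start"].to_numpy()
        ends = windows.loc[sel, "end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        pos = mids.loc[sub.index].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0)
        ok[ok] &= pos[ok] < ends[idx[ok]]
        for j, col in enumerate(sample_columns):
            w = sub[col].to_numpy(float)
            values[sel[order], j] += np.bincount(idx[ok], weights=w[ok],
                                                 minlength=len(sel))
    return SignalMatrix(windows, list(sample_columns), values,
                        normalization="raw")


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union-merge overlapping or bookended intervals per chromosome."""
    intervals = _as_interval_frame(intervals)
    if len(intervals) == 0:
        return intervals[BED_COLUMNS].copy()
    out = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each query interval overlap (>= 1 bp) any subject?"""
    query = _as_interval_frame(query)
    subject = _as_interval_frame(subject)
    mask = np.zeros(len(query), bool)
    if len(subject) == 0 or len(query) == 0:
        return mask
    merged = merge_intervals(subject)
    for chrom, sub in merged.groupby("chrom", sort=False):
        sel = (query["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        s_starts = sub["start"].to_numpy()
        s_ends = sub["end"].to_numpy()
        q_starts = query.loc[sel, "start"].to_numpy()
        q_ends = query.loc[sel, "end"].to_numpy()
        # overlap with merged disjoint intervals: the first subject whose end
        # exceeds the query start must begin before the query end
        idx = np.searchsorted(s_ends, q_starts, side="right")
        hit = (idx < len(s_starts)) & (s_starts[np.minimum(idx, len(s_starts) - 1)]
                                       < q_ends)
        mask[np.flatnonzero(sel)] = hit
    return mask


def consensus_peaks(peak_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Regions supported by every replicate peak set.

    All peaks are union-merged into candidate regions; a candidate is kept iff
    it overlaps (>= 1 bp) at least one peak from every input set.  Output
    coordinates are the merged candidates, so consensus over a single set
    returns that set merged.
    """
    if len(peak_sets) == 0:
        raise ValueError("consensus requires at least one peak set")
    candidates = merge_intervals(pd.concat(
        [_as_interval_frame(p)[BED_COLUMNS] for p in peak_sets],
        ignore_index=True))
    keep = np.ones(len(candidates), bool)
    for peaks in peak_sets:
        keep &= overlaps_any(candidates, peaks)
    return candidates.loc[keep].reset_index(drop=True)


def subtract_blacklist(peaks: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Drop whole peaks overlapping (>= 1 bp) any blacklisted region."""
    peaks = _as_interval_frame(peaks)
    if len(blacklist) == 0:
        return peaks.reset_index(drop=True)
    return peaks.loc[~overlaps_any(peaks, blacklist)].reset_index(drop=True)


def remove_retained_peaks(peaks: pd.DataFrame,
                          knockout_peak_calls: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks still called in the knockout condition.

    Signal retained after removing the profiled factor marks antibody or
    mapping artifacts, so any peak overlapping a knockout-condition call is
    discarded whole.
    """
    return subtract_blacklist(peaks, knockout_peak_calls)


def profile_matrix(fragments: pd.DataFrame, centers: pd.DataFrame,
                   chrom_sizes: Mapping[str, int], flank: int = 10_000,
                   bin_width: int = 1_000):
    """Per-center binned fragment density over +/- flank around each center.

    Returns ``(matrix, kept_mask)``: matrix rows align with centers whose
    full flank fits inside the chromosome; ``kept_mask`` marks which centers
    were usable.  ``centers`` needs ``chrom`` plus either a ``center`` column
    or start/end (midpoint used).  Values are fragments per bin (density per
    bin of constant width; scaling is the caller's concern).
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    if "center" in centers.columns:
        mids = centers["center"].to_numpy(np.int64)
    else:
        mids = ((centers["start"] + centers["end"]) // 2).to_numpy(np.int64)
    chroms = centers["chrom"].to_numpy()
    sizes = np.array([chrom_sizes.get(c, -1) for c in chroms])
    kept = (mids - flank >= 0) & (mids + flank <= sizes)
    mat = np.zeros((int(kept.sum()), n_bins))
    frag_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in
                     fragments.groupby("chrom", sort=False)}
    row = 0
    for i in np.flatnonzero(kept):
        pos = frag_by_chrom.get(chroms[i])
        if pos is not None:
            lo = np.searchsorted(pos, mids[i] - flank, side="left")
            hi = np.searchsorted(pos, mids[i] + flank, side="left")
            rel = (pos[lo:hi] - (mids[i] - flank)) // bin_width
            mat[row] = np.bincount(rel, minlength=n_bins)
        row += 1
    return mat, kept


def metaprofile(fragments_by_sample: Mapping[str, pd.DataFrame],
                centers: pd.DataFrame, chrom_sizes: Mapping[str, int],
                factors: Mapping[str, float], untreated: str,
                flank: int = 10_000, bin_width: int = 1_000) -> pd.DataFrame:
    """Mean calibrated density profile around centers, per sample.

    Per sample, fragment counts in each bin are averaged over centers and
    multiplied by the sample's calibration factor.  The whole dataset is then
    scaled by one constant so the untreated sample's center bin equals 1;
    treated samples share the constant, preserving treated/untreated ratios.
    Centers closer than ``flank`` to a chromosome edge are excluded (their
    count is reported in the ``n_excluded`` attribute of the result).
    """
    if untreated not in fragments_by_sample:
        raise ValueError(f"untreated sample {untreated!r} not supplied")
    n_bins = 2 * flank // bin_width
    offsets = (np.arange(n_bins) - n_bins // 2) * bin_width + bin_width // 2
    prof = {}
    n_excluded = 0
    for sid, frags in fragments_by_sample.items():
        mat, kept = profile_matrix(frags, centers, chrom_sizes, flank, bin_width)
        n_excluded = int((~kept).sum())
        prof[sid] = mat.mean(axis=0) * factors[sid]
    center_bins = [n_bins // 2 - 1, n_bins // 2]
    ref = np.mean(prof[untreated][center_bins])
    if ref <= 0:
        raise ValueError("untreated center-bin density is zero; cannot scale")
    out = pd.DataFrame({sid: v / ref for sid, v in prof.items()})
    out.insert(0, "offset", offsets)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["normalization"] = "center_1"
    return out


def chromosome_density(fragments_by_sample: Mapping[str, pd.DataFrame],
                       chrom_sizes: Mapping[str, int],
                       factors: Mapping[str, float],
                       bin_width: int = 250_000,
                       per_kb: bool = True) -> SignalMatrix:
    """Calibrated fragment density in fixed-width chromosome bins."""
    windows = make_windows(chrom_sizes, bin_width)
    samples = list(fragments_by_sample)
    values = np.zeros((len(windows), len(samples)))
    for j, sid in enumerate(samples):
        values[:, j] = count_in_intervals(fragments_by_sample[sid], windows)
        values[:, j] = values[:, j] * factors[sid]
    sm = SignalMatrix(windows, samples, values, normalization="raw")
    return sm.per_kb() if per_kb else sm
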