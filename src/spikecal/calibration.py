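"""Spike-in calibration of genome-split sequencing libraries.

Each experimental sample carries a fixed admixture of foreign ("spike-in")
cells, so reads split by genome of origin provide an internal anchor for
quantitative comparison across conditions.  The per-sample downsampling
factor is

    factor = alpha * (1 / N_spike_sample) * (N_spike_control / N_target_control)

where the control library (Input chromatin, or sheared genomic DNA for RNA
assays) measures the realized spike-in : target mixing ratio of that
particular sample, and ``alpha`` is a group constant chosen so the largest
factor within a jointly normalized sample group equals 1 exactly.

For differential testing, spike-in counts over a control interval set yield
median-of-ratios size factors after pre-normalizing each sample's spike
counts by its realized mixing ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd


class CalibrationError(ValueError):
    """Raised when a library's totals make spike-in calibration impossible."""


@dataclass
class SampleLibrary:
    """Genome-split fragment totals for one library and its matched control.

    Attributes
    ----------
    sample_id : str
        Unique label.
    assay : {"chip", "rna"}
    condition : str
        Biological condition label (e.g. ``"untreated"``, ``"treated"``).
    replicate : int
    n_target : int
        Fragments mapping to the target (experimental) genome.
    n_spike : int
        Fragments mapping to the spike-in genome.
    control_n_target, control_n_spike : int
        The same totals for the matched control library (Input chromatin or
        genomic DNA), which measure the realized mixing ratio.
    control_kind : {"input", "genomic_dna"}
        ``genomic_dna`` is permitted only for RNA assays.
    """

    sample_id: str
    assay: Literal["chip", "rna"]
    condition: str
    replicate: int
    n_target: int
    n_spike: int
    control_n_target: int
    control_n_spike: int
    control_kind: Literal["input", "genomic_dna"] = "input"

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "rna"):
            raise ValueError(f"{self.sample_id}: unknown assay {self.assay!r}")
        if self.control_kind not in ("input", "genomic_dna"):
            raise ValueError(
                f"{self.sample_id}: unknown control_kind {self.control_kind!r}"
            )
        if self.control_kind == "genomic_dna" and self.assay != "rna":
            raise ValueError(
                f"{self.sample_id}: genomic_dna controls are valid only for RNA assays"
            )
        for name in ("n_target", "n_spike", "control_n_target", "control_n_spike"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.sample_id}: {name} must be >= 0")

    @property
    def mixing_ratio(self) -> float:
        """Realized spike-in : target ratio measured in the control library."""
        return mixing_ratio(self.control_n_spike, self.control_n_target,
                            sample_id=self.sample_id)


@dataclass
class CalibrationSet:
    """Raw and alpha-scaled downsampling factors for one normalized group."""

    raw_factor: dict[str, float]
    scaled_factor: dict[str, float]
    alpha: float
    size_factor: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.raw_factor:
            rows.append({
                "sample_id": sid,
                "raw_factor": self.raw_factor[sid],
                "scaled_factor": self.scaled_factor[sid],
                "alpha": self.alpha,
                "size_factor": self.size_factor.get(sid, float("nan")),
            })
        return pd.DataFrame(rows)


def raw_downsampling_factor(n_spike: float, control_n_spike: float,
                            control_n_target: float, *,
                            sample_id: str = "<sample>") -> float:
    """Alpha-free downsampling factor from genome-split totals.

    ``(1 / n_spike) * (control_n_spike / control_n_target)`` — strictly
    decreasing in the sample's spike-in total and proportional to the
    spike:target ratio of the matched control.
    """
    if n_spike <= 0:
        raise CalibrationError(
            f"{sample_id}: n_spike must be > 0 for calibration (got {n_spike})"
        )
    if control_n_target <= 0:
        raise CalibrationError(
            f"{sample_id}: control_n_target must be > 0 (got {control_n_target})"
        )
    if control_n_spike < 0:
        raise CalibrationError(
            f"{sample_id}: control_n_spike must be >= 0 (got {control_n_spike})"
        )
    return (1.0 / n_spike) * (control_n_spike / control_n_target)


def mixing_ratio(control_n_spike: float, control_n_target: float, *,
                 sample_id: str = "<sample>") -> float:
    """Realized spike-in : target cell-mixing ratio from control totals."""
    if control_n_target <= 0:
        raise CalibrationError(
            f"{sample_id}: control_n_target must be > 0 (got {control_n_target})"
        )
    ratio = control_n_spike / control_n_target
    if ratio == 0:
        warnings.warn(
            f"{sample_id}: control spike-in total is zero; "
            "spike-in calibration will be impossible downstream",
            stacklevel=2,
        )
    return ratio


def alpha_scale(raw_factors: Mapping[str, float]) -> CalibrationSet:
    """Scale raw factors by the group constant alpha = 1 / max(raw).

    The largest scaled factor equals 1 exactly, so calibration only ever
    down-samples; every other sample is thinned relative to the least
    spike-rich library of the group.
    """
    if len(raw_factors) == 0:
        raise CalibrationError("alpha_scale requires at least one sample")
    for sid, f in raw_factors.items():
        if not np.isfinite(f) or f <= 0:
            raise CalibrationError(f"{sid}: raw factor must be positive (got {f})")
    alpha = 1.0 / max(raw_factors.values())
    scaled = {sid: alpha * f for sid, f in raw_factors.items()}
    # guard against round-off: the argmax sample is exactly 1
    top = max(scaled, key=scaled.get)
    scaled[top] = 1.0
    return CalibrationSet(raw_factor=dict(raw_factors), scaled_factor=scaled,
                          alpha=alpha)


def calibrate_group(libraries: Sequence[SampleLibrary]) -> CalibrationSet:
    """Raw factors + alpha scaling for one jointly normalized group."""
    raw = {
        lib.sample_id: raw_downsampling_factor(
            lib.n_spike, lib.control_n_spike, lib.control_n_target,
            sample_id=lib.sample_id)
        for lib in libraries
    }
    return alpha_scale(raw)


def calibrate_counts(counts, scaled_factor: float,
                     mode: Literal["expected", "subsample"] = "expected",
                     seed: int | None = None):
    """Apply a scaled downsampling factor to per-interval counts.

    ``expected`` multiplies counts by the factor (real-valued output);
    ``subsample`` draws Binomial(count, factor) per interval (integer
    output), the count-level equivalent of randomly subsampling reads.
    The expectation of ``subsample`` equals the ``expected`` mode.
    """
    if not (0 < scaled_factor <= 1):
        raise CalibrationError(
            f"scaled factor must lie in (0, 1], got {scaled_factor}"
        )
    arr = np.asarray(counts)
    if mode == "expected":
        return arr * scaled_factor
    if mode == "subsample":
        rng = np.random.default_rng(seed)
        return rng.binomial(arr.astype(np.int64), scaled_factor)
    raise ValueError(f"unknown calibration mode {mode!r}")


def spikein_size_factors(spike_counts: pd.DataFrame,
                         mixing_ratios: Mapping[str, float]) -> dict[str, float]:
    """Median-of-ratios size factors from spike-in control-interval counts.

    Each sample's spike counts are first divided by
    ``mixing_ratio_sample / mean(mixing_ratio over the group)`` so that
    sample-to-sample variation in the realized cell admixture does not
    masquerade as a sequencing-depth difference.  Size factors are then the
    per-sample median of count / per-feature geometric mean, computed over
    features whose counts are positive in every sample.

    Parameters
    ----------
    spike_counts : DataFrame
        Control intervals (rows) x samples (columns), raw spike-in counts.
    mixing_ratios : mapping sample_id -> realized spike:target ratio.
    """
    if spike_counts.shape[1] < 2:
        raise CalibrationError("size factors require at least two samples")
    missing = [s for s in spike_counts.columns if s not in mixing_ratios]
    if missing:
        raise CalibrationError(f"no mixing ratio for samples: {missing}")
    ratios = np.array([mixing_ratios[s] for s in spike_counts.columns], float)
    if np.any(ratios <= 0):
        raise CalibrationError("all mixing ratios must be positive")
    pre = spike_counts.to_numpy(float) / (ratios / ratios.mean())

    with np.errstate(divide="ignore"):
        logs = np.log(pre)
    all_positive = np.all(np.isfinite(logs), axis=1)
    if not np.any(all_positive):
        raise CalibrationError(
            "no control interval has positive counts in every sample"
        )
    log_geomean = logs[all_positive].mean(axis=1)
    log_ratios = logs[all_positive] - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return dict(zip(spike_counts.columns, factors))
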