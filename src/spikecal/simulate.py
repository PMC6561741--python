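"""Synthetic two-genome spike-in experiments with recorded ground truth.

The generator emulates the statistical structure of calibrated ChIP-seq and
nuclear RNA-seq in a two-genome design: a target genome carrying the signal
of interest mixed with a fixed quota of spike-in cells, matched Input (or
genomic-DNA) control libraries measuring the realized admixture, replicate
triplicates, and genotype scenarios acting on the signal.

The histone-mark model has two pools: a low, uniform "blanket" of expected
fragment intensity across the whole target genome, plus an additive punctate
component at a set of non-overlapping binding-site peaks.  A ``Scenario``
scales the two pools independently (``blanket_scale`` for uniform
genome-wide depletion, ``peak_scale`` for site-specific depletion applied to
a configurable fraction of peaks), mirroring the distinct depletion modes of
the enzyme sub-complexes that deposit each pool.

Counts are negative binomial with variance mu + phi * mu**2, drawn at
interval resolution (fragments per peak/tile); fragment midpoints can be
expanded from interval counts when positional tests need them.  Spike-in
expected counts depend only on the realized mixing ratio and library depth,
never on the scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import SampleLibrary

DEFAULT_CHROM_SIZES = {"chr1": 30_000_000, "chr2": 20_000_000, "chr3": 10_000_000}


@dataclass
class SimConfig:
    """Study conditions for a simulated spike-in ChIP experiment.

    Defaults follow the emulated assay: a spike-in : target cell ratio of 0.4
    (2e7 spike-in cells per 5e7 target cells) with 5% replicate-to-replicate
    jitter, biological triplicates, ~2e6 fragments per library, NB dispersion
    0.05, and a mark carried by 10% of nucleosomes in untreated cells.
    """

    target_chrom_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    spikein_total_features: int = 500
    n_peaks: int = 300
    peak_width: int = 100
    peak_enrichment: float = 40.0   # punctate component, median fold over blanket
    peak_enrichment_spread: float = 1.0  # lognormal sigma of per-peak strength
    blanket_rate: float | None = None  # expected fragments/kb untreated; None -> from depth
    global_mark_fraction: float = 0.10
    mixing_ratio: float = 0.4
    mixing_jitter_cv: float = 0.05
    dispersion: float = 0.05
    n_replicates: int = 3
    library_depth: int = 2_000_000
    seed: int = 0
    # generator plumbing (not part of the assay design)
    spike_share: float = 0.25   # expected spike fraction of an untreated library
    tile_width: int = 1_000     # background interval resolution, bp

    def __post_init__(self) -> None:
        if not self.target_chrom_sizes:
            raise ValueError("target_chrom_sizes must be non-empty")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not (0 < self.global_mark_fraction < 1):
            raise ValueError("global_mark_fraction must lie in (0, 1)")
        for name in ("peak_enrichment", "mixing_ratio", "dispersion",
                     "spike_share"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mixing_ratio <= 0:
            raise ValueError("mixing_ratio must be > 0")
        total_peak_bp = self.n_peaks * self.peak_width
        for chrom, size in self.target_chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"{chrom}: length must be > 0")
        if total_peak_bp >= self.genome_size:
            raise ValueError("peaks exceed the genome")

    @property
    def genome_size(self) -> int:
        return int(sum(self.target_chrom_sizes.values()))

    def resolved_blanket_rate(self) -> float:
        """Expected untreated blanket fragments per kb of target genome."""
        if self.blanket_rate is not None:
            return self.blanket_rate
        mass = self.genome_size + (peak_enrichments(self).sum()
                                   * self.peak_width)
        target_total = self.library_depth * (1 - self.spike_share)
        return 1000.0 * target_total / mass


@dataclass
class Scenario:
    """Multiplicative genotype effect on the two signal pools."""

    name: str = "null"
    blanket_scale: float = 1.0
    peak_scale: float = 1.0
    affected_peak_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.blanket_scale < 0 or self.peak_scale < 0:
            raise ValueError("scenario scales must be >= 0")
        if not (0 <= self.affected_peak_fraction <= 1):
            raise ValueError("affected_peak_fraction must lie in [0, 1]")


@dataclass
class RnaScenario:
    """Per-gene-class expression fold changes in the treated condition."""

    name: str = "null"
    class_fold: dict = field(default_factory=dict)

    def fold(self, gene_class: str) -> float:
        return float(self.class_fold.get(gene_class, 1.0))


@dataclass
class SimTruth:
    """Ground-truth ledger recorded before counts are drawn."""

    scenario: dict
    per_sample_mixing: dict
    per_peak_effect: list = field(default_factory=list)
    silencing_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


@dataclass
class ChipSimResult:
    libraries: list
    counts: pd.DataFrame        # intervals + one count column per sample
    spike_counts: pd.DataFrame  # spike features x samples
    input_counts: pd.DataFrame  # intervals + per-sample Input target counts
    truth: SimTruth
    config: SimConfig
    scenario: Scenario

    @property
    def sample_ids(self) -> list:
        return [lib.sample_id for lib in self.libraries]

    def intervals(self) -> pd.DataFrame:
        return self.counts[["chrom", "start", "end", "is_peak", "peak_id"]]


def nb_counts(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """NB(mu, phi) draws with variance mu + phi * mu**2 (gamma-Poisson)."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def _lognormal_jitter(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-1 multiplicative lognormal jitter with the given CV."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=n)


def _place_peaks(rng: np.random.Generator, chrom_sizes: Mapping[str, int],
                 n_peaks: int, width: int) -> pd.DataFrame:
    """Non-overlapping peaks, allocated to chromosomes by length."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], float)
    alloc = np.floor(n_peaks * sizes / sizes.sum()).astype(int)
    for i in np.argsort(-sizes):
        if alloc.sum() >= n_peaks:
            break
        alloc[i] += n_peaks - alloc.sum()
    rows = []
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        L = chrom_sizes[chrom]
        if k * width >= L:
            raise ValueError(f"{chrom}: {k} peaks of {width} bp exceed bounds")
        slack = L - k * width
        offsets = np.sort(rng.integers(0, slack, size=k))
        starts = offsets + np.arange(k) * width
        for s in starts:
            rows.append((chrom, int(s), int(s + width)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["peak_id"] = np.arange(len(df))
    return df


def build_intervals(config: SimConfig) -> pd.DataFrame:
    """Peak + background-tile partition of the target genome.

    Deterministic given ``config.seed``: peak placement consumes its own
    seed stream so that count draws do not perturb the geometry.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    peaks = _place_peaks(rng, config.target_chrom_sizes, config.n_peaks,
                         config.peak_width)
    rows = []
    for chrom, size in config.target_chrom_sizes.items():
        sub = peaks[peaks["chrom"] == chrom]
        edges = [0]
        for _, p in sub.sort_values("start").iterrows():
            edges.extend([p["start"], p["end"]])
        edges.append(size)
        for lo, hi in zip(edges[0::2], edges[1::2]):
            pos = lo
            while pos < hi:
                nxt = min(pos + config.tile_width, hi)
                rows.append((chrom, pos, nxt, False, -1))
                pos = nxt
    tiles = pd.DataFrame(rows, columns=["chrom", "start", "end", "is_peak",
                                        "peak_id"])
    peaks = peaks.assign(is_peak=True)[["chrom", "start", "end", "is_peak",
                                        "peak_id"]]
    out = pd.concat([peaks, tiles], ignore_index=True)
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def peak_enrichments(config: SimConfig) -> np.ndarray:
    """Per-peak punctate strength, lognormal with median peak_enrichment.

    Binding-site strengths span orders of magnitude in real profiles;
    deterministic given the config seed so geometry, expectations and draws
    agree.
    """
    if config.peak_enrichment_spread <= 0:
        return np.full(config.n_peaks, config.peak_enrichment)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    return config.peak_enrichment * rng.lognormal(
        0.0, config.peak_enrichment_spread, size=config.n_peaks)


def expected_interval_means(config: SimConfig, scenario: Scenario,
                            per_peak_effect: np.ndarray | None = None
                            ) -> pd.DataFrame:
    """Expected target fragment counts per interval for both conditions.

    The untreated intensity per bp is ``b`` outside peaks and
    ``b * (1 + e_i)`` inside peak ``i`` (``e_i`` the per-peak punctate
    strength), with ``b`` set by the blanket rate.  Treated intensity scales
    the blanket term by ``blanket_scale`` and the punctate term by the
    realized per-peak effect.
    """
    intervals = build_intervals(config)
    if per_peak_effect is None:
        per_peak_effect = _peak_effects(config, scenario)
    enrich = peak_enrichments(config)
    b = config.resolved_blanket_rate() / 1000.0   # fragments per bp
    length = (intervals["end"] - intervals["start"]).to_numpy(float)
    peak_term = np.zeros(len(intervals))
    mask = intervals["is_peak"].to_numpy()
    pid = intervals.loc[mask, "peak_id"].to_numpy()
    peak_term[mask] = enrich[pid]
    unt = b * length * (1.0 + peak_term)
    trt = b * length * scenario.blanket_scale
    trt_peak = b * length[mask] * (scenario.blanket_scale
                                   + enrich[pid] * per_peak_effect[pid])
    trt[np.flatnonzero(mask)] = trt_peak
    out = intervals.copy()
    out["untreated_mean"] = unt
    out["treated_mean"] = trt
    return out


def _peak_effects(config: SimConfig, scenario: Scenario) -> np.ndarray:
    """Realized per-peak punctate fold changes (deterministic given seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    effects = np.ones(config.n_peaks)
    n_aff = int(round(scenario.affected_peak_fraction * config.n_peaks))
    affected = rng.choice(config.n_peaks, size=n_aff, replace=False)
    effects[affected] = scenario.peak_scale
    return effects


def simulate_chip_experiment(config: SimConfig,
                             scenario: Scenario) -> ChipSimResult:
    """Two-condition replicate spike-in ChIP experiment with ground truth.

    For each condition (untreated, treated) and replicate the generator
    draws: NB target fragment counts per interval under the two-pool model,
    NB spike-in counts per spike feature with expectation proportional to the
    realized mixing ratio (scenario-free), and a matched Input library whose
    target and spike components reflect genome composition and mixing only
    (no peak enrichment).  The truth ledger records the scenario, realized
    mixing ratios, and per-peak effects before any counts are drawn.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(4)[2])

    per_peak_effect = _peak_effects(config, scenario)
    means = expected_interval_means(config, scenario, per_peak_effect)
    conditions = ["untreated", "treated"]
    sample_ids = [f"{cond}_rep{r + 1}" for cond in conditions
                  for r in range(config.n_replicates)]
    jitter = _lognormal_jitter(rng, len(sample_ids), config.mixing_jitter_cv)
    mixing = {sid: config.mixing_ratio * j for sid, j in zip(sample_ids, jitter)}

    truth = SimTruth(
        scenario=asdict(scenario),
        per_sample_mixing=dict(mixing),
        per_peak_effect=per_peak_effect.tolist(),
    )

    counts = means[["chrom", "start", "end", "is_peak", "peak_id"]].copy()
    input_counts = counts.copy()
    spike_counts = pd.DataFrame(
        index=pd.RangeIndex(config.spikein_total_features, name="spike_feature"))
    length = (counts["end"] - counts["start"]).to_numpy(float)

    libraries = []
    spike_total = config.library_depth * config.spike_share
    for sid in sample_ids:
        cond = sid.rsplit("_", 1)[0]
        mu_target = means[f"{cond}_mean"].to_numpy()
        counts[sid] = nb_counts(rng, mu_target, config.dispersion)

        rel_mix = mixing[sid] / config.mixing_ratio
        mu_spike = np.full(config.spikein_total_features,
                           spike_total * rel_mix / config.spikein_total_features)
        spike_counts[sid] = nb_counts(rng, mu_spike, config.dispersion)

        # matched Input: composition + mixing only, uniform over the genome
        m = mixing[sid]
        input_target_mu = (config.library_depth / (1 + m)
                           * length / config.genome_size)
        input_counts[sid] = nb_counts(rng, input_target_mu, config.dispersion)
        input_spike_mu = np.full(
            config.spikein_total_features,
            config.library_depth * m / (1 + m) / config.spikein_total_features)
        input_spike = nb_counts(rng, input_spike_mu, config.dispersion)

        libraries.append(SampleLibrary(
            sample_id=sid, assay="chip", condition=cond,
            replicate=int(sid.rsplit("rep", 1)[1]),
            n_target=int(counts[sid].sum()),
            n_spike=int(spike_counts[sid].sum()),
            control_n_target=int(input_counts[sid].sum()),
            control_n_spike=int(input_spike.sum()),
            control_kind="input",
        ))
    return ChipSimResult(libraries=libraries, counts=counts,
                         spike_counts=spike_counts, input_counts=input_counts,
                         truth=truth, config=config, scenario=scenario)


def fragment_midpoints(interval_counts: pd.DataFrame, sample: str,
                       seed: int = 0) -> pd.DataFrame:
    """Expand per-interval counts into uniform fragment midpoints.

    Midpoints are drawn uniformly within each interval, so window counting at
    any resolution coarser than or aligned with the intervals reproduces the
    interval totals in expectation (exactly, for aligned partitions).
    """
    rng = np.random.default_rng(seed)
    n = interval_counts[sample].to_numpy(np.int64)
    starts = np.repeat(interval_counts["start"].to_numpy(np.int64), n)
    ends = np.repeat(interval_counts["end"].to_numpy(np.int64), n)
    chroms = np.repeat(interval_counts["chrom"].to_numpy(), n)
    pos = rng.integers(starts, ends)
    return pd.DataFrame({"chrom": chroms, "pos": pos})


# ---------------------------------------------------------------------------
# RNA


def make_gene_table(n_genes: int = 2_000, pcg_fraction: float = 0.25,
                    mean_expression: float = 100.0, seed: int = 0,
                    chrom_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Synthetic gene annotation with Polycomb-target / other classes."""
    if n_genes <= 0:
        raise ValueError("empty gene set")
    rng = np.random.default_rng(seed)
    chrom_sizes = chrom_sizes or DEFAULT_CHROM_SIZES
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], float)
    which = rng.choice(len(chroms), size=n_genes, p=sizes / sizes.sum())
    tss = rng.integers(0, sizes[which].astype(np.int64))
    cls = np.where(rng.random(n_genes) < pcg_fraction, "PcG_target", "other")
    baseline = rng.lognormal(np.log(mean_expression), 1.0, size=n_genes)
    return pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "chrom": [chroms[i] for i in which],
        "tss": tss,
        "strand": rng.choice(["+", "-"], size=n_genes),
        "gene_class": cls,
        "baseline": baseline,
    })


@dataclass
class RnaSimResult:
    libraries: list
    counts: pd.DataFrame        # genes x samples (gene_id index)
    spike_counts: pd.DataFrame  # spike genes x samples
    genes: pd.DataFrame
    truth: SimTruth


def simulate_rna_experiment(genes: pd.DataFrame, scenario: RnaScenario,
                            n_replicates: int = 3, depth: int = 2_000_000,
                            n_spike_genes: int = 300, dispersion: float = 0.05,
                            mixing_ratio: float = 0.4,
                            mixing_jitter_cv: float = 0.05,
                            spike_share: float = 0.25,
                            seed: int = 0) -> RnaSimResult:
    """Calibrated nuclear RNA-seq emulation with genomic-DNA controls.

    Treated-condition genes of each class are scaled by the scenario's
    class fold; spike-in gene expectations are invariant to the scenario and
    proportional to the realized per-sample mixing ratio.  A sheared
    genomic-DNA control pair is emitted per sample so the realized mixing
    ratio can be recovered downstream.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[3])
    baseline = genes["baseline"].to_numpy(float)
    scale = depth * (1 - spike_share) / baseline.sum()
    mu_unt = baseline * scale
    fold = np.array([scenario.fold(c) for c in genes["gene_class"]])
    mu_trt = mu_unt * fold

    spike_baseline = rng.lognormal(np.log(depth * spike_share / n_spike_genes),
                                   1.0, size=n_spike_genes)
    spike_baseline *= depth * spike_share / spike_baseline.sum()

    conditions = ["untreated", "treated"]
    sample_ids = [f"{cond}_rep{r + 1}" for cond in conditions
                  for r in range(n_replicates)]
    jitter = _lognormal_jitter(rng, len(sample_ids), mixing_jitter_cv)
    mixing = {sid: mixing_ratio * j for sid, j in zip(sample_ids, jitter)}
    truth = SimTruth(scenario={"name": scenario.name,
                               "class_fold": dict(scenario.class_fold)},
                     per_sample_mixing=dict(mixing))

    counts = pd.DataFrame(index=pd.Index(genes["gene_id"], name="gene_id"))
    spike_counts = pd.DataFrame(
        index=pd.Index([f"spike{i:04d}" for i in range(n_spike_genes)],
                       name="gene_id"))
    libraries = []
    control_depth = depth
    for sid in sample_ids:
        cond = sid.rsplit("_", 1)[0]
        mu = mu_trt if cond == "treated" else mu_unt
        counts[sid] = nb_counts(rng, mu, dispersion)
        rel_mix = mixing[sid] / mixing_ratio
        spike_counts[sid] = nb_counts(rng, spike_baseline * rel_mix, dispersion)
        m = mixing[sid]
        ctrl_target = int(rng.poisson(control_depth / (1 + m)))
        ctrl_spike = int(rng.poisson(control_depth * m / (1 + m)))
        libraries.append(SampleLibrary(
            sample_id=sid, assay="rna", condition=cond,
            replicate=int(sid.rsplit("rep", 1)[1]),
            n_target=int(counts[sid].sum()),
            n_spike=int(spike_counts[sid].sum()),
            control_n_target=ctrl_target, control_n_spike=ctrl_spike,
            control_kind="genomic_dna",
        ))
    return RnaSimResult(libraries=libraries, counts=counts,
                        spike_counts=spike_counts, genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# peak-call and domain-profile stand-ins


def simulate_peak_calls(true_peaks: pd.DataFrame, n_replicates: int,
                        jitter_bp: int, fdr_extra_peaks: int,
                        chrom_sizes: Mapping[str, int],
                        seed: int = 0) -> list:
    """Per-replicate peak sets: truth with boundary jitter plus false peaks."""
    if jitter_bp < 0:
        raise ValueError("jitter_bp must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], float)
    width = int(np.median(true_peaks["end"] - true_peaks["start"])) \
        if len(true_peaks) else 1000
    out = []
    for _ in range(n_replicates):
        rep = true_peaks[["chrom", "start", "end"]].copy()
        if jitter_bp > 0 and len(rep):
            rep["start"] = rep["start"] + rng.integers(-jitter_bp, jitter_bp + 1,
                                                       len(rep))
            rep["end"] = rep["end"] + rng.integers(-jitter_bp, jitter_bp + 1,
                                                   len(rep))
            lims = rep["chrom"].map(chrom_sizes).to_numpy()
            rep["start"] = np.clip(rep["start"], 0, lims - 1)
            rep["end"] = np.clip(rep["end"], rep["start"] + 1, lims)
        extras = []
        for _ in range(fdr_extra_peaks):
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            s = int(rng.integers(0, chrom_sizes[chroms[ci]] - width))
            extras.append((chroms[ci], s, s + width))
        if extras:
            rep = pd.concat([rep, pd.DataFrame(extras, columns=["chrom",
                                                                "start", "end"])],
                            ignore_index=True)
        out.append(rep.sort_values(["chrom", "start"]).reset_index(drop=True))
    return out


def simulate_domain_profiles(n_peaks: int = 300, n_bins: int = 20,
                             separation: float = 5.0, seed: int = 0,
                             weights: Sequence[float] = (0.35, 0.35, 0.30)):
    """Planted three-cluster binding profiles around peak centers.

    Two clusters carry high combined PRC1 + PRC2 signal at different levels,
    one is low; cluster means are separated by ``separation`` noise SDs per
    bin.  Returns ``(ring_mat, suz_mat, labels, high_mask)`` where
    ``high_mask`` marks rows belonging to the two high-signal clusters.
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n_peaks, p=np.asarray(weights) / sum(weights))
    x = np.linspace(-1, 1, n_bins)
    bump = np.exp(-(x ** 2) / 0.18)
    amps = np.array([2.0, 1.0, 0.0]) * separation   # noise sd = 1 per bin
    ring = amps[labels][:, None] * bump[None, :] + rng.normal(0, 1,
                                                              (n_peaks, n_bins))
    suz = amps[labels][:, None] * 0.8 * bump[None, :] + rng.normal(
        0, 1, (n_peaks, n_bins))
    return ring, suz, labels, labels < 2


# ---------------------------------------------------------------------------
# allele-specific silencing


@dataclass
class AllelicSimResult:
    genes: pd.DataFrame         # gene_id, tss, distance, silencing_factor
    expr_counts: pd.DataFrame   # per gene: allele{1,2}_{pre,post}
    mark_reads: pd.DataFrame    # read_id, chrom, pos, true_allele
    snp_obs: pd.DataFrame       # read_id, position, call
    truth: SimTruth


def silencing_factor(distance, max_silencing: float,
                     decay_length: float) -> np.ndarray:
    """Residual expression fraction s(d) = 1 - max_silencing * exp(-d / decay)."""
    if decay_length <= 0:
        raise ValueError("decay_length must be > 0")
    return 1.0 - max_silencing * np.exp(-np.asarray(distance, float)
                                        / decay_length)


def simulate_allelic_silencing(chrom_length: int = 100_000_000,
                               n_genes: int = 200,
                               integration_position: int = 50_000_000,
                               max_silencing: float = 0.9,
                               decay_length: float = 20_000_000,
                               mean_reads_per_gene: float = 2000.0,
                               snp_density: float = 0.005,
                               snp_error_rate: float = 0.002,
                               read_length: int = 80,
                               n_mark_reads: int = 100_000,
                               mark_gain: float = 8.0,
                               dispersion: float = 0.001,
                               seed: int = 0) -> AllelicSimResult:
    """Two-haplotype chromosome with distance-decaying silencing.

    After induction from the integration site, the silenced allele's
    expression is multiplied by ``s(d) = 1 - max_silencing * exp(-d/decay)``
    at distance ``d`` from the site, and its histone-mark density is raised
    complementarily (gain proportional to the local silencing strength).
    Mark reads carry zero or more haplotype-informative SNP observations
    (Poisson with ``snp_density * read_length`` expected per read), each
    reporting the true allele except for a configurable error rate.

    Default depth and dispersion reflect the allele-specific regime of the
    emulated assay: allelic libraries are sequenced deep (to maximize
    SNP-overlapping reads) and the pre/post comparison is between merged
    libraries of one cell line, so residual overdispersion is small.
    """
    if not (0 <= max_silencing <= 1):
        raise ValueError("max_silencing must lie in [0, 1]")
    if not (0 < integration_position < chrom_length):
        raise ValueError("integration_position must lie within the chromosome")
    rng = np.random.default_rng(seed)

    tss = np.sort(rng.integers(0, chrom_length, size=n_genes))
    distance = np.abs(tss - integration_position)
    s = silencing_factor(distance, max_silencing, decay_length)
    baseline = rng.lognormal(np.log(mean_reads_per_gene), 0.6, size=n_genes)

    genes = pd.DataFrame({
        "gene_id": [f"gene{i:04d}" for i in range(n_genes)],
        "chrom": "chrX",
        "tss": tss,
        "distance": distance,
        "silencing_factor": s,
    })
    expr = pd.DataFrame(index=pd.Index(genes["gene_id"], name="gene_id"))
    expr["allele1_pre"] = nb_counts(rng, baseline / 2, dispersion)
    expr["allele2_pre"] = nb_counts(rng, baseline / 2, dispersion)
    expr["allele1_post"] = nb_counts(rng, baseline / 2, dispersion)
    expr["allele2_post"] = nb_counts(rng, baseline / 2 * s, dispersion)

    truth = SimTruth(
        scenario={"name": "xist_induction"},
        per_sample_mixing={},
        silencing_params={
            "integration_position": int(integration_position),
            "max_silencing": float(max_silencing),
            "decay_length": float(decay_length),
            "mark_gain": float(mark_gain),
        },
    )

    # mark reads: allele1 blanket-only; allele2 blanket + induced gain.
    # Reads are split between alleles in proportion to total mark mass, so
    # the silenced allele gains coverage rather than redistributing it.
    grid = np.linspace(0, chrom_length, 4097)
    mids = (grid[:-1] + grid[1:]) / 2
    w = 1.0 + mark_gain * max_silencing * np.exp(
        -np.abs(mids - integration_position) / decay_length)
    n2 = int(round(n_mark_reads * w.mean() / (1.0 + w.mean())))
    n1 = n_mark_reads - n2
    pos1 = rng.integers(0, chrom_length, size=n1)
    cell = rng.choice(len(mids), size=n2, p=w / w.sum())
    pos2 = rng.integers(grid[cell].astype(np.int64),
                        grid[cell + 1].astype(np.int64))
    reads = pd.DataFrame({
        "read_id": np.arange(n_mark_reads),
        "chrom": "chrX",
        "pos": np.concatenate([pos1, pos2]),
        "true_allele": np.array(["allele1"] * n1 + ["allele2"] * n2),
    })

    k = rng.poisson(snp_density * read_length, size=n_mark_reads)
    read_idx = np.repeat(np.arange(n_mark_reads), k)
    obs_pos = (reads["pos"].to_numpy()[read_idx]
               + rng.integers(0, read_length, size=read_idx.size))
    call = reads["true_allele"].to_numpy()[read_idx].copy()
    u = rng.random(read_idx.size)
    other = np.where(call == "allele1", "allele2", "allele1")
    call = np.where(u < snp_error_rate / 2, other, call)
    call = np.where((u >= snp_error_rate / 2) & (u < snp_error_rate),
                    "other", call)
    snp_obs = pd.DataFrame({"read_id": read_idx, "position": obs_pos,
                            "call": call})
    return AllelicSimResult(genes=genes, expr_counts=expr, mark_reads=reads,
                            snp_obs=snp_obs, truth=truth)
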