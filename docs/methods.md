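# Methods

## The measurement problem

Per-library normalization (reads-per-million, total-count size factors)
expresses every sample on its own internal scale. If a perturbation changes
the measured quantity at most of the genome — erasing a pervasive histone
mark, derepressing thousands of genes — that internal scale shifts with the
signal, and the change is partly or wholly invisible after normalization.
Spike-in calibration fixes this by adding a constant quota of
foreign-genome cells to each sample before processing: the foreign genome's
read share is an internal standard unaffected by the perturbation, so
cross-condition comparisons can be made on an absolute per-cell scale.

## Calibration model

For sample *i* with spike-in read total N<sub>s,i</sub> and a matched
control library (Input chromatin; sheared genomic DNA for RNA assays) with
spike-in and target totals N<sup>c</sup><sub>s,i</sub>,
N<sup>c</sup><sub>t,i</sub>:

    raw_i    = (1 / N_s,i) · (N^c_s,i / N^c_t,i)
    scaled_i = α · raw_i,     α = 1 / max_j raw_j

The control ratio corrects sample-to-sample variation in the realized
cell-mixing ratio; α puts the jointly normalized group on a common scale on
which the least spike-rich library keeps all of its reads
(max scaled factor = 1, exact by construction) and every other library is
down-sampled. The group over which α is shared is whatever set of libraries
is passed to one `calibrate_group` call — in the intended design, all
samples of one antibody/assay in one cell line.

Calibration of counts supports two modes. `expected` multiplies counts by
the scaled factor (real-valued, deterministic; the default everywhere).
`subsample` draws Binomial(count, factor) per interval, which has exactly
the distribution of per-interval totals under random read subsampling — the
alignment-level operation it replaces — and is retained for track emulation.
Equality of the two in expectation is asserted by test.

For differential testing, per-sample size factors come from spike-in counts
over a control interval set by median-of-ratios (per-feature geometric mean
over features positive in all samples; per-sample median of count/geomean),
after dividing each sample's spike counts by
(mixing ratio / group-mean mixing ratio). Any common pre-normalization
constant cancels in median-of-ratios; the group mean is used for
interpretability.

## Synthetic data generator

The generator emulates the statistical structure of a two-genome calibrated
experiment, not its sequences. Counts are drawn at interval resolution
(fragments per peak or background tile) as negative binomial with
variance μ + φμ²; fragment midpoints are expanded from interval counts when
positional operations need them, uniformly within each interval.

**Two-pool signal model.** Untreated target intensity per bp is *b* outside
peaks and *b*(1 + e<sub>i</sub>) inside peak *i*: a uniform blanket plus an
additive punctate component. A scenario scales the blanket term
(`blanket_scale`) and the punctate term (`peak_scale`, applied to a
configurable fraction of peaks) independently — the additive form is what
lets a uniform genome-wide depletion leave punctate enrichment intact, the
defining behaviour of the two pools. Per-peak strengths e<sub>i</sub> are
lognormal (median = `peak_enrichment`, σ = `peak_enrichment_spread`),
since real binding-site strengths span orders of magnitude and
replicate-concordance statistics are meaningless over flat signal.

**Spike-in and controls.** Expected spike-in counts are
depth × share × (realized mixing / nominal mixing), independent of the
scenario by construction — the spike-in cells' chromatin is untouched by
the perturbation. Target totals shrink under depletion scenarios, as ChIP
yield does. Matched Input libraries sample target and spike genomes in
proportion to composition and mixing only (no peak enrichment), so the
control spike:target ratio estimates the realized mixing ratio. Mixing
jitter is mean-1 lognormal with configurable CV.

**Defaults as study conditions.** 60 Mb target genome over three
chromosomes; 300 peaks × 100 bp at median 40-fold punctate enrichment
(σ = 1); spike-in:target mixing 0.4 (the 2×10⁷ : 5×10⁷ cell design)
with 5% CV; φ = 0.05; triplicates; ~2×10⁶ fragments per library; 10% of
nucleosomes marked in untreated cells. The peak geometry keeps punctate
signal mass near 3% of the genome-wide total, so naive total-count
normalization reports a uniform 5-fold blanket loss as a ratio near 0.9 —
the masking artifact calibration exists to expose — while per-peak depth
(~300 merged fragments) keeps the punctate medians stable. The allelic
generator defaults to deeper per-gene counts (2,000) and lower
overdispersion (φ = 0.001): allele-informative libraries are sequenced
deep precisely to capture SNP-overlapping reads, and the pre/post-induction
comparison is within one cell line.

**What the generator does not model.** Sequence composition, mappability
and GC bias, fragment-length distributions, duplicate reads, peak shape
within binding sites, trans effects between loci, or biological replicate
heterogeneity beyond NB dispersion and mixing jitter. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to real-data artifacts upstream of
counting.

## Interval arithmetic

Coordinates are 0-based, half-open; BED I/O is native. Fragments are
assigned to at most one interval by midpoint containment (boundary midpoint
belongs to the right-hand window), which conserves totals over genome
partitions. Consensus across replicate peak sets union-merges all peaks
into candidates and keeps a candidate iff it overlaps ≥ 1 bp with at least
one peak from every input set; blacklist and retained-signal filters remove
whole peaks on ≥ 1 bp overlap. The ≥ 1 bp criterion and merged-union
consensus coordinates are design choices (matching default
interval-intersection semantics of the standard toolchain); all four
operations are verified against a brute-force all-pairs oracle on random
instances. Metaprofiles are scaled by one constant per dataset so the
untreated center-bin density is 1; treated samples share the constant, so
treated/untreated ratios are preserved. Centers closer than one flank to a
chromosome edge are excluded and counted.

## Domain and gene classification

k-means (k = 3, scikit-learn, k-means++ with 50 restarts, fixed seed) over
the concatenated per-bin PRC1 and PRC2 profiles, standardized per column
(clustering should not be dominated by the bins with the largest absolute
signal; the original analysis does not state its scaling). Clusters are
ranked by mean combined raw signal and the top two merged into the
classical-domain set — an automated version of what is otherwise a visual
identification. Identical-row input is rejected as degenerate.

Gene tri-partition: PcG-occupied iff the [TSS − 2500, TSS + 2500) window
overlaps both a PRC1 and a PRC2 peak; else non-PcG-NMI iff it overlaps a
non-methylated CpG island; else non-NMI. The half-open window makes the
partition exhaustive and disjoint by construction; strand is ignored
(symmetric windows). Sensitivity classes are chained exclusions of the
significant-up sets from progressively larger knockout combinations,
pairwise disjoint by construction.

The two-pool summary converts peak-level and 100-kb-window matrices to
per-kb densities and divides both by the untreated punctate median, so the
untreated punctate median is exactly 1 and both pools share a scale.

## Differential testing

A simplified NB Wald test stands in for a full GLM fit: the acceptance
bar is parameter recovery and error control on synthetic data, not
numerical identity with any particular implementation. Per feature,
dispersion is estimated by method of moments on size-factor-normalized
counts pooled within condition, φ̂ = max(φ_floor, (s² − m̄)/m̄²) combined
across conditions by residual degrees of freedom, then shrunk toward the
across-feature median with 5 pseudo-degrees of freedom. With triplicates
the raw moment estimator is wildly variable and truncates at the floor
whenever s² < m̄; the moderation is what keeps the Wald p-values calibrated
(null discovery fraction ≪ 0.05 at adj. p < 0.05 in the suite).
log2FC = log2((m̄_t + c)/(m̄_u + c)) with pseudocount c = 0.5 normalized
counts; SE from the delta method, var(m̄) = (m̄ + φm̄²)/n per condition;
two-sided normal p; Benjamini–Hochberg adjustment over tested features
(all-zero features are excluded and reported NA). Thresholds: adj. p < 0.05
(ChIP mode); additionally fold change > 1.5 (RNA mode). The test is exactly
antisymmetric under condition-label swap, and invariant to scaling one
sample's counts and size factor together.

## Allele-specific quantitation

Read assignment consumes abstract SNP observations (the step downstream of
N-masked alignment and read splitting): unanimous observations give the
allele, none give `unassigned`, any disagreement or non-allelic base gives
`conflicting`; conflicting reads are excluded from per-allele totals and
reported in a QC counter. Silencing follows
s(d) = 1 − max_silencing·exp(−d/decay_length) on the silenced allele's
expression at distance d from the integration site, with mark density
raised complementarily (gain ∝ exp(−d/decay)); the exponential form is a
simulator choice recorded in the truth ledger (the motivating observation
is only that silencing scales with distance). The gradient statistic is
Spearman ρ(|log2FC|, distance) over genes, with the active allele anchoring
per-gene log2FC (post/pre ratio of silenced/active, cancelling per-phase
depth); ρ is negative under a genuine gradient and the sign convention is
recorded in the output. Fewer than 10 finite genes is refused.

## Replicate QC

Pairwise Pearson on log2(x + 1) per-interval signal over regions of
interest (the log transform is a package choice; the threshold, default
0.9, is configurable). A group passes iff the minimum pairwise r exceeds
the threshold; zero-variance samples fail with an explicit message rather
than propagating undefined correlations. Merging is elementwise summation
and refuses failed groups without an explicit override. Expected-mode
calibration commutes with merging when the calibration inputs are likewise
summed; this identity is asserted by test.

## Numerical and degenerate-input conventions

Seeds are mandatory for every stochastic operation; independent seed
streams separate geometry (peak placement, per-peak strengths) from count
draws so expectations and draws agree. NB draws use the gamma–Poisson
construction (exact for non-integer 1/φ, Poisson at φ = 0). α-scaling pins
the argmax sample to exactly 1.0 against round-off. Zero control spike
totals warn at ratio estimation and error at calibration; zero untreated
medians, empty gene sets, empty groups, and factor values outside (0, 1]
raise named errors.

## Problem sizes

Simulated experiments use the 60 Mb / 2×10⁶-fragment design above
(~60,000 intervals × 12 libraries per scenario, a few seconds each);
differential checks use 5,000 null features and 100–800 planted features;
oracle equivalence uses 100 random instances of ≤ 10³ intervals; the
allelic run uses 200 genes and 10⁵ mark reads. These sizes are the
package's chosen study conditions: large enough that the stated recovery
and error-control properties are sharp, small enough that the full suite
runs in well under a minute of simulation time per module.

## Known limitations

The Wald test has no dispersion trend fitting, outlier handling, or LFC
shrinkage; at very low counts its p-values lean on the pseudocount. The
consensus operation returns merged-union coordinates (not intersections).
Cross-antibody comparisons are out of scope — calibration is within
antibody/assay. Real-data peak and gene-class counts are not reproduced
here; they require the original sequencing data and genome annotation.
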