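# spikecal

Spike-in calibrated quantitation of ChIP-seq and nuclear RNA-seq, built for
the situation where a perturbation changes a chromatin mark or a
transcriptome *globally* — the regime in which conventional per-library
normalization silently erases the effect being measured.

The package targets the analysis pattern of quantitative Polycomb genomics
in mouse embryonic stem cells: H2AK119ub1 (the histone mark written by
PRC1) exists in two pools — punctate, high-level enrichment at
PRC1-bound sites, and a low, pervasive "blanket" across the genome — and
genetic removal of different PRC1 sub-complexes depletes the two pools
independently, globally, or chromosome-wide (during Xist-mediated
silencing). Every stage of that analysis is implemented and exercised
against a synthetic two-genome data generator with recorded ground truth,
so parameter recovery and error control are testable without any external
data.

## What it computes

**Spike-in calibration.** Each library carries a fixed admixture of
foreign-genome cells. With N<sub>s</sub> the sample's spike-in read total and
N<sup>c</sup><sub>s</sub>, N<sup>c</sup><sub>t</sub> the spike-in and target
totals of its matched Input (or genomic-DNA) control, the per-sample
downsampling factor is

```
factor_i = α · (1 / N_s,i) · (N^c_s,i / N^c_t,i)
```

with α one constant per jointly normalized group chosen so max<sub>i</sub>
factor<sub>i</sub> = 1. Calibrated counts are obtained either as expected
values (counts × factor) or by binomial thinning (the count-level equivalent
of random read subsampling).

**Two-pool decomposition.** Calibrated per-kb densities at binding-site
peaks (punctate pool) and in 100-kb genome windows (blanket pool), medians
anchored so the untreated punctate median is 1.

**Interval arithmetic.** Genome windows, midpoint counting,
consensus-across-replicates peak logic, blacklist and retained-signal
filtering (all ≥ 1 bp overlap, 0-based half-open), metaprofiles, 250-kb
chromosome density bins.

**Domain and gene classification.** k-means (k = 3) over ±10 kb PRC1 + PRC2
binding profiles, merging the two high-signal clusters into the classical
Polycomb chromatin-domain set; gene tri-partition (PcG-occupied / non-PcG
with a non-methylated CpG island / non-NMI) by ±2.5 kb promoter overlap;
PRC1-target selection and chained knockout-sensitivity classes.

**Differential testing.** Simplified negative-binomial Wald test
(method-of-moments dispersion with median moderation, delta-method standard
errors, Benjamini–Hochberg adjustment) with spike-in-anchored size factors:
median-of-ratios over spike-in control intervals after pre-normalizing each
sample by its realized mixing ratio. Significance: adj. p < 0.05 (ChIP),
additionally fold change > 1.5 (RNA).

**Allele-specific quantitation.** SNP-observation-based read assignment
(unanimous → allele, none → unassigned, disagreement → conflicting),
per-allele calibrated densities, and the silencing gradient: Spearman ρ
between per-gene repression magnitude |log2FC| and distance from the
silencing-RNA integration site.

## Worked example

```python
from spikecal import simulate as sim
from spikecal import workflows as wf

cfg = sim.SimConfig(seed=1)                      # 60 Mb genome, triplicates,
scen = sim.Scenario("blanket_loss",              # ~2e6 fragments/library
                    blanket_scale=0.2)           # uniform 5-fold mark loss
res = sim.simulate_chip_experiment(cfg, scen)

print(wf.genome_window_ratio(res, normalization="spike"))   # 0.20648
print(wf.genome_window_ratio(res, normalization="naive"))   # 0.90357
print(wf.two_pool_from_sim(res))
#    sample_id  punctate_median  blanket_median
# 0  untreated          1.00000        0.024205
# 1    treated          0.94976        0.004946
```

A planted uniform 5-fold genome-wide depletion is recovered by spike-in
calibration (median 100-kb-window ratio 0.206 ≈ 0.2) but reported as 0.904 —
essentially no change — by naive total-count normalization, because scaling
away library totals also scales away a uniform true change. The two-pool
summary shows the same run leaves the punctate pool intact (0.95 ≈ 1) while
the blanket drops 4.9-fold.

The numbered drivers under `analysis/` run the full study: scenario panel
generation, calibration recovery, two-pool dissociation, spike-anchored
differential expression (planted 4-fold derepression of Polycomb targets is
recovered at mean log2FC 2.04 with power 1.0, while naive size factors
shift unaffected genes by −0.92 log2 units), domain classification
(ARI 1.0 against planted clusters), and the allelic silencing gradient
(ρ = −0.89 over 200 genes; no-silencing control ρ = 0.17). Each writes its
tables under `results/`:

```
python analysis/01_simulate_experiments.py --seed 1
python analysis/02_calibration_recovery.py --seed 1
...
python analysis/06_allelic_silencing.py    --seed 1
```

A `spikecal` command-line interface exposes the pipeline stages
(`simulate`, `calibrate`, `quantify`, `domains`, `diff`, `allelic`, `qc`)
over TSV/BED/bedGraph/chrom.sizes interchange files with provenance
headers; `spikecal <cmd> --help` documents each.

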