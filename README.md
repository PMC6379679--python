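# selandscape

Super-enhancer-centric analysis of transcriptional dysregulation, built
around the regulatory genomics of Ewing sarcoma: H3K27ac-based
super-enhancer (SE) calling, consensus SE-gene nomination across
samples, SE-vs-typical-enhancer (TE) enrichment of transcription-factor
binding and GGAA microsatellites, direct-target and co-occupancy
statistics, and GSEA-style enrichment of SE-associated genes in
perturbation-response rankings. Every stage can be exercised
end-to-end on seeded synthetic data with planted ground truth.

It is intended for computational biologists who have peak calls (BED /
narrowPeak), coverage tracks (bedGraph), TF ChIP peak sets, a gene
annotation, a genome FASTA, and count matrices — i.e. everything
downstream of alignment and peak calling — and want a reproducible,
tested implementation of the SE-centric analysis chain.

## The method

**SE calling (ROSE-style).** Candidate peaks fully contained in
promoter windows (TSS ± 2.5 kb by default) are removed; survivors
within 12.5 kb of each other are stitched into enhancer units; each
unit is quantified as background-subtracted summed coverage
Σ(chip) − Σ(input), floored at 0. Units are ranked by signal; with
rank and signal both scaled to [0, 1] on the ascending curve
(x = rank, y = signal), the SE cutoff sits at

```
i* = argmax_i (x_i − y_i)
```

— the tangent-of-slope-1 point of the hockey-stick curve. Units with
signal strictly above the cutoff are super-enhancers. Genes are linked
to enhancers by body overlap or TSS proximity (± 50 kb default), and
consensus SE genes are those SE-assigned in ≥ `min_cell_lines`
cell-line samples **and** ≥ `min_tumors` tumor samples.

**SE/TE statistics.** Containment of TF peaks in SE vs TE regions is
tested by Pearson's chi-squared (df = 1, no continuity correction);
genome-wide co-localization of two TF peak sets by a two-sided Fisher
exact test over disjoint genome windows, reported with reciprocal
overlap fractions; GGAA microsatellites (maximal runs of ≥ 4 GGAA/TTCC
units) are scanned exactly and compared SE vs TE the same way. Direct
targets of a TF are genes bound (peak within TSS ± 50 kb or over the
body) and changed more than 2-fold (|log2FC| > 1) on knockdown.

**Response enrichment.** Per-gene log2 fold changes are computed from
CPM-normalized count matrices. A gene set S is scored against the
descending fold-change ranking with the weighted Kolmogorov–Smirnov
running sum: hits add `|fc|^p / Σ_hits |fc|^p`, misses subtract
`1/(N − N_hit)`; ES is the signed extremum, and significance comes
from a gene-set permutation null (NES = ES / mean |same-sign null ES|).

**Synthetic truth.** The `simulate` module plants: SE clusters of 3–8
peaks whose summed signal is `se_amplification` × the median background
unit (background signals log-normal, winsorized); TF peaks
preferentially in SE units; (GGAA)ₖ runs at higher Poisson rates in SE
sequence; and negative-binomial count matrices in which SE-assigned
genes carry stronger log2FC effects. Every generator is a pure
function of its config and seed.

## Worked example

```python
from selandscape.simulate import SimConfig, generate_landscape, \
    generate_tf_peaks, recovery_jaccard
from selandscape.landscape import build_landscape, LandscapeParams, assign_genes
from selandscape.tfstats import containment_chi2

cfg = SimConfig(seed=1, n_chromosomes=2, chrom_length=4_000_000,
                n_enhancer_peaks=400, n_planted_se=20, n_genes=300)
bundle = generate_landscape(cfg)
ls = build_landscape(bundle.peaks, bundle.chip, bundle.control,
                     bundle.genes, LandscapeParams(), sample_id="sim1")
print(f"{len(ls.enhancers)} stitched enhancers, "
      f"{len(ls.super_enhancers)} super (cutoff={ls.cutoff_signal:.0f})")
print(f"planted-SE recovery Jaccard: {recovery_jaccard(ls, bundle.truth):.2f}")

tf = generate_tf_peaks(cfg, bundle.truth)
res = containment_chi2([e.region for e in ls.super_enhancers],
                       [e.region for e in ls.typical_enhancers], tf)
print(f"TF containment: table={res.table}, chi2={res.statistic:.1f}, "
      f"p={res.p_value:.2e}, OR={res.odds_ratio:.1f}")
```

prints

```
400 stitched enhancers, 20 super (cutoff=1854)
planted-SE recovery Jaccard: 1.00
TF containment: table=((16, 4), (32, 348)), chi2=92.2, p=7.89e-22, OR=43.5
```

All 20 planted SE clusters are recovered exactly (Jaccard 1.0 between
called and planted SE sets), and the planted TF preference (80% of SE
units vs 10% of TE units hosting a peak) is detected by the
containment chi-squared with a large odds ratio.

## Command line

A `selandscape` console script wraps the library:

```bash
selandscape run-all --config config.yaml            # full pipeline + JSON report
selandscape simulate --config config.yaml           # emit a synthetic bundle
selandscape landscape|consensus|tf-overlap|repeats|enrich --config config.yaml
```

The YAML config carries input paths (or a `simulate:` block of
`SimConfig` overrides), a sample manifest with `cell_line`/`tumor`
classes, the landscape distances, and statistical parameters; every
output file header records the tool version and a config fingerprint,
and re-running with the same config and seed reproduces the report's
results hash bit-for-bit. Exit codes: 0 success, 2 validation error,
1 runtime error.

Per-sample outputs: ranked landscape TSV, SE/TE BED, hockey-stick data
table (x, y, cutoff), gene-assignment TSV; cohort outputs: SE
membership table, consensus gene list, contingency/overlap blocks and
enrichment results in `run_report.json`.

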