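# methylphase

Analysis of **mutation-specific DNA hypermethylation** from whole-genome
bisulfite sequencing (WGBS), built around the question posed by IDH-mutant
acute myeloid leukemia: which focal regions are hypermethylated in one
mutation-defined tumor group *and in no other*, where do they sit in the
regulatory genome, and which genes do they contact?

The package is aimed at computational epigenomics researchers who have
per-CpG methylation count tracks (biscuit-style bedGraphs), a sample sheet
grouping samples by mutation status, and standard annotation files (ChromHMM
states, histone-mark peaks, CpG islands, HiC loop calls, an expression
table). It provides:

- **Two-stage differential methylation.** Per-CpG beta-binomial Wald tests of
  a tumor group against normal reference cells (stage 1), segmentation of
  differentially methylated CpGs (DMCs) into regions (DMRs), then a second
  aggregated beta-binomial test of each DMR against *all other* tumor samples
  (stage 2) to isolate mutation-specific regions.
- **5hmC estimation** from paired standard and oxidative bisulfite tracks
  (WGBS reports 5mC + 5hmC, oxWGBS reports 5mC; their difference at jointly
  well-covered CpGs estimates 5hmC).
- **Regulatory annotation**: chromatin-state assignment and fold enrichment,
  active/poised/weak enhancer classification from H3K27ac/H3K4me1/H3K27me3
  peaks, CpG density, a permutation test for region-set overlap, and
  ROSE-style superenhancer calling (stitching + tangent cutoff on the scaled
  rank-signal curve).
- **Enhancer-to-gene linking** through HiC loop anchors, with target-gene
  expression percentile summaries.
- A **synthetic cohort generator** that emulates the study design
  (beta-binomial counts over group-level mean tracks, planted group-specific
  and pan-tumor hypermethylated regions, paired oxWGBS tracks, consistent
  annotation tracks with ground-truth labels), so the whole pipeline is
  testable end to end without controlled-access patient data.

## The statistical core

For a CpG (or a region, after summing counts per sample across its span),
each group's methylation level is the pooled proportion
μ̂\_g = Σᵢxᵢ / Σᵢnᵢ over samples with coverage. The test statistic for
group B vs group A is

```
W = (μ̂_B − μ̂_A) / sqrt(V_A + V_B),
V_g = μ̃_g (1 − μ̃_g) · Σᵢ nᵢ (1 + (nᵢ − 1) φ) / (Σᵢ nᵢ)²
```

the variance of a pooled beta-binomial proportion with overdispersion φ
(μ̃\_g is a continuity-shrunk mean used only inside the variance). φ is
estimated per CpG by method of moments on the residuals of per-sample betas
around their group means and shrunk toward the chromosome-wide median with
weight proportional to the number of usable samples. Two-sided p-values come
from the standard normal, with Benjamini–Hochberg FDR control per comparison.
A CpG is a DMC when q < 0.05 **and** |Δμ| ≥ 0.2; a chain of same-direction
DMCs becomes a DMR when its span holds more than 10 covered CpGs, at least
half of them DMCs, and a pooled span-level |Δμ| ≥ 0.2. A DMR is
*group-specific* when the stage-2 test against all non-excluded tumor
samples is significant in the same direction at the same thresholds.

## Worked example

Generate a synthetic cohort (33 samples in four mutation groups, two 5 Mb
chromosomes, ~50k CpGs, 100 planted IDH-specific enhancer regions and 50
pan-tumor CpG-island regions) and run the full pipeline:

```sh
methylphase simulate --seed 1 --out demo
# {"n_samples": 33, "n_cpgs": 49172, "n_planted": 150, "n_loops": 127, "seed": 1}

# add wgbs_path/oxwgbs_path columns to demo/sample_sheet.tsv, write run.yaml
# pointing at the bundle (see docs/methods.md), then:
methylphase run-all --config run.yaml
```

The run prints its summary and writes TSV tables plus `manifest.json`:

```json
{"low_meth_fraction": 1.0,
 "mean_cpg_density": 0.842,
 "permutation": {"observed": 99, "p": 9.999e-05, "n_perm": 10000},
 "superenhancers": {"n_superenhancers": 23, "fraction_with_dmr": 0.609},
 "anchored_dmr_fraction": 0.27,
 "top_quartile_fraction": 0.609}
```

Reading this output: stage 1 found 149 DMRs (6052 DMCs) of which exactly the
100 planted target-only regions survived stage 2 (`specific: n_specific:
100`); every specific DMR sits at a low-methylation locus in the reference
group (`low_meth_fraction: 1.0`); specific DMRs are CpG-poor (0.84 CpGs per
100 bp) relative to the pan-tumor island regions; their overlap with H3K27ac
peaks is far beyond chance draws from the full DMR universe (permutation
p ≈ 1e-4); 27% fall inside a loop anchor, and 61% of their loop-linked
target genes rank in the top expression quartile.

Each subcommand (`dmc`, `dmr`, `specific`, `hmc`, `annotate`, `enrich`,
`permtest`, `superenhancers`, `loops`) is also available standalone; all
thresholds are exposed as flags with the defaults above, and every run
records its parameters in the manifest.

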