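# Methods

This note documents the models, estimators, defaults and design choices
behind `methylphase`, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Data model and coordinate conventions

All coordinates are 0-based half-open. A CpG is identified by the
forward-strand position of its cytosine and, for every overlap computation,
occupies the dinucleotide `[pos, pos + 2)`. Input methylation tracks are
biscuit-style 5-column bedGraphs (chrom, start, end, beta, coverage); both
the 1 bp and 2 bp row dialects are accepted and normalised to the cytosine
start. Methylated counts are reconstructed as `round(beta × coverage)`,
rounding half away from zero — deterministic and inverse-consistent for
betas printed at two or more decimals. Tracks are assumed already
strand-collapsed to the forward-strand cytosine (the usual CpG-mode
extractor output); no internal strand merging is performed. Zero-coverage
cells are retained in the count matrix so that position universes stay
comparable across samples, and every statistical operation excludes them by
testing coverage, not presence.

## The beta-binomial Wald test

**Model.** Within group *g*, sample *i*'s methylated count at a CpG is
beta-binomial: `x_i ~ BetaBin(n_i, μ_g, φ)` with mean `μ_g` and
overdispersion `φ ∈ [0, 1)`, parameterised so that
`Var(x_i) = n_i μ_g(1−μ_g)(1 + (n_i−1)φ)`. The group estimate is the pooled
proportion `μ̂_g = Σx_i / Σn_i`, whose variance is

    V_g = μ_g(1−μ_g) · Σ n_i (1 + (n_i−1)φ) / (Σ n_i)².

**Dispersion estimation.** φ is estimated per CpG by method of moments on
the residuals of per-sample betas around their group means, pooled across
both groups: solving `Σ r_i² = Σ v_i (φ + (1−φ)/n_i)` for φ with
`v_i = μ̂_g(1−μ̂_g)`, clipped to `[0, 0.95]`. Per-CpG moment estimates are
noisy at cohort-scale sample counts, so they are shrunk toward the
chromosome-wide median φ (the scale on which dispersion is roughly
homogeneous) with weight proportional to the number of usable samples *m*:

    φ* = (m·φ̂ + m₀·φ_med) / (m + m₀),    m₀ = 20.

CpGs whose moment estimate is undefined take the median outright; a
chromosome with no finite estimate falls back to φ = 0.05, a typical WGBS
cohort value. No local smoothing of methylation levels along the genome is
applied: the signal of interest is focal, and smoothing couples neighbouring
CpGs in ways the region-level stage already handles.

**Statistic.** `W = (μ̂_B − μ̂_A)/sqrt(V_A + V_B)`, two-sided p from the
standard normal. Inside the variance only, group means are continuity-shrunk
(`μ̃ = (Σx + 0.5)/(Σn + 1)`) so the SE stays finite at fully methylated or
unmethylated CpGs; the reported difference uses raw pooled means, and
`diff == 0` maps to `W = 0, p = 1` exactly. The statistic is antisymmetric
under swapping the groups. CpGs with fewer than two covered samples in
either group are skipped and counted. Benjamini–Hochberg FDR is applied
within each comparison (CpG-level at stage 1, region-level at stage 2).

**Defaults** (all exposed in `Thresholds` and logged in the run manifest):
minimum absolute methylation difference 0.2; FDR 0.05; minimum 11 CpGs per
DMR ("more than 10"); coverage flag at 10×; low-methylation cutoff 0.3;
1 kb bins for genome-wide summaries; 5 kb profile flanks with 100 bp
sub-bins.

## DMR segmentation

Same-direction DMCs within `max_gap = 1000` bp are chained. A chain is a DMR
iff (a) its CpG-anchored span `[first pos, last pos + 2)` contains at least
11 covered CpGs, (b) at least half of them are DMCs, and (c) the pooled
group-mean difference over *all* CpGs in the span (not only DMCs) reaches
0.2 in the chain's direction. A chain failing (b) or (c) is split at its
largest inter-DMC gap and the halves are re-examined; this keeps one stray
DMC from dragging a genuine region below threshold while never altering
chains that already pass. The gap, the DMC share and the split rule are this
package's choices where the underlying method is stated only as ">10 CpGs
and a difference in mean methylation of 0.2"; they are exposed as
parameters.

## Two-stage specificity

Stage 2 re-tests each stage-1 DMR with counts aggregated per sample over the
region span, target group versus the pool of all comparison samples not in
an excluded group (exclusions exist because some mutation groups are known
confounders — hypomethylating or phenocopying mutations). One beta-binomial
Wald test per region, BH across regions, and a region is group-specific iff
`q < 0.05`, aggregated `|Δμ| ≥ 0.2`, and the direction matches stage 1. The
same Wald machinery implements both stages; shrinkage pools dispersion
across regions rather than per chromosome.

## 5hmC by oxidative-bisulfite subtraction

`hmc = β_WGBS − β_oxWGBS` per CpG per sample, defined only where **both**
assays exceed 10 reads (strict inequality). Negative values are retained:
they are unbiased sampling noise around small true levels, and flooring
would bias region means upward. Region summaries are unweighted means over
covered CpGs; group comparisons are two-sided Welch t-tests on per-sample
region-set means (the sample is the unit of replication), BH-adjusted across
reported contrasts. Conversion inefficiency is modeled on the oxidation
axis only: an efficiency *e* leaves `(1−e)·5hmC` unconverted in the oxWGBS
read-out, so the subtraction estimates `e·5hmC`.

## Regulatory annotation

- **State assignment**: each region takes the chromatin state with maximal
  bp overlap; ties break to the lowest state index (order of first
  appearance in the state map). State maps must be non-overlapping tilings.
  Enrichment is the ratio of state fractions between a region set and a
  background set, with 0/0 reported as missing.
- **Enhancer classes** from peak overlap booleans (≥ 1 bp): H3K27ac with
  H3K27me3 → poised (even if H3K4me1 is present); otherwise H3K27ac →
  active; otherwise H3K4me1 without H3K27me3 → weak; everything else —
  including H3K4me1 + H3K27me3 without H3K27ac — → none. The full 8-row
  table is asserted in the tests. Keeping "weak" a clean H3K4me1-only class
  is deliberate.
- **CpG density** is reported as CpGs per 100 bp (dinucleotide-overlap
  counting).
- **Permutation overlap test**: the unit of permutation is the whole region,
  drawn without replacement from a finite universe of candidate regions (not
  random genomic shuffling), matching a design in which the universe is "all
  DMRs called in any group". `p = (1 + #{null ≥ obs})/(1 + n_perm)` with
  add-one smoothing so p > 0; an exact mode enumerates all subsets via the
  hypergeometric tail and is used as its own oracle on small instances.
- **Superenhancers**: peaks within 12.5 kb are stitched with signals summed;
  stitched regions are sorted ascending by signal, the rank-signal curve is
  scaled to the unit square, and the cutoff is the signal at the point where
  a slope-1 line is tangent from below (argmin of y − x). Regions strictly
  above the cutoff are superenhancers; an all-equal (degenerate) curve
  yields none. The TSS-exclusion refinement of the original stitching
  algorithm is omitted — it requires transcript annotation the pipeline may
  not have, and the geometry of the cutoff is unaffected.

## Loop linking and expression percentiles

A DMR is anchored when it overlaps either anchor of a loop by ≥ 1 bp. For
each (eDMR, loop) hit, every gene promoter overlapping the partner anchor
yields a candidate target link; links are deduplicated per (DMR, gene).
Promoters default to TSS ± 2 kb when derived from gene locations. Expression
percentiles use the mid-rank convention `100·(rank − 0.5)/N` over all
expressed genes (mean TPM > 0 in the chosen sample set); the top-quartile
fraction is the share of rankable target genes at or above the 75th
percentile. Target genes that are absent or unexpressed are reported and
dropped rather than silently ranked.

## The synthetic cohort

The generator emulates the *structure* the analysis assumes, with ground
truth for every planted feature. Defaults describe the emulated study
conditions: four groups — reference normals (n = 6), the target mutation
group (n = 7), a phenocopy-risk group excluded from stage 2 (n = 5), and a
pool of other tumors (n = 15) — on 2 × 5 Mb chromosomes with ~50,000 CpGs;
beta-binomial dispersion φ = 0.05; negative-binomial coverage (mean 30,
size 10); 100 planted target-only regions of 20–60 CpGs with effect
δ = 0.4 placed inside enhancer-state segments; 50 pan-tumor regions placed
in CpG-island-like segments; baseline methylation bimodal at 0.25/0.85 with
regulatory states at the low mode; planted 5hmC of 0.2 at the specific
regions in TET-intact groups; oxidation efficiency 1.0 by default (the
0.73–0.83 range observed in real libraries is exercised explicitly in
tests). The genome is tiled with 15 chromatin states whose CpG spacing is
state-dependent (island-like ≫ enhancer ≫ background), rescaled so the
expected CpG total matches the configured count. Annotation tracks are
emitted consistently: H3K27ac/H3K4me1 peaks over enhancer states, H3K27me3
over repressed/bivalent states, genes inside transcribed segments with
log-normal TPM, loops wrapping a configurable fraction (default 0.3) of
enhancer-placed planted regions with partner anchors on gene promoters
(top-quartile genes with probability 0.68), plus decoy loops confined to
heterochromatic segments so truth links stay exactly recoverable. Everything
is a deterministic function of the config, including its seed (stream
fan-out via `SeedSequence.spawn`).

**What passing tests show — and don't.** The generator matches the model the
statistics assume (beta-binomial counts, exchangeable samples within
groups, focal planted effects on a smooth baseline). Real WGBS data violate
these assumptions in known ways the generator does not emulate: positionally
correlated errors (mapping, conversion failure), copy-number and purity
variation between tumor samples, subclonal methylation heterogeneity,
SNP-overlapping CpGs, and non-bimodal baseline structure. Recovery and
calibration results on synthetic cohorts therefore validate the
implementation and the statistical logic, not performance on any particular
patient cohort.

**Problem sizes.** Tests and the acceptance script run at the study-scale
default (~50k CpGs, 33–40 samples) for the main pipeline checks, a 10-seed
or 20-seed battery at the same scale for calibration, and a desk-scale
genome (1.2 Mb, ~8k CpGs) for unit-level checks; these sizes make each
pipeline stage take seconds while leaving all rates and tolerances at their
stated values.

## Numerical and degenerate-input choices

Rounding of `beta × coverage` is half-away-from-zero. `diff == 0` short-
circuits to `W = 0` before any division. φ estimates clip at 0.95 to keep
variances finite. Fully degenerate CpGs (all counts 0/0 beyond two samples)
are skipped as untestable rather than returned with NaNs. Regions with no
covered CpG are flagged missing and excluded from the denominators of
derived fractions, with counts reported. Empty inputs (BED, BEDPE, DMC
lists) produce empty outputs, not errors; malformed rows produce errors with
line numbers. Ties in expression ranks take mid-ranks; ties in state
assignment take the earlier state; the superenhancer tangent takes the
first argmin. TSV outputs are written with a fixed float format so that
identical configurations yield byte-identical files.

## Known limitations

- The second-stage comparison pools all non-excluded samples; per-group
  contrasts within the comparison pool are not modeled.
- No covariate adjustment, paired designs, or local-likelihood smoothing.
- Subtraction-based 5hmC is a method-of-moments estimate; no joint
  maximum-likelihood (5mC, 5hmC, conversion) model is fitted.
- The permutation test assumes the universe is a meaningful candidate pool;
  it does not shuffle genomic coordinates and cannot detect enrichment
  relative to arbitrary genomic background.
- Superenhancer calling omits TSS exclusion and uses summed (not
  input-normalised) signal.
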