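"""Synthetic WGBS/oxWGBS cohorts with ground truth, emulating the data
structure of a mutation-grouped AML methylome study.

The generator lays out a small genome as a 15-state chromatin tiling with
clustered CpG placement (CpG-island-like states are dense, enhancer states
intermediate, the rest sparse), assigns a bimodal baseline methylation
(regulatory states sit at the low mode), plants focal hypermethylated regions
(group-specific ones preferentially inside enhancer-state segments, shared
pan-tumor ones inside CpG-island-like segments), and draws per-sample read
counts from a beta-binomial with group-level mean tracks and negative-binomial
coverage. Paired oxidative-bisulfite tracks model 5hmC: WGBS reports
5mC + 5hmC, oxWGBS reports 5mC plus the un-oxidised 5hmC leakage
(1 - conversion_efficiency) * 5hmC. Annotation tracks (states, histone peaks,
CGIs, promoters, loops, expression) are emitted consistently with the planted
regions, including loop links from enhancer-placed regions to highly
expressed genes.

Everything is a deterministic function of the config (including its seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (CpGCountMatrix, GenomicIntervalSet, LoopSet,
                         ExpressionTable, write_bedpe, write_bed,
                         write_cpg_bedgraph, write_expression)

__all__ = ["PlantSpec", "SimConfig", "SimTruth", "AnnotationBundle",
           "simulate_methylomes", "simulate_paired_oxbs",
           "simulate_annotations", "write_bundle"]

STATE_NAMES = ["TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh",
               "ZNF/Rpts", "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC",
               "ReprPCWk", "Quies"]
STATE_WEIGHTS = {"TssA": 0.04, "TssAFlnk": 0.02, "TxFlnk": 0.02, "Tx": 0.10,
                 "TxWk": 0.10, "EnhG": 0.05, "Enh": 0.13, "ZNF/Rpts": 0.02,
                 "Het": 0.10, "TssBiv": 0.03, "BivFlnk": 0.02, "EnhBiv": 0.03,
                 "ReprPC": 0.05, "ReprPCWk": 0.07, "Quies": 0.22}
ENHANCER_STATES = ("Enh", "EnhG")
CGI_STATES = ("TssA", "TssBiv", "BivFlnk", "EnhBiv")
LOW_METH_STATES = ENHANCER_STATES + CGI_STATES + ("TssAFlnk",)
GENE_STATES = ("Tx", "TxWk")
DECOY_STATES = ("Het", "Quies")
# relative CpG spacing (bp) by state class before rescaling to hit n_cpgs
SPACING = {"cgi": 25, "enhancer": 75, "background": 500}


@dataclass
class PlantSpec:
    """One family of planted differentially methylated regions."""

    target_groups: tuple[str, ...]
    n_regions: int
    cpgs_per_region: tuple[int, int] = (20, 60)
    effect: float = 0.4
    placement: str = "enhancer_state"  # enhancer_state | cgi_state | random

    def __post_init__(self) -> None:
        self.target_groups = tuple(self.target_groups)
        if not 0 < self.effect <= 1:
            raise ValueError("effect must be in (0, 1]")
        if self.placement not in ("enhancer_state", "cgi_state", "random"):
            raise ValueError(f"unknown placement {self.placement!r}")
        lo, hi = self.cpgs_per_region
        if lo < 2 or hi < lo:
            raise ValueError("cpgs_per_region range invalid")


def _default_groups() -> tuple[tuple[str, int], ...]:
    return (("CD34", 6), ("IDH", 7), ("TET2", 5), ("AML", 15))


def _default_planted() -> tuple[PlantSpec, ...]:
    return (PlantSpec(("IDH",), 100, (20, 60), 0.4, "enhancer_state"),)


def _default_shared() -> tuple[PlantSpec, ...]:
    # pan-tumor hypermethylation: CpG-island-like placement, every non-normal group
    return (PlantSpec(("IDH", "TET2", "AML"), 50, (20, 60), 0.4, "cgi_state"),)


@dataclass
class SimConfig:
    """Full description of one synthetic cohort (seed included)."""

    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_cpgs: int = 50_000
    groups: tuple[tuple[str, int], ...] = field(default_factory=_default_groups)
    reference_group: str = "CD34"
    baseline_low: float = 0.25
    baseline_high: float = 0.85
    low_mode_fraction: float = 0.25
    dispersion: float = 0.05
    coverage_mean: float = 30.0
    coverage_size: float = 10.0
    planted_dmrs: tuple[PlantSpec, ...] = field(default_factory=_default_planted)
    planted_shared_hyper: tuple[PlantSpec, ...] = field(default_factory=_default_shared)
    hmc_level: float = 0.2
    hmc_null_groups: tuple[str, ...] = ("TET2",)
    oxbs_conversion_efficiency: float = 1.0
    n_genes: int = 150
    loop_anchor_fraction: float = 0.3
    top_quartile_link_fraction: float = 0.68
    n_decoy_loops: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple((str(g), int(n)) for g, n in self.groups)
        self.planted_dmrs = tuple(self.planted_dmrs)
        self.planted_shared_hyper = tuple(self.planted_shared_hyper)
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.reference_group not in names:
            raise ValueError("reference_group missing from groups")
        for prop in ("baseline_low", "baseline_high", "low_mode_fraction",
                     "loop_anchor_fraction", "top_quartile_link_fraction",
                     "hmc_level"):
            if not 0 <= getattr(self, prop) <= 1:
                raise ValueError(f"{prop} must be in [0, 1]")
        if not 0 < self.dispersion < 1:
            raise ValueError("dispersion must be in (0, 1)")
        if not 0 < self.oxbs_conversion_efficiency <= 1:
            raise ValueError("oxbs_conversion_efficiency must be in (0, 1]")
        if self.hmc_level > self.baseline_low:
            raise ValueError("hmc_level may not exceed baseline_low "
                             "(5mC would go negative at planted 5hmC sites)")
        for spec in self.planted_dmrs + self.planted_shared_hyper:
            unknown = set(spec.target_groups) - set(names)
            if unknown:
                raise ValueError(f"planted spec targets unknown groups {sorted(unknown)}")
            if spec.placement != "random" and self.baseline_low + spec.effect > 1:
                raise ValueError("baseline_low + effect exceeds 1")

    def group_sizes(self) -> dict[str, int]:
        return dict(self.groups)

    def sample_ids(self) -> list[tuple[str, str]]:
        return [(f"{g}_{i + 1}", g) for g, n in self.groups for i in range(n)]


@dataclass
class SimTruth:
    """Ground truth: planted regions, per-CpG per-group mean tracks, layout."""

    config: SimConfig
    cpg_chroms: np.ndarray
    cpg_positions: np.ndarray
    segments: pd.DataFrame          # chrom, start, end, state
    cgis: pd.DataFrame              # chrom, start, end
    regions: pd.DataFrame           # planted regions with metadata
    group_means: dict[str, np.ndarray]   # apparent WGBS mean per CpG
    hmc: dict[str, np.ndarray]           # true 5hmC per CpG
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    links: pd.DataFrame = field(default_factory=pd.DataFrame)

    def region_cpg_mask(self, region_row) -> np.ndarray:
        m = (self.cpg_chroms == region_row.chrom)
        return m & (self.cpg_positions >= region_row.start - 1) & \
            (self.cpg_positions < region_row.end)


AnnotationBundle = namedtuple(
    "AnnotationBundle",
    ["states", "cgis", "promoters", "peaks", "loops", "expression"])


# ---------------------------------------------------------------------------
# layout


def _spacing_class(state: str) -> str:
    if state in CGI_STATES:
        return "cgi"
    if state in ENHANCER_STATES:
        return "enhancer"
    return "background"


def _build_layout(config: SimConfig, rng: np.random.Generator):
    """Segment the genome into states and place CpGs with clustered density."""
    names = list(STATE_WEIGHTS)
    weights = np.array([STATE_WEIGHTS[s] for s in names])
    weights = weights / weights.sum()
    pad = len(str(config.n_chroms))  # zero-pad so lexicographic == numeric order
    seg_rows = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1:0{pad}d}"
        pos = 0
        while pos < config.chrom_length_bp:
            length = int(rng.integers(4000, 20001))
            end = min(pos + length, config.chrom_length_bp)
            state = names[rng.choice(len(names), p=weights)]
            seg_rows.append((chrom, pos, end, state))
            pos = end
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])

    # rescale spacings so the expected CpG total matches n_cpgs
    seg_len = (segments["end"] - segments["start"]).to_numpy(float)
    cls = segments["state"].map(_spacing_class)
    expected = sum(seg_len[cls == k].sum() / v for k, v in SPACING.items())
    scale = expected / config.n_cpgs
    spacing = {k: max(2.0, v * scale) for k, v in SPACING.items()}

    chroms, positions = [], []
    for r, klass in zip(segments.itertuples(index=False), cls):
        mean_gap = spacing[klass]
        length = r.end - r.start
        n_here = rng.poisson(length / mean_gap)
        if n_here == 0:
            continue
        offs = np.unique(rng.integers(0, max(length - 2, 1), size=n_here))
        if len(offs) > 1:  # CpG dinucleotides may not overlap each other
            offs = offs[np.concatenate([[True], np.diff(offs) >= 2])]
        positions.append(r.start + offs)
        chroms.extend([r.chrom] * len(offs))
    cpg_positions = np.concatenate(positions) if positions else np.empty(0, np.int64)
    cpg_chroms = np.asarray(chroms, dtype=object)

    # CGI track: the core of every CGI-class segment
    cgi_rows = []
    for r in segments[segments["state"].isin(CGI_STATES)].itertuples(index=False):
        span = r.end - r.start
        cgi_rows.append((r.chrom, r.start + span // 4, r.end - span // 4))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    return segments, cgis, cpg_chroms, cpg_positions


def _plant_regions(config: SimConfig, segments: pd.DataFrame,
                   cpg_chroms: np.ndarray, cpg_positions: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Choose non-overlapping planted regions.

    A segment with enough CpGs offers one "slot" per hi+2 CpGs (disjoint CpG
    blocks), so one spec may plant several regions in a large segment; a
    segment is used by at most one spec.
    """
    seg = segments.reset_index(drop=True)
    counts = np.zeros(len(seg), dtype=np.int64)
    for i, r in enumerate(seg.itertuples(index=False)):
        m = (cpg_chroms == r.chrom) & (cpg_positions >= r.start) & (cpg_positions < r.end)
        counts[i] = int(m.sum())
    used = np.zeros(len(seg), dtype=bool)
    rows = []
    specs = ([("specific", s) for s in config.planted_dmrs]
             + [("shared", s) for s in config.planted_shared_hyper])
    for kind, spec in specs:
        lo, hi = spec.cpgs_per_region
        if spec.placement == "enhancer_state":
            eligible = seg["state"].isin(ENHANCER_STATES).to_numpy()
        elif spec.placement == "cgi_state":
            eligible = seg["state"].isin(CGI_STATES).to_numpy()
        else:
            eligible = np.ones(len(seg), dtype=bool)
        eligible &= (counts >= hi + 2) & ~used
        slots = [(si, j, int(counts[si] // (hi + 2)))
                 for si in np.flatnonzero(eligible)
                 for j in range(int(counts[si] // (hi + 2)))]
        if len(slots) < spec.n_regions:
            raise ValueError(
                f"cannot place {spec.n_regions} {spec.placement} regions: "
                f"only {len(slots)} eligible slots")
        chosen = rng.choice(len(slots), size=spec.n_regions, replace=False)
        for ci in np.sort(chosen):
            si, j, n_slots = slots[ci]
            used[si] = True
            r = seg.iloc[si]
            m = ((cpg_chroms == r["chrom"]) & (cpg_positions >= r["start"])
                 & (cpg_positions < r["end"]))
            pos = np.array_split(cpg_positions[m], n_slots)[j]
            k = int(rng.integers(lo, min(hi, len(pos)) + 1))
            start_i = int(rng.integers(0, len(pos) - k + 1))
            run = pos[start_i:start_i + k]
            rows.append((r["chrom"], int(run[0]), int(run[-1]) + 2, kind,
                         spec.target_groups, spec.effect, spec.placement, k,
                         r["state"]))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "targets",
                                      "effect", "placement", "n_cpgs", "state"])
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _group_mean_tracks(config: SimConfig, segments: pd.DataFrame,
                       regions: pd.DataFrame, cpg_chroms: np.ndarray,
                       cpg_positions: np.ndarray, rng: np.random.Generator):
    """Baseline bimodal means per CpG plus planted effects and 5hmC per group."""
    n = len(cpg_positions)
    baseline = np.full(n, config.baseline_high)
    for r in segments.itertuples(index=False):
        low = (r.state in LOW_METH_STATES) or (rng.random() < config.low_mode_fraction)
        if low:
            m = ((cpg_chroms == r.chrom) & (cpg_positions >= r.start)
                 & (cpg_positions < r.end))
            baseline[m] = config.baseline_low

    group_means: dict[str, np.ndarray] = {}
    hmc: dict[str, np.ndarray] = {}
    for g, _ in config.groups:
        group_means[g] = baseline.copy()
        hmc[g] = np.zeros(n)
    for r in regions.itertuples(index=False):
        m = ((cpg_chroms == r.chrom) & (cpg_positions >= r.start - 1)
             & (cpg_positions < r.end))
        for g in r.targets:
            lifted = group_means[g][m] + r.effect
            if np.any(lifted > 1 + 1e-12):
                raise ValueError(
                    f"planted effect drives mean above 1 in region "
                    f"{r.chrom}:{r.start}-{r.end} for group {g}")
            group_means[g][m] = lifted
        if r.kind == "specific":
            for g, _ in config.groups:
                if g not in r.targets and g not in config.hmc_null_groups:
                    hmc[g][m] = config.hmc_level
    return group_means, hmc


# ---------------------------------------------------------------------------
# sampling


def _draw_counts(means: np.ndarray, n_samples: int, config: SimConfig,
                 rng: np.random.Generator):
    """Beta-binomial counts for one group: (meth, total) of shape (n_cpg, n_samples)."""
    phi = config.dispersion
    n_cpg = len(means)
    p_nb = config.coverage_size / (config.coverage_size + config.coverage_mean)
    total = rng.negative_binomial(config.coverage_size, p_nb, size=(n_cpg, n_samples))
    mu = np.repeat(means[:, None], n_samples, axis=1)
    a = mu * (1 - phi) / phi
    b = (1 - mu) * (1 - phi) / phi
    interior = (mu > 0) & (mu < 1)
    p = mu.copy()
    if interior.any():
        p[interior] = rng.beta(a[interior], b[interior])
    meth = rng.binomial(total, p)
    return meth.astype(np.int64), total.astype(np.int64)


def _assemble_matrix(config: SimConfig, truth: SimTruth, mean_of, assay: str,
                     rng: np.random.Generator) -> CpGCountMatrix:
    ids_groups = config.sample_ids()
    meth_cols, total_cols, ids = [], [], []
    for g, n_samples in config.groups:
        means = mean_of(g)
        meth, total = _draw_counts(means, n_samples, config, rng)
        meth_cols.append(meth)
        total_cols.append(total)
        ids.extend(sid for sid, grp in ids_groups if grp == g)
    meta = pd.DataFrame({"assay": assay, "group": [g for _, g in ids_groups]},
                        index=[sid for sid, _ in ids_groups])
    meta.index.name = "sample_id"
    return CpGCountMatrix(truth.cpg_chroms, truth.cpg_positions, ids,
                          np.hstack(meth_cols), np.hstack(total_cols),
                          meta.loc[ids])


def simulate_methylomes(config: SimConfig) -> tuple[CpGCountMatrix, SimTruth]:
    """Generate the WGBS cohort and its ground truth.

    Per CpG c and group g, the apparent methylation mean is
    baseline(c) + effect * 1[c inside a region planted for g]; per-sample
    proportions are Beta with that mean and overdispersion ``dispersion``,
    coverage is negative-binomial, and methylated counts are binomial.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_meth, _, _ = [np.random.default_rng(s) for s in ss.spawn(4)]
    segments, cgis, cpg_chroms, cpg_positions = _build_layout(config, rng_layout)
    regions = _plant_regions(config, segments, cpg_chroms, cpg_positions, rng_layout)
    group_means, hmc = _group_mean_tracks(config, segments, regions, cpg_chroms,
                                          cpg_positions, rng_layout)
    truth = SimTruth(config, cpg_chroms, cpg_positions, segments, cgis, regions,
                     group_means, hmc)
    matrix = _assemble_matrix(config, truth, lambda g: truth.group_means[g],
                              "WGBS", rng_meth)
    return matrix, truth


def simulate_paired_oxbs(truth: SimTruth,
                         config: SimConfig | None = None
                         ) -> tuple[CpGCountMatrix, CpGCountMatrix]:
    """Draw paired WGBS / oxWGBS tracks from the truth's 5mC and 5hmC levels.

    WGBS success probability is 5mC + 5hmC (the apparent mean); oxWGBS is
    5mC + (1 - conversion_efficiency) * 5hmC, i.e. perfect oxidation removes
    the whole 5hmC fraction from the oxidised read-out.
    """
    config = config or truth.config
    for g, _ in config.groups:
        five_mc = truth.group_means[g] - truth.hmc[g]
        if np.any(five_mc < -1e-12) or np.any(truth.group_means[g] > 1 + 1e-12):
            raise ValueError("5mC + 5hmC outside [0, 1] for group " + g)
    ss = np.random.SeedSequence(config.seed)
    _, _, rng_oxbs, _ = [np.random.default_rng(s) for s in ss.spawn(4)]
    eff = config.oxbs_conversion_efficiency
    wgbs = _assemble_matrix(config, truth, lambda g: truth.group_means[g],
                            "WGBS", rng_oxbs)
    oxwgbs = _assemble_matrix(
        config, truth,
        lambda g: truth.group_means[g] - eff * truth.hmc[g], "oxWGBS", rng_oxbs)
    return wgbs, oxwgbs


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(truth: SimTruth,
                         config: SimConfig | None = None) -> AnnotationBundle:
    """Emit annotation tracks consistent with the planted regions.

    Histone peaks follow the state tiling (H3K27ac + H3K4me1 over enhancer
    states, H3K27me3 over repressed/bivalent states); a configurable fraction
    of enhancer-placed planted regions is wrapped in a loop anchor whose
    partner anchor covers the promoter of a highly expressed gene; genes live
    in transcribed-state segments; decoy loops connect heterochromatic
    segments. Links are recorded on ``truth.links``.
    """
    config = config or truth.config
    ss = np.random.SeedSequence(config.seed)
    _, _, _, rng = [np.random.default_rng(s) for s in ss.spawn(4)]
    seg = truth.segments

    states = GenomicIntervalSet(seg.rename(columns={"state": "label"}))
    cgis = GenomicIntervalSet(truth.cgis.assign(label="CGI"))

    def _peaks(state_names, trim=0.2) -> GenomicIntervalSet:
        rows = []
        for r in seg[seg["state"].isin(state_names)].itertuples(index=False):
            span = r.end - r.start
            pad = int(span * trim)
            rows.append((r.chrom, r.start + pad, r.end - pad, "peak",
                         float(np.round(rng.lognormal(2.0, 1.0), 4))))
        return GenomicIntervalSet(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"]))

    peaks = {
        "H3K27ac": _peaks(ENHANCER_STATES + ("TssA", "TssAFlnk")),
        "H3K4me1": _peaks(ENHANCER_STATES + ("TxFlnk",)),
        "H3K27me3": _peaks(("ReprPC", "ReprPCWk", "TssBiv", "BivFlnk", "EnhBiv")),
    }

    # genes in transcribed segments, TPM lognormal, continuous (untied) ranks
    gene_segs = seg[seg["state"].isin(GENE_STATES)
                    & (seg["end"] - seg["start"] > 5200)].reset_index(drop=True)
    n_genes = min(config.n_genes, len(gene_segs))
    picks = rng.choice(len(gene_segs), size=n_genes, replace=False)
    gene_rows = []
    for gi, si in enumerate(np.sort(picks)):
        r = gene_segs.iloc[si]
        tss = int(rng.integers(r["start"] + 2500, r["end"] - 2500))
        gene_rows.append((f"gene{gi + 1:04d}", r["chrom"], tss))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss"])
    sample_ids = [sid for sid, _ in config.sample_ids()]
    base = rng.lognormal(1.0, 1.5, size=n_genes)
    noise = rng.lognormal(0.0, 0.3, size=(n_genes, len(sample_ids)))
    tpm = pd.DataFrame(base[:, None] * noise, index=genes["gene_id"],
                       columns=sample_ids)
    gene_locs = GenomicIntervalSet(pd.DataFrame({
        "chrom": genes["chrom"], "start": genes["tss"],
        "end": genes["tss"] + 1000, "label": genes["gene_id"]}))
    expression = ExpressionTable(tpm, gene_locs)
    promoters = GenomicIntervalSet(pd.DataFrame({
        "chrom": genes["chrom"], "start": np.maximum(genes["tss"] - 2000, 0),
        "end": genes["tss"] + 2000, "label": genes["gene_id"]}))

    # loops: planted enhancer regions -> gene promoters
    mean_tpm = tpm.mean(axis=1)
    q75 = mean_tpm.quantile(0.75)
    top_genes = genes[mean_tpm.loc[genes["gene_id"]].to_numpy() >= q75]
    loop_rows, link_rows = [], []
    enh_regions = truth.regions[(truth.regions["kind"] == "specific")
                                & (truth.regions["placement"] == "enhancer_state")]
    for ridx, r in enh_regions.iterrows():
        if rng.random() >= config.loop_anchor_fraction:
            continue
        pool = top_genes if rng.random() < config.top_quartile_link_fraction else genes
        same = pool[pool["chrom"] == r["chrom"]]
        if len(same) == 0:
            continue
        gene = same.iloc[int(rng.integers(0, len(same)))]
        pad = 1000
        a1 = (r["chrom"], max(int(r["start"]) - pad, 0), int(r["end"]) + pad)
        a2 = (gene["chrom"], max(int(gene["tss"]) - 2500, 0), int(gene["tss"]) + 2500)
        loop_rows.append(a1 + a2)
        link_rows.append((int(ridx), gene["gene_id"]))

    # decoy loops between heterochromatic segments (keeps truth links exact)
    decoy = seg[seg["state"].isin(DECOY_STATES)].reset_index(drop=True)
    wide = decoy[(decoy["end"] - decoy["start"]) > 8000]
    for _ in range(config.n_decoy_loops):
        if len(wide) < 2:
            break
        i, j = rng.choice(len(wide), size=2, replace=False)
        r1, r2 = wide.iloc[i], wide.iloc[j]
        loop_rows.append((r1["chrom"], r1["start"] + 3000, r1["end"] - 3000,
                          r2["chrom"], r2["start"] + 3000, r2["end"] - 3000))
    loops = LoopSet(pd.DataFrame(
        loop_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]),
        provenance="synthetic")
    truth.genes = genes
    truth.links = pd.DataFrame(link_rows, columns=["region_id", "gene_id"])
    return AnnotationBundle(states, cgis, promoters, peaks, loops, expression)


# ---------------------------------------------------------------------------
# bundle writer (CLI surface)


def write_bundle(config: SimConfig, out_dir: str) -> dict:
    """Write the full synthetic bundle (bedGraphs, sample sheet, BEDs, BEDPE,
    expression, truth JSON) into a directory; returns a manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    matrix, truth = simulate_methylomes(config)
    wgbs, oxwgbs = simulate_paired_oxbs(truth, config)
    bundle = simulate_annotations(truth, config)

    sheet_rows = []
    for sid in matrix.samples:
        write_cpg_bedgraph(matrix, sid, os.path.join(out_dir, f"{sid}.wgbs.bedgraph"))
        write_cpg_bedgraph(oxwgbs, sid, os.path.join(out_dir, f"{sid}.oxwgbs.bedgraph"))
        sheet_rows.append((sid, "WGBS", matrix.metadata.loc[sid, "group"]))
    pd.DataFrame(sheet_rows, columns=["sample_id", "assay", "group"]).to_csv(
        os.path.join(out_dir, "sample_sheet.tsv"), sep="\t", index=False)

    write_bed(bundle.states, os.path.join(out_dir, "chromatin_states.bed"))
    write_bed(bundle.cgis, os.path.join(out_dir, "cgi.bed"))
    write_bed(bundle.promoters, os.path.join(out_dir, "promoters.bed"))
    for mark, pk in bundle.peaks.items():
        write_bed(pk, os.path.join(out_dir, f"peaks_{mark}.bed"))
    write_bedpe(bundle.loops, os.path.join(out_dir, "loops.bedpe"))
    write_expression(bundle.expression, os.path.join(out_dir, "expression.tsv"))

    regions = truth.regions.copy()
    regions["targets"] = regions["targets"].map(list)
    payload = {
        "config": dataclasses.asdict(config),
        "regions": regions.to_dict(orient="records"),
        "links": truth.links.to_dict(orient="records"),
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
    return {"n_samples": len(matrix.samples), "n_cpgs": matrix.n_positions,
            "n_planted": len(truth.regions), "n_loops": len(bundle.loops),
            "seed": config.seed}
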