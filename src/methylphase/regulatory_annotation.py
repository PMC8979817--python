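"""Chromatin-state annotation, enhancer classification, CpG density,
permutation overlap testing, and superenhancer calling.

Overlap throughout means at least 1 bp unless a function exposes
``min_overlap_bp``. Enhancer classes follow the histone-mark rule table:
H3K27ac alone or with H3K4me1 is an active enhancer, H3K27ac with H3K27me3 is
poised (regardless of H3K4me1), H3K4me1 alone is weak, and everything else —
including H3K4me1 with H3K27me3 but no H3K27ac — is none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from ._intervals import max_overlap_assignment, overlap_bp_flags
from .io_formats import GenomicIntervalSet, MethylationValidationError

__all__ = [
    "state_overlap_distribution",
    "state_enrichment",
    "overlap_fraction",
    "cpg_density",
    "classify_enhancers",
    "PermutationResult",
    "permutation_overlap_test",
    "SuperenhancerSet",
    "call_superenhancers",
    "count_dmrs_per_superenhancer",
]


def _df(x) -> pd.DataFrame:
    if isinstance(x, GenomicIntervalSet):
        return x.df
    return pd.DataFrame(x).reset_index(drop=True)


def _check_tiling(state_df: pd.DataFrame) -> None:
    for chrom, sub in state_df.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        if (sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]).any():
            raise MethylationValidationError(
                f"state map has overlapping intervals on {chrom}")


def _state_priority(state_df: pd.DataFrame) -> dict[int, int]:
    # tie-break: lowest state index = order of first appearance in the map
    order: dict[str, int] = {}
    for lab in state_df["label"]:
        order.setdefault(lab, len(order))
    return {i: order[lab] for i, lab in enumerate(state_df["label"])}


def assign_states(regions, state_map) -> pd.Series:
    """Per region, the chromatin state with maximal bp overlap (ties: lowest
    state index); NaN for regions overlapping no state interval."""
    rdf, sdf = _df(regions), _df(state_map).reset_index(drop=True)
    _check_tiling(sdf)
    idx = max_overlap_assignment(rdf, sdf, priority=_state_priority(sdf))
    labels = sdf["label"].to_numpy(object)
    return pd.Series([labels[i] if i >= 0 else np.nan for i in idx], name="state")


def state_overlap_distribution(regions, state_map) -> pd.Series:
    """Fraction of regions assigned to each state; sums to 1 over assigned regions."""
    assigned = assign_states(regions, state_map).dropna()
    states = list(dict.fromkeys(_df(state_map)["label"]))
    counts = assigned.value_counts()
    frac = pd.Series({s: counts.get(s, 0) for s in states}, dtype=float)
    if frac.sum() > 0:
        frac = frac / frac.sum()
    return frac


def state_enrichment(regions, background, state_map) -> pd.Series:
    """Fold enrichment of each state in regions relative to background.

    enrichment = fraction(regions) / fraction(background); 0/0 is reported as
    NaN (missing).
    """
    if len(_df(background)) == 0:
        raise ValueError("background must be non-empty")
    fr = state_overlap_distribution(regions, state_map)
    fb = state_overlap_distribution(background, state_map)
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = fr / fb
    enr[(fr == 0) & (fb == 0)] = np.nan
    return enr


def overlap_fraction(regions, features, min_overlap_bp: int = 1):
    """Fraction of regions overlapping any feature by >= min_overlap_bp.

    Returns (fraction, per-region boolean flags).
    """
    rdf, fdf = _df(regions), _df(features)
    if len(rdf) == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if len(fdf) == 0:
        return 0.0, np.zeros(len(rdf), dtype=bool)
    flags = overlap_bp_flags(rdf, fdf, min_overlap_bp)
    return float(flags.mean()), flags


def cpg_density(regions, cpg_chroms, cpg_positions=None):
    """CpGs per 100 bp for each region, plus the set mean.

    Accepts either (chroms, positions) arrays or a CpGCountMatrix-like object
    with ``.chroms`` / ``.positions``. A CpG counts if its dinucleotide
    [pos, pos+2) overlaps the region.
    """
    from ._intervals import region_cpg_indices
    if cpg_positions is None:
        cpg_positions, cpg_chroms = cpg_chroms.positions, cpg_chroms.chroms
    rdf = _df(regions)
    idx_lists = region_cpg_indices(np.asarray(cpg_chroms, dtype=object),
                                   np.asarray(cpg_positions), rdf)
    length = (rdf["end"] - rdf["start"]).to_numpy(float)
    density = 100.0 * np.array([len(i) for i in idx_lists]) / length
    return density, float(density.mean()) if len(density) else float("nan")


def classify_enhancers(regions, k27ac, k4me1, k27me3) -> pd.DataFrame:
    """Classify regions as active / poised / weak / none enhancers.

    Evidence booleans record >=1 bp overlap with each peak set; the class is a
    deterministic function of the three booleans (see module docstring).
    """
    rdf = _df(regions)
    a = overlap_fraction(rdf, k27ac)[1]
    m1 = overlap_fraction(rdf, k4me1)[1]
    m3 = overlap_fraction(rdf, k27me3)[1]
    cls = np.where(a & m3, "poised",
                   np.where(a, "active",
                            np.where(m1 & ~m3, "weak", "none")))
    out = rdf[["chrom", "start", "end"]].copy()
    out["k27ac"], out["k4me1"], out["k27me3"] = a, m1, m3
    out["enhancer_class"] = cls
    return out


@dataclass
class PermutationResult:
    observed: int
    p: float
    n_perm: int
    null_mean: float
    exact: bool = False


def permutation_overlap_test(query, reference, universe, n_perm: int = 10000,
                             seed: int = 0, exact: bool = False) -> PermutationResult:
    """Empirical overlap test: is the query's reference-overlap count high
    relative to equally sized draws from the universe?

    The null resamples |query| members from the universe without replacement;
    p = (1 + #{null >= observed}) / (1 + n_perm). With ``exact=True`` all
    C(|universe|, |query|) subsets are enumerated and p is the exact tail
    fraction (the observed subset is itself one of the enumerated subsets).
    """
    qdf, rdf, udf = _df(query), _df(reference), _df(universe)
    ukeys = list(zip(udf["chrom"], udf["start"], udf["end"]))
    qkeys = list(zip(qdf["chrom"], qdf["start"], qdf["end"]))
    lut: dict[tuple, int] = {}
    for i, k in enumerate(ukeys):
        lut.setdefault(k, i)
    try:
        qidx = np.array([lut[k] for k in qkeys], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"query interval not in universe: {exc.args[0]}") from None
    if len(udf) < len(qdf):
        raise ValueError("universe smaller than query")
    if not exact and n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    flags = (overlap_bp_flags(udf, rdf) if len(rdf)
             else np.zeros(len(udf), dtype=bool)).astype(np.int64)
    observed = int(flags[qidx].sum())
    k, n = len(qdf), len(udf)

    if exact:
        n_hit = int(flags.sum())
        # observed-count null is hypergeometric in the number of flagged members
        total = math.comb(n, k)
        ge = sum(math.comb(n_hit, j) * math.comb(n - n_hit, k - j)
                 for j in range(observed, min(n_hit, k) + 1))
        return PermutationResult(observed, ge / total, total,
                                 k * n_hit / n, exact=True)

    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    block = 2000
    for s in range(0, n_perm, block):
        m = min(block, n_perm - s)
        keys = rng.random((m, n))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts[s:s + m] = flags[picks].sum(axis=1)
    p = (1 + int((counts >= observed).sum())) / (1 + n_perm)
    return PermutationResult(observed, p, n_perm, float(counts.mean()))


@dataclass
class SuperenhancerSet:
    """Stitched peak regions ranked by aggregate signal with a tangent cutoff."""

    df: pd.DataFrame  # chrom, start, end, signal, rank, is_superenhancer
    cutoff_signal: float
    stitch_distance: int


def stitch_peaks(peaks, stitch_distance: int = 12500) -> pd.DataFrame:
    """Merge peaks within stitch_distance of each other, summing signal."""
    pdf = _df(peaks)
    if len(pdf) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "signal"])
    sig = pdf["score"].fillna(0.0) if "score" in pdf else pd.Series(0.0, index=pdf.index)
    if (sig < 0).any():
        raise ValueError("peak signal must be >= 0")
    rows = []
    work = pdf.assign(signal=sig).sort_values(
        ["chrom", "start"], kind="mergesort").itertuples(index=False)
    cur = None
    for r in work:
        if cur is not None and r.chrom == cur[0] and r.start - cur[2] <= stitch_distance:
            cur[2] = max(cur[2], r.end)
            cur[3] += r.signal
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [r.chrom, r.start, r.end, r.signal]
    if cur is not None:
        rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


def call_superenhancers(peaks, stitch_distance: int = 12500) -> SuperenhancerSet:
    """Rank stitched regions by signal and call superenhancers by the tangent rule.

    Regions are sorted ascending by signal and the rank-signal curve is scaled
    to the unit square; the cutoff is the signal at the point where a slope-1
    line is tangent to the curve from below (argmin of y - x). Regions with
    signal strictly above the cutoff are superenhancers. A degenerate all-equal
    curve yields zero superenhancers.
    """
    stitched = stitch_peaks(peaks, stitch_distance)
    n = len(stitched)
    if n == 0:
        df = stitched.assign(rank=pd.Series(dtype=int),
                             is_superenhancer=pd.Series(dtype=bool))
        return SuperenhancerSet(df, float("nan"), stitch_distance)
    s = stitched["signal"].to_numpy(float)
    order_desc = np.argsort(-s, kind="mergesort")
    rank = np.empty(n, dtype=np.int64)
    rank[order_desc] = np.arange(1, n + 1)
    if n == 1 or s.max() == s.min():
        cutoff = float("inf")  # degenerate line: nothing above
        is_se = np.zeros(n, dtype=bool)
    else:
        asc = np.sort(s)
        x = np.arange(n) / (n - 1)
        y = (asc - asc[0]) / (asc[-1] - asc[0])
        cutoff = float(asc[int(np.argmin(y - x))])
        is_se = s > cutoff
    out = stitched.copy()
    out["rank"] = rank
    out["is_superenhancer"] = is_se
    return SuperenhancerSet(out, cutoff, stitch_distance)


def count_dmrs_per_superenhancer(ses: SuperenhancerSet, dmrs) -> pd.Series:
    """Number of DMRs overlapping (>=1 bp) each superenhancer."""
    from ._intervals import overlap_hits
    se_df = ses.df[ses.df["is_superenhancer"]].reset_index(drop=True)
    ddf = _df(dmrs)
    if len(se_df) == 0:
        return pd.Series(dtype=np.int64)
    if len(ddf) == 0:
        return pd.Series(np.zeros(len(se_df), dtype=np.int64))
    hits = overlap_hits(se_df, ddf)
    return pd.Series([len(h) for h in hits], dtype=np.int64)
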