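"""5-hydroxymethylcytosine estimation from paired standard and oxidative
bisulfite tracks.

WGBS reports 5mC + 5hmC combined; oxidative bisulfite (oxWGBS) oxidises 5hmC
before conversion, so it reports 5mC alone. Their per-CpG beta difference is
therefore an estimate of 5hmC. Negative values are retained: they are sampling
noise around small true levels, and flooring them would bias region means
upward. A CpG counts as covered only where BOTH assays exceed ``min_cov``
reads (strict inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._intervals import region_cpg_indices
from .io_formats import CpGCountMatrix, GenomicIntervalSet

__all__ = ["HmcTrack", "compute_hmc", "region_hmc", "compare_region_hmc"]


@dataclass
class HmcTrack:
    """Per-CpG per-sample 5hmC estimates; NaN where the coverage rule fails."""

    chroms: np.ndarray
    positions: np.ndarray
    samples: list[str]
    hmc: np.ndarray       # (n_pos, n_samples) float, NaN where not covered
    covered: np.ndarray   # (n_pos, n_samples) bool

    def __post_init__(self) -> None:
        finite = self.hmc[self.covered]
        if finite.size and (np.nanmax(np.abs(finite)) > 1 + 1e-12):
            raise ValueError("hmc values must lie in [-1, 1]")
        if np.isfinite(self.hmc[~self.covered]).any():
            raise ValueError("hmc defined at uncovered cells")


def _position_key(m: CpGCountMatrix) -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays([m.chroms, m.positions])


def compute_hmc(wgbs: CpGCountMatrix, oxwgbs: CpGCountMatrix,
                min_cov: int = 10) -> HmcTrack:
    """Subtract oxWGBS betas from WGBS betas at jointly well-covered CpGs.

    Samples are paired by id: both matrices must carry the same sample set.
    Positions are intersected; an empty intersection is an error.
    """
    if set(wgbs.samples) != set(oxwgbs.samples):
        odd = set(wgbs.samples) ^ set(oxwgbs.samples)
        raise ValueError(f"unpaired samples between assays: {sorted(odd)}")
    ox_cols = oxwgbs.sample_index(wgbs.samples)

    kw, ko = _position_key(wgbs), _position_key(oxwgbs)
    common = kw.intersection(ko, sort=False)
    if len(common) == 0:
        raise ValueError("no CpG positions shared between the paired assays")
    iw = kw.get_indexer(common)
    io = ko.get_indexer(common)

    tw = wgbs.total[iw]
    to = oxwgbs.total[io][:, ox_cols]
    covered = (tw > min_cov) & (to > min_cov)
    with np.errstate(invalid="ignore", divide="ignore"):
        bw = wgbs.meth[iw] / np.maximum(tw, 1)
        bo = oxwgbs.meth[io][:, ox_cols] / np.maximum(to, 1)
    hmc = np.where(covered, bw - bo, np.nan)
    chroms = np.asarray([c for c, _ in common], dtype=object)
    positions = np.asarray([p for _, p in common], dtype=np.int64)
    order = np.lexsort((positions, chroms.astype(str)))
    return HmcTrack(chroms[order], positions[order], list(wgbs.samples),
                    hmc[order], covered[order])


def region_hmc(track: HmcTrack, regions) -> pd.DataFrame:
    """Unweighted mean 5hmC over covered CpGs per region per sample.

    Regions with no covered CpG for a sample are NaN (flagged missing, excluded
    from group summaries downstream).
    """
    rdf = regions.df if isinstance(regions, GenomicIntervalSet) else pd.DataFrame(regions)
    rdf = rdf.reset_index(drop=True)
    idx_lists = region_cpg_indices(track.chroms, track.positions, rdf)
    out = np.full((len(rdf), len(track.samples)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        for k, idx in enumerate(idx_lists):
            if idx.size:
                out[k] = np.nanmean(track.hmc[idx], axis=0)
    res = rdf[["chrom", "start", "end"]].copy()
    for j, s in enumerate(track.samples):
        res[s] = out[:, j]
    return res


def compare_region_hmc(region_sets: dict[str, object], groups: dict[str, list],
                       track: HmcTrack):
    """Mean 5hmC per (region set, sample group) plus pairwise Welch contrasts.

    The unit of replication is the sample: each sample's value for a region set
    is its mean over that set's per-region means. Contrasts are two-sided Welch
    t-tests between groups within each set, BH-adjusted across all reported
    contrasts. Groups with fewer than two samples are skipped with a warning.
    """
    sample_means: dict[str, pd.Series] = {}
    for set_name, regions in region_sets.items():
        per_region = region_hmc(track, regions)
        vals = per_region[track.samples]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            sample_means[set_name] = vals.mean(axis=0, skipna=True)

    mean_rows = []
    contrast_rows = []
    for set_name, per_sample in sample_means.items():
        for gname, members in groups.items():
            vals = per_sample[list(members)].to_numpy(float)
            mean_rows.append((set_name, gname, float(np.nanmean(vals)), len(members)))
        for (ga, ma), (gb, mb) in combinations(groups.items(), 2):
            va = per_sample[list(ma)].to_numpy(float)
            vb = per_sample[list(mb)].to_numpy(float)
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if len(va) < 2 or len(vb) < 2:
                warnings.warn(f"contrast {ga} vs {gb} in {set_name} skipped: "
                              "fewer than 2 samples", stacklevel=2)
                continue
            if np.var(va) == 0 and np.var(vb) == 0:
                p = 1.0 if np.mean(va) == np.mean(vb) else 0.0
                t = 0.0 if p == 1.0 else np.inf
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=False)
            contrast_rows.append((set_name, ga, gb, float(np.mean(va)),
                                  float(np.mean(vb)), float(t), float(p)))
    means = pd.DataFrame(mean_rows, columns=["region_set", "group", "mean_hmc", "n_samples"])
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["region_set", "group_a", "group_b", "mean_a", "mean_b", "t", "p"])
    if len(contrasts):
        contrasts["q"] = multipletests(contrasts["p"], method="fdr_bh")[1]
    else:
        contrasts["q"] = pd.Series(dtype=float)
    return means, contrasts
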