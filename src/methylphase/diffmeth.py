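"""Beta-binomial differential methylation: DMC testing, DMR segmentation,
two-stage mutation-specificity calling, and fixed-region summaries.

The per-CpG test is a Wald test on the difference of pooled group methylation
proportions. Counts within a group are pooled (mu_g = sum meth / sum total) and
the variance of the pooled estimator allows beta-binomial overdispersion:

    Var(mu_g) = mu_g (1 - mu_g) * sum_i n_i (1 + (n_i - 1) phi) / (sum_i n_i)^2

Overdispersion phi is estimated per CpG by method of moments on the residuals
of per-sample betas around their group mean, then shrunk toward the
chromosome-wide median with weight proportional to the number of usable
samples. No local smoothing of methylation levels is applied.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._intervals import region_cpg_indices
from .io_formats import CpGCountMatrix, GenomicIntervalSet

__all__ = [
    "Thresholds",
    "pooled_group_means",
    "dmc_test",
    "segment_dmrs",
    "call_group_specific",
    "region_test",
    "dmr_set_operations",
    "bin_mean_methylation",
    "region_group_methylation",
    "low_meth_fraction",
    "profile_matrix",
]


@dataclass
class Thresholds:
    """All tunable cutoffs of the differential-methylation pipeline.

    Defaults follow the analysis this package reproduces: minimum methylation
    difference 0.2, FDR 0.05, DMRs with more than 10 CpGs (min 11), coverage
    filter 10x, low-methylation cutoff 0.3, 1 kb bins, 5 kb profile flanks.
    """

    min_diff: float = 0.2
    fdr: float = 0.05
    min_cpgs_per_dmr: int = 11
    min_cov: int = 10
    low_meth_cutoff: float = 0.3
    bin_size: int = 1000
    flank: int = 5000
    max_gap: int = 1000
    min_dmc_fraction: float = 0.5
    profile_bin: int = 100
    phi_prior_weight: float = 20.0
    phi_fallback: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_diff", "fdr", "low_meth_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("min_cpgs_per_dmr", "min_cov", "bin_size", "max_gap", "profile_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _resolve_samples(matrix: CpGCountMatrix, group) -> list[str]:
    """A group argument may be a metadata group label or an explicit id list."""
    if isinstance(group, str):
        samples = matrix.group_samples(group)
        if not samples:
            raise ValueError(f"no samples in group {group!r}")
        return samples
    samples = list(group)
    if not samples:
        raise ValueError("empty sample group")
    matrix.sample_index(samples)  # raises on unknown ids
    return samples


# ---------------------------------------------------------------------------
# core Wald machinery


def _wald_core(meth: np.ndarray, total: np.ndarray, cols_a: np.ndarray,
               cols_b: np.ndarray, phi_prior_weight: float,
               phi_fallback: float) -> dict[str, np.ndarray]:
    """Vectorised beta-binomial Wald test over rows (CpGs or regions).

    The phi median used for shrinkage is taken over the rows passed in, so the
    caller controls the shrinkage pool (per chromosome for CpGs, global for
    regions).
    """
    xa, na = meth[:, cols_a].astype(float), total[:, cols_a].astype(float)
    xb, nb = meth[:, cols_b].astype(float), total[:, cols_b].astype(float)
    ua, ub = na >= 1, nb >= 1  # usable samples
    ma, mb = ua.sum(1), ub.sum(1)
    tested = (ma >= 2) & (mb >= 2)

    sxa, sna = (xa * ua).sum(1), (na * ua).sum(1)
    sxb, snb = (xb * ub).sum(1), (nb * ub).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_a = np.where(sna > 0, sxa / np.maximum(sna, 1), np.nan)
        mu_b = np.where(snb > 0, sxb / np.maximum(snb, 1), np.nan)
        pa = np.where(ua, xa / np.maximum(na, 1), np.nan)
        pb = np.where(ub, xb / np.maximum(nb, 1), np.nan)

    # method-of-moments phi from residuals around group means:
    #   E[(p_i - mu_g)^2] ~= mu_g(1-mu_g) (phi + (1-phi)/n_i)
    ss = np.nansum((pa - mu_a[:, None]) ** 2, 1) + np.nansum((pb - mu_b[:, None]) ** 2, 1)
    va, vb = mu_a * (1 - mu_a), mu_b * (1 - mu_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_na = np.where(ua, 1.0 / np.maximum(na, 1), 0.0)
        inv_nb = np.where(ub, 1.0 / np.maximum(nb, 1), 0.0)
    bin_part = va * inv_na.sum(1) + vb * inv_nb.sum(1)
    denom = va * (ua.sum(1) - inv_na.sum(1)) + vb * (ub.sum(1) - inv_nb.sum(1))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_hat = np.where(denom > 0, (ss - bin_part) / np.where(denom > 0, denom, 1), np.nan)
    phi_hat = np.clip(phi_hat, 0.0, 0.95)

    finite = np.isfinite(phi_hat) & tested
    phi_med = float(np.median(phi_hat[finite])) if finite.any() else phi_fallback
    m = (ma + mb).astype(float)
    phi = np.where(np.isfinite(phi_hat),
                   (m * np.nan_to_num(phi_hat) + phi_prior_weight * phi_med)
                   / (m + phi_prior_weight),
                   phi_med)

    # variance of the pooled estimator; continuity-shrunk means keep SE finite
    mt_a = (sxa + 0.5) / (sna + 1.0)
    mt_b = (sxb + 0.5) / (snb + 1.0)
    wa = (na * (1 + (na - 1) * phi[:, None]) * ua).sum(1)
    wb = (nb * (1 + (nb - 1) * phi[:, None]) * ub).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a = mt_a * (1 - mt_a) * wa / np.maximum(sna, 1) ** 2
        var_b = mt_b * (1 - mt_b) * wb / np.maximum(snb, 1) ** 2
    diff = mu_b - mu_a
    se = np.sqrt(var_a + var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(diff == 0, 0.0, diff / se)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    return {"mu_a": mu_a, "mu_b": mu_b, "diff": diff, "phi": phi,
            "wald": wald, "p": p, "tested": tested, "n_used_a": ma, "n_used_b": mb}


# ---------------------------------------------------------------------------
# operations


def pooled_group_means(matrix: CpGCountMatrix, group, min_cov: int = 10,
                       per_sample: bool = False) -> pd.DataFrame:
    """Per-CpG pooled group methylation mean with a low-coverage flag.

    Pooled mean = sum(n_meth) / sum(n_total) over samples with any coverage;
    ``per_sample=True`` instead averages per-sample betas (each covered sample
    weighted equally). CpGs with pooled total below ``min_cov`` are flagged.
    """
    samples = _resolve_samples(matrix, group)
    cols = matrix.sample_index(samples)
    x, n = matrix.meth[:, cols], matrix.total[:, cols]
    pooled_n = n.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if per_sample:
            betas = np.where(n > 0, x / np.maximum(n, 1), np.nan)
            mean = np.nanmean(betas, axis=1)
        else:
            mean = np.where(pooled_n > 0, x.sum(1) / np.maximum(pooled_n, 1), np.nan)
    return pd.DataFrame({"chrom": matrix.chroms, "pos": matrix.positions,
                         "mean": mean, "pooled_total": pooled_n,
                         "low_coverage": pooled_n < min_cov})


def dmc_test(matrix: CpGCountMatrix, group_a, group_b,
             thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Per-CpG beta-binomial Wald test of group_b vs group_a (the reference).

    Returns a table of tested CpGs with mu_a, mu_b, diff, wald, p, BH q and
    ``is_dmc`` (q < fdr and |diff| >= min_diff). CpGs with fewer than two
    covered samples in either group are skipped; their count is in
    ``df.attrs['n_skipped']``.
    """
    th = thresholds or Thresholds()
    sa, sb = _resolve_samples(matrix, group_a), _resolve_samples(matrix, group_b)
    shared = set(sa) & set(sb)
    if shared:
        raise ValueError(f"groups share samples: {sorted(shared)}")
    cols_a, cols_b = matrix.sample_index(sa), matrix.sample_index(sb)

    frames = []
    n_skipped = 0
    for chrom, sl in matrix.chrom_blocks():
        res = _wald_core(matrix.meth[sl], matrix.total[sl], cols_a, cols_b,
                         th.phi_prior_weight, th.phi_fallback)
        keep = res["tested"]
        n_skipped += int((~keep).sum())
        if not keep.any():
            continue
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": matrix.positions[sl][keep],
            "mu_a": res["mu_a"][keep], "mu_b": res["mu_b"][keep],
            "diff": res["diff"][keep], "phi": res["phi"][keep],
            "wald": res["wald"][keep], "p": res["p"][keep],
        }))
    if not frames:
        raise ValueError("no testable CpGs")
    df = pd.concat(frames, ignore_index=True)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["is_dmc"] = (df["q"] < th.fdr) & (df["diff"].abs() >= th.min_diff)
    df.attrs["n_skipped"] = n_skipped
    return df


def segment_dmrs(dmcs: pd.DataFrame, matrix: CpGCountMatrix, group_a, group_b,
                 thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Chain same-direction DMCs into DMRs.

    DMCs within ``max_gap`` bp of each other and of identical sign are chained;
    a chain becomes a DMR iff the span holds more than 10 covered CpGs
    (``min_cpgs_per_dmr``), the DMC share among them is at least
    ``min_dmc_fraction``, and the span's pooled group-mean difference reaches
    ``min_diff`` with the chain's sign. A chain failing the share or
    mean-difference filter is split at its largest inter-DMC gap and the halves
    are re-examined, so an isolated stray DMC cannot drag a real region below
    threshold. Boundaries are CpG-anchored: [first pos, last pos + 2).
    """
    th = thresholds or Thresholds()
    cols = ["chrom", "start", "end", "n_cpgs", "n_dmcs", "mean_a", "mean_b",
            "diff", "direction", "stage"]
    if len(dmcs) == 0 or not dmcs["is_dmc"].any():
        return pd.DataFrame(columns=cols)
    sa, sb = _resolve_samples(matrix, group_a), _resolve_samples(matrix, group_b)
    cols_a, cols_b = matrix.sample_index(sa), matrix.sample_index(sb)

    out = []
    for chrom, sub in dmcs.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        tested_pos = sub["pos"].to_numpy()
        hits = sub[sub["is_dmc"]]
        if len(hits) == 0:
            continue
        pos = hits["pos"].to_numpy()
        sign = np.sign(hits["diff"].to_numpy())
        brk = np.flatnonzero((np.diff(pos) > th.max_gap) | (np.diff(sign) != 0)) + 1
        stack = [c for c in np.split(np.arange(len(pos)), brk)]
        while stack:
            chunk = stack.pop()
            start, end = int(pos[chunk[0]]), int(pos[chunk[-1]]) + 2
            lo = np.searchsorted(tested_pos, start - 1, side="left")
            hi = np.searchsorted(tested_pos, end, side="left")
            n_cpgs, n_dmcs = int(hi - lo), len(chunk)
            if n_cpgs < th.min_cpgs_per_dmr:
                continue

            def _split():
                if len(chunk) < 2:
                    return
                cut = int(np.argmax(np.diff(pos[chunk]))) + 1
                stack.append(chunk[cut:])
                stack.append(chunk[:cut])

            if n_dmcs / n_cpgs < th.min_dmc_fraction:
                _split()
                continue
            region = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
            idx = region_cpg_indices(matrix.chroms, matrix.positions, region)[0]
            na, nb = matrix.total[idx][:, cols_a].sum(), matrix.total[idx][:, cols_b].sum()
            if na == 0 or nb == 0:
                continue
            mean_a = matrix.meth[idx][:, cols_a].sum() / na
            mean_b = matrix.meth[idx][:, cols_b].sum() / nb
            diff = mean_b - mean_a
            if abs(diff) < th.min_diff or np.sign(diff) != sign[chunk[0]]:
                _split()
                continue
            out.append((chrom, start, end, n_cpgs, n_dmcs, mean_a, mean_b, diff,
                        "hyper" if diff > 0 else "hypo", "vs_reference"))
    out.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(out, columns=cols)


def _aggregate_region_counts(matrix: CpGCountMatrix, regions: pd.DataFrame):
    """Per-region per-sample summed (meth, total) counts over the region span."""
    idx_lists = region_cpg_indices(matrix.chroms, matrix.positions, regions)
    n_r, n_s = len(regions), len(matrix.samples)
    x = np.zeros((n_r, n_s), dtype=np.int64)
    n = np.zeros((n_r, n_s), dtype=np.int64)
    for k, idx in enumerate(idx_lists):
        if idx.size:
            x[k] = matrix.meth[idx].sum(0)
            n[k] = matrix.total[idx].sum(0)
    return x, n


def region_test(matrix: CpGCountMatrix, regions: pd.DataFrame, group_a, group_b,
                thresholds: Thresholds | None = None) -> pd.DataFrame:
    """One aggregated beta-binomial Wald test per region, group_b vs group_a.

    Counts are summed per sample over the region span before testing; BH is
    applied across regions. Shrinkage pools phi across all regions.
    """
    th = thresholds or Thresholds()
    sa, sb = _resolve_samples(matrix, group_a), _resolve_samples(matrix, group_b)
    shared = set(sa) & set(sb)
    if shared:
        raise ValueError(f"groups share samples: {sorted(shared)}")
    regions = regions.reset_index(drop=True)
    x, n = _aggregate_region_counts(matrix, regions)
    res = _wald_core(x, n, matrix.sample_index(sa), matrix.sample_index(sb),
                     th.phi_prior_weight, th.phi_fallback)
    df = regions[["chrom", "start", "end"]].copy()
    df["mu_a"], df["mu_b"] = res["mu_a"], res["mu_b"]
    df["diff"], df["wald"], df["p"] = res["diff"], res["wald"], res["p"]
    df["tested"] = res["tested"]
    df["q"] = np.nan
    if df["tested"].any():
        df.loc[df["tested"], "q"] = multipletests(
            df.loc[df["tested"], "p"], method="fdr_bh")[1]
    return df


def call_group_specific(dmrs: pd.DataFrame, matrix: CpGCountMatrix, target_group,
                        comparison_groups, excluded_groups=(),
                        thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Stage-2 specificity call: re-test stage-1 DMRs, target vs all comparison samples.

    The comparison pool is every sample of ``comparison_groups`` not in an
    excluded group; it is tested as one pooled set. A DMR is group-specific iff
    its BH-adjusted stage-2 p is below fdr, the aggregated |difference| reaches
    min_diff, and the direction matches stage 1.
    """
    th = thresholds or Thresholds()
    target = set(_resolve_samples(matrix, target_group))
    comparison: list[str] = []
    for g in ([comparison_groups] if isinstance(comparison_groups, str)
              else list(comparison_groups)):
        comparison.extend(_resolve_samples(matrix, g))
    excluded: set[str] = set()
    for g in ([excluded_groups] if isinstance(excluded_groups, str)
              else list(excluded_groups)):
        excluded.update(_resolve_samples(matrix, g))
    comparison = [s for s in dict.fromkeys(comparison) if s not in excluded]
    if set(comparison) & target:
        raise ValueError("target and comparison groups overlap")
    if not comparison:
        raise ValueError("comparison set empty after exclusions")
    if len(dmrs) == 0:
        out = dmrs.copy()
        out["stage2_p"] = out["stage2_q"] = out["stage2_diff"] = pd.Series(dtype=float)
        return out
    tested = region_test(matrix, dmrs, sorted(comparison), sorted(target), th)
    out = dmrs.reset_index(drop=True).copy()
    out["stage2_diff"] = tested["diff"]
    out["stage2_p"] = tested["p"]
    out["stage2_q"] = tested["q"]
    sign = np.where(out["direction"] == "hyper", 1.0, -1.0)
    keep = (tested["tested"].to_numpy()
            & (out["stage2_q"].to_numpy() < th.fdr)
            & (np.abs(out["stage2_diff"].to_numpy()) >= th.min_diff)
            & (np.sign(out["stage2_diff"].to_numpy()) == sign))
    out = out[keep].reset_index(drop=True)
    out["stage"] = "group_specific"
    return out


def _as_df(x) -> pd.DataFrame:
    return x.df if isinstance(x, GenomicIntervalSet) else pd.DataFrame(x)


def dmr_set_operations(set_a, set_b) -> dict:
    """Symmetric >=1 bp overlap report between two region sets."""
    from ._intervals import overlap_bp_flags
    a, b = _as_df(set_a).reset_index(drop=True), _as_df(set_b).reset_index(drop=True)
    fa = overlap_bp_flags(a, b) if len(a) and len(b) else np.zeros(len(a), bool)
    fb = overlap_bp_flags(b, a) if len(a) and len(b) else np.zeros(len(b), bool)
    return {
        "n_a": len(a), "n_b": len(b),
        "a_overlapping_b": int(fa.sum()), "b_overlapping_a": int(fb.sum()),
        "fraction_a_in_b": float(fa.mean()) if len(a) else 0.0,
        "fraction_b_in_a": float(fb.mean()) if len(b) else 0.0,
        "n_union": len(a) + len(b) - int(fb.sum()),
    }


def bin_mean_methylation(matrix: CpGCountMatrix, bin_size: int = 1000):
    """Per-sample pooled mean methylation in fixed genomic bins (complete-case).

    Bins where any sample has zero covered CpGs are dropped; the number dropped
    is returned alongside the table. The table is the input to PCA/clustering.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins = matrix.positions // bin_size
    key = pd.MultiIndex.from_arrays(
        [matrix.chroms, bins * bin_size], names=["chrom", "bin_start"])
    meth = pd.DataFrame(matrix.meth, index=key, columns=matrix.samples)
    total = pd.DataFrame(matrix.total, index=key, columns=matrix.samples)
    msum = meth.groupby(level=[0, 1]).sum()
    tsum = total.groupby(level=[0, 1]).sum()
    complete = (tsum > 0).all(axis=1)
    table = msum[complete] / tsum[complete]
    return table, int((~complete).sum())


def region_group_methylation(matrix: CpGCountMatrix, regions,
                             groups: dict[str, object]) -> pd.DataFrame:
    """Per-region pooled mean methylation for each named group.

    Regions with zero covered CpGs for a group get NaN (flagged, excluded from
    downstream fractions' denominators).
    """
    regions = _as_df(regions).reset_index(drop=True)
    x, n = _aggregate_region_counts(matrix, regions)
    out = regions[["chrom", "start", "end"]].copy()
    for name, group in groups.items():
        cols = matrix.sample_index(_resolve_samples(matrix, group))
        tot = n[:, cols].sum(1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(tot > 0, x[:, cols].sum(1) / np.maximum(tot, 1), np.nan)
    return out


def low_meth_fraction(region_means: pd.DataFrame, reference_group: str,
                      cutoff: float = 0.3) -> float:
    """Fraction of regions whose reference-group mean is below cutoff.

    Regions with undefined (NaN) reference means are excluded from the
    denominator.
    """
    vals = region_means[reference_group].to_numpy(float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("no regions with a defined reference mean")
    return float((vals[ok] < cutoff).mean())


ProfileResult = namedtuple("ProfileResult", ["offsets", "per_region", "aggregate"])


def profile_matrix(matrix: CpGCountMatrix, regions, group, flank: int = 5000,
                   bin_width: int = 100) -> ProfileResult:
    """Meta-region methylation profile over [center - flank, center + flank).

    Each region contributes a pooled-beta value per fixed-width sub-bin (NaN
    where uncovered; windows truncate silently at chromosome edges); the
    aggregate is the per-bin mean over regions. ``offsets`` are sub-bin start
    offsets relative to the region center.
    """
    regions = _as_df(regions).reset_index(drop=True)
    cols = matrix.sample_index(_resolve_samples(matrix, group))
    n_bins = (2 * flank) // bin_width
    per_region = np.full((len(regions), n_bins), np.nan)
    for k, row in enumerate(regions.itertuples(index=False)):
        center = (int(row.start) + int(row.end)) // 2
        w0 = center - flank
        window = pd.DataFrame({"chrom": [row.chrom], "start": [max(w0, 0)],
                               "end": [w0 + n_bins * bin_width]})
        idx = region_cpg_indices(matrix.chroms, matrix.positions, window)[0]
        if idx.size == 0:
            continue
        which = (matrix.positions[idx] - w0) // bin_width
        ok = (which >= 0) & (which < n_bins)
        idx, which = idx[ok], which[ok].astype(np.int64)
        msum = np.zeros(n_bins)
        tsum = np.zeros(n_bins)
        np.add.at(msum, which, matrix.meth[idx][:, cols].sum(1))
        np.add.at(tsum, which, matrix.total[idx][:, cols].sum(1))
        with np.errstate(invalid="ignore", divide="ignore"):
            per_region[k] = np.where(tsum > 0, msum / np.maximum(tsum, 1), np.nan)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN bins
        aggregate = np.nanmean(per_region, axis=0) if len(regions) else np.full(n_bins, np.nan)
    offsets = np.arange(n_bins) * bin_width - flank
    return ProfileResult(offsets, per_region, aggregate)
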