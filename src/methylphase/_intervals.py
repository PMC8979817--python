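"""Shared interval-overlap helpers (intervaltree-backed) used across modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def build_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    """One IntervalTree per chrom from a DataFrame with chrom/start/end columns."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), int(i)) for i, s, e in zip(sub.index, sub["start"], sub["end"]))
    return trees


def overlap_bp_flags(regions: pd.DataFrame, features: pd.DataFrame,
                     min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean per region: does it overlap any feature by >= min_overlap_bp?"""
    trees = build_trees(features)
    flags = np.zeros(len(regions), dtype=bool)
    for k, (chrom, start, end) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        for hit in tree.overlap(int(start), int(end)):
            if min(hit.end, int(end)) - max(hit.begin, int(start)) >= min_overlap_bp:
                flags[k] = True
                break
    return flags


def overlap_hits(regions: pd.DataFrame, features: pd.DataFrame) -> list[list[int]]:
    """Per region, the positional indices (0..len(features)-1) of overlapping features."""
    feats = features.reset_index(drop=True)
    trees = build_trees(feats)
    out: list[list[int]] = []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        tree = trees.get(str(chrom))
        if tree is None:
            out.append([])
        else:
            out.append(sorted(hit.data for hit in tree.overlap(int(start), int(end))))
    return out


def max_overlap_assignment(regions: pd.DataFrame, features: pd.DataFrame,
                           priority: dict[int, int] | None = None) -> np.ndarray:
    """Per region, the positional index of the feature with maximal bp overlap.

    Ties broken by lowest priority value (default: feature order). Regions with
    no overlap get -1.
    """
    feats = features.reset_index(drop=True)
    trees = build_trees(feats)
    assign = np.full(len(regions), -1, dtype=np.int64)
    for k, (chrom, start, end) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])):
        tree = trees.get(str(chrom))
        if tree is None:
            continue
        best_bp, best_pri, best_idx = 0, None, -1
        for hit in tree.overlap(int(start), int(end)):
            bp = min(hit.end, int(end)) - max(hit.begin, int(start))
            pri = priority[hit.data] if priority is not None else hit.data
            if bp > best_bp or (bp == best_bp and best_pri is not None and pri < best_pri):
                best_bp, best_pri, best_idx = bp, pri, hit.data
        assign[k] = best_idx
    return assign


def cpgs_in_span(chroms: np.ndarray, positions: np.ndarray,
                 chrom: str, start: int, end: int) -> np.ndarray:
    """Indices of CpGs whose dinucleotide [pos, pos+2) overlaps [start, end).

    Requires (chroms, positions) sorted with positions strictly increasing per
    chrom (the CpGCountMatrix invariant).
    """
    mask = chroms == chrom
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx
    pos = positions[idx]
    # overlap iff pos < end and pos + 2 > start  <=>  pos >= start - 1
    lo = np.searchsorted(pos, start - 1, side="left")
    hi = np.searchsorted(pos, end, side="left")
    return idx[lo:hi]


def region_cpg_indices(matrix_chroms: np.ndarray, matrix_positions: np.ndarray,
                       regions: pd.DataFrame) -> list[np.ndarray]:
    """Per-region CpG row indices (dinucleotide overlap rule), vectorised per chrom."""
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * len(regions)
    chrom_arr = np.asarray(matrix_chroms, dtype=object)
    # precompute chrom block offsets
    blocks: dict[str, tuple[int, np.ndarray]] = {}
    if len(chrom_arr):
        bounds = np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(chrom_arr)]])
        for a, b in zip(starts, ends):
            blocks[str(chrom_arr[a])] = (int(a), matrix_positions[a:b])
    for k, (chrom, start, end) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])):
        blk = blocks.get(str(chrom))
        if blk is None:
            continue
        off, pos = blk
        lo = np.searchsorted(pos, int(start) - 1, side="left")
        hi = np.searchsorted(pos, int(end), side="left")
        out[k] = np.arange(off + lo, off + hi, dtype=np.int64)
    return out
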