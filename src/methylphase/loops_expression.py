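"""Link enhancer DMRs (eDMRs) to target genes through chromatin-loop anchors
and summarise target-gene expression percentiles.

A DMR is "anchored" when it overlaps either anchor of a loop by >= 1 bp; its
candidate targets are the genes whose promoters overlap the partner anchor.
Promoters default to TSS +/- 2 kb when only gene locations are available.
Expression percentiles use the mid-rank convention, 100 * (rank - 0.5) / N,
over all expressed genes (mean TPM > 0 in the chosen sample set).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._intervals import overlap_hits
from .io_formats import ExpressionTable, GenomicIntervalSet, LoopSet

__all__ = [
    "promoters_from_genes",
    "intersect_dmr_anchors",
    "map_edmr_targets",
    "expression_percentiles",
]

PROMOTER_FLANK = 2000


def _df(x) -> pd.DataFrame:
    if isinstance(x, GenomicIntervalSet):
        return x.df
    return pd.DataFrame(x).reset_index(drop=True)


def promoters_from_genes(gene_locations: GenomicIntervalSet,
                         flank: int = PROMOTER_FLANK) -> GenomicIntervalSet:
    """TSS +/- flank promoter intervals from gene bodies (TSS = interval start)."""
    g = gene_locations.df
    return GenomicIntervalSet(pd.DataFrame({
        "chrom": g["chrom"],
        "start": np.maximum(g["start"] - flank, 0),
        "end": g["start"] + flank,
        "label": g["label"],
    }))


def intersect_dmr_anchors(dmrs, loops: LoopSet):
    """Fraction of DMRs overlapping any loop anchor, plus per-DMR anchor hits.

    Returns (fraction, hits) where hits has one row per (dmr, loop, anchor)
    overlap.
    """
    ddf = _df(dmrs).reset_index(drop=True)
    anchors = loops.anchors()
    if len(ddf) == 0 or len(anchors) == 0:
        return 0.0, pd.DataFrame(columns=["dmr", "loop", "anchor"])
    hit_lists = overlap_hits(ddf, anchors)
    rows = [(k, int(anchors.iloc[j]["loop"]), int(anchors.iloc[j]["anchor"]))
            for k, hits in enumerate(hit_lists) for j in hits]
    hits = pd.DataFrame(rows, columns=["dmr", "loop", "anchor"])
    fraction = hits["dmr"].nunique() / len(ddf)
    return float(fraction), hits


def map_edmr_targets(edmrs, loops: LoopSet, promoters: GenomicIntervalSet) -> pd.DataFrame:
    """Emit one link per (eDMR, gene) pair connected through a loop.

    For every loop whose anchor an eDMR overlaps, each gene promoter
    overlapping the partner anchor yields a link; duplicates per (dmr, gene)
    from multiple loops are dropped (first loop kept).
    """
    ddf = _df(edmrs).reset_index(drop=True)
    _, hits = intersect_dmr_anchors(ddf, loops)
    cols = ["dmr", "dmr_chrom", "dmr_start", "dmr_end", "loop", "anchor",
            "gene_id", "promoter_chrom", "promoter_start", "promoter_end"]
    if len(hits) == 0:
        return pd.DataFrame(columns=cols)
    anchors = loops.anchors().set_index(["loop", "anchor"])
    pdf = promoters.df.reset_index(drop=True)
    rows = []
    for h in hits.itertuples(index=False):
        partner = anchors.loc[(h.loop, 3 - h.anchor)]
        panchor = pd.DataFrame({"chrom": [partner["chrom"]],
                                "start": [partner["start"]], "end": [partner["end"]]})
        for j in overlap_hits(panchor, pdf)[0]:
            prom = pdf.iloc[j]
            d = ddf.iloc[h.dmr]
            rows.append((h.dmr, d["chrom"], d["start"], d["end"], h.loop, h.anchor,
                         prom["label"], prom["chrom"], prom["start"], prom["end"]))
    links = pd.DataFrame(rows, columns=cols)
    return links.drop_duplicates(subset=["dmr", "gene_id"],
                                 keep="first").reset_index(drop=True)


def expression_percentiles(expr: ExpressionTable, sample_set, target_genes):
    """Rank target genes' mean TPM among all expressed genes.

    Returns (percentiles: Series per target gene, top_quartile_fraction,
    missing: targets absent from the table or not expressed). Percentile is
    mid-rank scaled to [0, 100]; the top-quartile fraction is the share of
    rankable target genes at or above the 75th percentile.
    """
    samples = list(sample_set)
    if not samples:
        raise ValueError("sample_set must be non-empty")
    means = expr.tpm[samples].mean(axis=1)
    expressed = means[means > 0]
    if len(expressed) == 0:
        raise ValueError("no expressed genes")
    pct = pd.Series(100.0 * (rankdata(expressed.to_numpy()) - 0.5) / len(expressed),
                    index=expressed.index, name="percentile")
    targets = list(dict.fromkeys(target_genes))
    missing = [g for g in targets if g not in pct.index]
    usable = [g for g in targets if g in pct.index]
    if not usable:
        return pct.loc[[]], float("nan"), missing
    tp = pct.loc[usable]
    return tp, float((tp >= 75.0).mean()), missing
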