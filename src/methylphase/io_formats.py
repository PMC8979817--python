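"""Readers, writers and validated containers for every external file the pipeline touches.

All coordinates are 0-based half-open. A CpG is addressed by the forward-strand
position of its cytosine; for overlap purposes the dinucleotide occupies
``[pos, pos + 2)``. Input methylation tracks are biscuit-style 5-column
bedGraphs (chrom, start, end, beta, coverage); both the 1-bp and 2-bp CpG row
dialects are accepted and normalised to the cytosine start.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGCountMatrix",
    "GenomicIntervalSet",
    "LoopSet",
    "ExpressionTable",
    "MethylationParseError",
    "MethylationValidationError",
    "read_cpg_bedgraph",
    "write_cpg_bedgraph",
    "merge_samples",
    "read_sample_sheet",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_expression",
    "write_expression",
    "write_results_tables",
]

ASSAYS = ("WGBS", "oxWGBS")


class MethylationParseError(ValueError):
    """A file could not be parsed into the expected column layout."""


class MethylationValidationError(ValueError):
    """Parsed data violate a container invariant."""


def _chrom_sort_key(chroms: np.ndarray) -> np.ndarray:
    # lexicographic chromosome order; stable and convention-free
    order = {c: i for i, c in enumerate(sorted(set(chroms)))}
    return np.array([order[c] for c in chroms], dtype=np.int64)


@dataclass
class CpGCountMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``meth`` and ``total`` are integer arrays of shape (n_positions, n_samples);
    ``metadata`` is indexed by sample id with columns ``assay`` and ``group``.
    Zero-coverage cells are retained (they mean "not covered here"), and every
    statistical operation downstream excludes them by testing coverage.
    """

    chroms: np.ndarray
    positions: np.ndarray
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        self.samples = list(self.samples)
        self.validate()

    def validate(self) -> None:
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.positions) != n or len(self.chroms) != n:
            raise MethylationValidationError("count matrix shapes are inconsistent")
        if len(self.samples) != s:
            raise MethylationValidationError("sample list does not match count columns")
        if len(set(self.samples)) != s:
            raise MethylationValidationError("duplicate sample ids")
        if np.any(self.meth < 0) or np.any(self.total < 0) or np.any(self.meth > self.total):
            raise MethylationValidationError("counts must satisfy 0 <= n_meth <= n_total")
        missing = [sid for sid in self.samples if sid not in self.metadata.index]
        if missing:
            raise MethylationValidationError(f"samples missing from metadata: {missing}")
        bad_assay = set(self.metadata.loc[self.samples, "assay"]) - set(ASSAYS)
        if bad_assay:
            raise MethylationValidationError(f"unknown assay labels: {sorted(bad_assay)}")
        # strictly increasing positions within each chrom, lexicographic chrom blocks
        key = _chrom_sort_key(self.chroms)
        if n > 1:
            same = key[1:] == key[:-1]
            if np.any(key[1:] < key[:-1]):
                raise MethylationValidationError("chromosome blocks are not sorted")
            if np.any(self.positions[1:][same] <= self.positions[:-1][same]):
                raise MethylationValidationError("positions must be strictly increasing per chrom")

    # -- convenience -------------------------------------------------------

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def sample_index(self, sample_ids) -> np.ndarray:
        lut = {sid: i for i, sid in enumerate(self.samples)}
        try:
            return np.array([lut[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def group_samples(self, group: str) -> list[str]:
        meta = self.metadata.loc[self.samples]
        return [s for s in self.samples if meta.loc[s, "group"] == group]

    def betas(self) -> np.ndarray:
        """Beta values with NaN at zero-coverage cells."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def chrom_blocks(self):
        """Yield (chrom, slice) for each contiguous chromosome block."""
        if self.n_positions == 0:
            return
        bounds = np.flatnonzero(self.chroms[1:] != self.chroms[:-1]) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [self.n_positions]])
        for a, b in zip(starts, ends):
            yield str(self.chroms[a]), slice(int(a), int(b))


@dataclass
class GenomicIntervalSet:
    """A sorted set of labelled, optionally scored genomic intervals (BED semantics)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label", "score"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("label", "."), ("score", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "label", "score"]]
        df["score"] = pd.to_numeric(df["score"], errors="coerce").astype(float)
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if (df["start"] >= df["end"]).any():
                bad = df.index[df["start"] >= df["end"]][0]
                raise MethylationValidationError(f"interval with start >= end at row {bad}")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        a, b = self.df.fillna("NA"), other.df.fillna("NA")
        return a.equals(b)

    def intervals(self):
        return list(self.df.itertuples(index=False, name="Interval"))


@dataclass
class LoopSet:
    """Paired genomic anchors (BEDPE semantics); anchor1 precedes anchor2 canonically."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]))
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df[["chrom1", "start1", "end1", "chrom2", "start2", "end2"]].copy()
        if len(df):
            for c in ("start1", "end1", "start2", "end2"):
                df[c] = df[c].astype(np.int64)
            if ((df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])).any():
                raise MethylationValidationError("loop anchor with start >= end")
            # canonical anchor order within each loop
            swap = (df["chrom1"] > df["chrom2"]) | (
                (df["chrom1"] == df["chrom2"]) & (df["start1"] > df["start2"]))
            if swap.any():
                a = df.loc[swap, ["chrom1", "start1", "end1"]].to_numpy()
                df.loc[swap, ["chrom1", "start1", "end1"]] = df.loc[
                    swap, ["chrom2", "start2", "end2"]].to_numpy()
                df.loc[swap, ["chrom2", "start2", "end2"]] = a
            df = df.sort_values(["chrom1", "start1", "chrom2", "start2"],
                                kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def anchors(self) -> pd.DataFrame:
        """Long-form table of anchors: loop index, anchor index (1|2), chrom, start, end."""
        rows = []
        for i, r in enumerate(self.df.itertuples(index=False)):
            rows.append((i, 1, r.chrom1, r.start1, r.end1))
            rows.append((i, 2, r.chrom2, r.start2, r.end2))
        return pd.DataFrame(rows, columns=["loop", "anchor", "chrom", "start", "end"])


@dataclass
class ExpressionTable:
    """Gene-level TPM per sample, with optional gene locations for promoter derivation."""

    tpm: pd.DataFrame  # index gene_id, columns sample ids
    gene_locations: GenomicIntervalSet | None = None

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            raise MethylationValidationError("duplicate gene ids in expression table")
        if (self.tpm.to_numpy() < 0).any():
            raise MethylationValidationError("TPM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)


# ---------------------------------------------------------------------------
# bedGraph methylation tracks


def read_cpg_bedgraph(path: str, sample_id: str, assay: str,
                      group: str = ".") -> CpGCountMatrix:
    """Read one biscuit-style bedGraph into a single-sample count matrix.

    Columns: chrom, start, end, beta, coverage. ``end`` must be start+1 or
    start+2 (both CpG dialects accepted). n_meth is reconstructed as
    round(beta x coverage), rounding half away from zero.
    """
    if assay not in ASSAYS:
        raise MethylationValidationError(f"assay must be one of {ASSAYS}, got {assay!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "beta", "coverage"],
                         dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MethylationParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 5:
        raise MethylationParseError(f"{path}: expected 5 tab-separated columns")
    for col in ("start", "end", "coverage"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise MethylationParseError(f"{path}: non-integer {col} at line {line}")
        df[col] = vals.astype(np.int64)
    beta = pd.to_numeric(df["beta"], errors="coerce")
    if beta.isna().any():
        line = int(beta.isna().idxmax()) + 1
        raise MethylationParseError(f"{path}: non-numeric beta at line {line}")
    if ((beta < 0) | (beta > 1)).any():
        line = int(((beta < 0) | (beta > 1)).idxmax()) + 1
        raise MethylationValidationError(f"{path}: beta outside [0, 1] at line {line}")
    if (df["coverage"] < 0).any():
        line = int((df["coverage"] < 0).idxmax()) + 1
        raise MethylationValidationError(f"{path}: negative coverage at line {line}")
    width = df["end"] - df["start"]
    if ((width < 1) | (width > 2)).any():
        line = int(((width < 1) | (width > 2)).idxmax()) + 1
        raise MethylationValidationError(
            f"{path}: row width must be 1 or 2 bp (CpG dialects) at line {line}")
    if df.duplicated(subset=["chrom", "start"]).any():
        line = int(df.duplicated(subset=["chrom", "start"]).idxmax()) + 1
        raise MethylationValidationError(f"{path}: duplicate position at line {line}")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    total = df["coverage"].to_numpy(np.int64)
    # round half away from zero; beta*coverage >= 0 so floor(x + 0.5) suffices
    meth = np.floor(beta.to_numpy() * total + 0.5).astype(np.int64)
    meta = pd.DataFrame({"assay": [assay], "group": [group]}, index=[sample_id])
    meta.index.name = "sample_id"
    return CpGCountMatrix(df["chrom"].to_numpy(object), df["start"].to_numpy(np.int64),
                          [sample_id], meth[:, None], total[:, None], meta)


def write_cpg_bedgraph(matrix: CpGCountMatrix, sample_id: str, path: str) -> None:
    """Write one sample back out as a 2-bp-dialect bedGraph (beta to 6 decimals)."""
    j = matrix.sample_index([sample_id])[0]
    total = matrix.total[:, j]
    with np.errstate(invalid="ignore"):
        beta = np.where(total > 0, matrix.meth[:, j] / np.maximum(total, 1), 0.0)
    out = pd.DataFrame({
        "chrom": matrix.chroms, "start": matrix.positions,
        "end": matrix.positions + 2,
        "beta": [f"{b:.6f}" for b in beta], "coverage": total,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    """TSV with columns sample_id, assay, group (extra columns preserved)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "assay", "group"}
    if not required.issubset(sheet.columns):
        raise MethylationParseError(
            f"{path}: sample sheet needs columns {sorted(required)}")
    if sheet["sample_id"].duplicated().any():
        raise MethylationValidationError(f"{path}: duplicate sample_id in sample sheet")
    return sheet.set_index("sample_id")


def merge_samples(tracks: list[CpGCountMatrix], sample_sheet: pd.DataFrame) -> CpGCountMatrix:
    """Merge single-sample tracks over the union of positions, zero-filling gaps.

    Metadata (assay, group) is joined from the sample sheet; a track sample
    missing from the sheet, or an assay label conflicting with the track's, is
    an error.
    """
    if not tracks:
        raise MethylationValidationError("no tracks to merge")
    sample_ids: list[str] = []
    for t in tracks:
        sample_ids.extend(t.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise MethylationValidationError("duplicate sample ids across tracks")
    missing = [s for s in sample_ids if s not in sample_sheet.index]
    if missing:
        raise MethylationValidationError(f"sample ids absent from sample sheet: {missing}")
    for t in tracks:
        for s in t.samples:
            if str(sample_sheet.loc[s, "assay"]) != str(t.metadata.loc[s, "assay"]):
                raise MethylationValidationError(f"conflicting assay labels for sample {s!r}")
    key_frames = [pd.DataFrame({"chrom": t.chroms, "pos": t.positions}) for t in tracks]
    univ = (pd.concat(key_frames).drop_duplicates()
            .sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True))
    n = len(univ)
    lut = {(c, p): i for i, (c, p) in enumerate(zip(univ["chrom"], univ["pos"]))}
    meth = np.zeros((n, len(sample_ids)), dtype=np.int64)
    total = np.zeros((n, len(sample_ids)), dtype=np.int64)
    col = 0
    for t in tracks:
        rows = np.array([lut[(c, p)] for c, p in zip(t.chroms, t.positions)], dtype=np.int64)
        for j in range(len(t.samples)):
            meth[rows, col] = t.meth[:, j]
            total[rows, col] = t.total[:, j]
            col += 1
    meta = sample_sheet.loc[sample_ids, ["assay", "group"]].copy()
    return CpGCountMatrix(univ["chrom"].to_numpy(object), univ["pos"].to_numpy(np.int64),
                          sample_ids, meth, total, meta)


# ---------------------------------------------------------------------------
# BED / BEDPE / expression


def read_bed(path: str) -> GenomicIntervalSet:
    """Read BED3/BED6+ (name -> label, score column optional). Empty file -> empty set."""
    if os.path.getsize(path) == 0:
        return GenomicIntervalSet()
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise MethylationParseError(f"{path}: BED needs >= 3 columns")
    out = pd.DataFrame({"chrom": df[0].astype(str)})
    for i, col in ((1, "start"), (2, "end")):
        vals = pd.to_numeric(df[i], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            raise MethylationParseError(
                f"{path}: non-integer {col} at line {int(bad.idxmax()) + 1}")
        out[col] = vals.astype(np.int64)
    out["label"] = df[3].astype(str) if df.shape[1] > 3 else "."
    out["score"] = pd.to_numeric(df[4], errors="coerce") if df.shape[1] > 4 else np.nan
    if (out["start"] >= out["end"]).any():
        line = int((out["start"] >= out["end"]).idxmax()) + 1
        raise MethylationValidationError(f"{path}: start >= end at line {line}")
    return GenomicIntervalSet(out)


def write_bed(iset: GenomicIntervalSet, path: str) -> None:
    df = iset.df.copy()
    df["score"] = df["score"].map(lambda v: "." if pd.isna(v) else f"{v:g}")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str, provenance: str = "") -> LoopSet:
    if os.path.getsize(path) == 0:
        return LoopSet(provenance=provenance)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 6:
        raise MethylationParseError(f"{path}: BEDPE needs >= 6 columns")
    out = pd.DataFrame({
        "chrom1": df[0].astype(str), "start1": df[1], "end1": df[2],
        "chrom2": df[3].astype(str), "start2": df[4], "end2": df[5],
    })
    for c in ("start1", "end1", "start2", "end2"):
        vals = pd.to_numeric(out[c], errors="coerce")
        if vals.isna().any():
            raise MethylationParseError(f"{path}: non-integer {c}")
        out[c] = vals.astype(np.int64)
    return LoopSet(out, provenance=provenance)


def write_bedpe(loops: LoopSet, path: str) -> None:
    loops.df.to_csv(path, sep="\t", header=False, index=False)


def read_expression(path: str, gene_bed: str | None = None) -> ExpressionTable:
    """TSV: gene_id column then one TPM column per sample; optional gene-model BED."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise MethylationParseError(f"{path}: first column must be gene_id")
    tpm = df.set_index("gene_id").astype(float)
    locs = read_bed(gene_bed) if gene_bed else None
    return ExpressionTable(tpm, locs)


def write_expression(expr: ExpressionTable, path: str) -> None:
    expr.tpm.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def write_results_tables(records: dict[str, pd.DataFrame], out_dir: str,
                         manifest: dict | None = None) -> None:
    """Write named result tables as TSV into out_dir, plus an optional JSON manifest.

    DMR-style tables (with chrom/start/end leading columns) are BED-compatible:
    coordinate columns come first, extras follow.
    """
    os.makedirs(out_dir, exist_ok=True)
    for name, df in records.items():
        cols = list(df.columns)
        lead = [c for c in ("chrom", "start", "end") if c in cols]
        df = df[lead + [c for c in cols if c not in lead]]
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False,
                  float_format="%.6g")
    if manifest is not None:
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
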