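"""Readers and writers for the on-disk formats the toolkit touches.

Per-cytosine methylation calls travel as Bismark-style CX cytosine
reports (7-column TSV, 1-based positions), optionally gzip-compressed,
or as BS-Seeker2 CGmap files which are converted on ingest.  Gene
annotation is read from genePred or BED12.  Interval outputs are
standard BED / bedGraph.  Internally every coordinate is 0-based
half-open; 1-based coordinates exist only at the file boundary.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")

#: column order of the in-memory per-cytosine call table
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth",
                "trinucleotide"]

_FILE_CONTEXT = {"CG": "CpG", "CHG": "CHG", "CHH": "CHH"}
_MEM_CONTEXT = {v: k for k, v in _FILE_CONTEXT.items()}


class ReportParseError(ValueError):
    """A call file line could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violates a format or model invariant."""


@dataclass
class CytosineCallSet:
    """Per-cytosine methylated/unmethylated call counts.

    ``df`` holds one row per (chrom, pos, strand) with columns
    ``chrom, pos, strand, context, n_meth, n_unmeth, trinucleotide``,
    sorted by (chrom, pos, strand).  Positions are 0-based.
    """

    df: pd.DataFrame
    source_label: str = ""

    def __post_init__(self) -> None:
        self.df = _normalize_calls(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CytosineCallSet):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(
            other.df.reset_index(drop=True))


@dataclass
class GeneModel:
    """One transcript: 0-based half-open span plus exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValidationError(
                f"{self.gene_id}: invalid span [{self.tx_start},{self.tx_end})")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        merged: list[tuple[int, int]] = []
        for s, e in exons:
            if s >= e:
                raise ValidationError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValidationError(
                    f"{self.gene_id}: exon [{s},{e}) outside transcript span")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.exons = merged


def _normalize_calls(df: pd.DataFrame) -> pd.DataFrame:
    df = df[CALL_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise ValidationError("negative call counts")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValidationError(
            f"unknown context {df.loc[bad, 'context'].iloc[0]!r}")
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable",
                        ignore_index=True)
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate call at {r.chrom}:{r.pos}({r.strand})")
    return df


def _open_text(path) -> _stdio.TextIOBase:
    # gzip detected by magic bytes, not extension
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cytosine_report(path, source_label: str | None = None) -> CytosineCallSet:
    """Read a Bismark-style CX cytosine report (optionally gzipped).

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context (CG/CHG/CHH), trinucleotide.  Positions
    are converted to 0-based; zero-coverage rows are retained; unsorted
    input is sorted silently.
    """
    path = Path(path)
    try:
        with _open_text(path) as fh:
            raw = pd.read_csv(
                fh, sep="\t", header=None, dtype=str,
                names=["chrom", "pos", "strand", "n_meth", "n_unmeth",
                       "context", "trinucleotide"],
                keep_default_na=False, comment=None)
    except pd.errors.ParserError as exc:
        raise ReportParseError(f"{path}: {exc}") from exc
    if raw.empty:
        return CytosineCallSet(pd.DataFrame(columns=CALL_COLUMNS),
                               source_label or path.name)

    def _fail(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ReportParseError(f"{path}, line {line}: {what}")

    _fail(raw["trinucleotide"] == "", "expected 7 tab-separated columns")
    for col in ("pos", "n_meth", "n_unmeth"):
        _fail(~raw[col].str.fullmatch(r"\d+"), f"non-integer {col}")
    _fail(~raw["strand"].isin(["+", "-"]), "strand not '+' or '-'")
    _fail(~raw["context"].isin(_FILE_CONTEXT), "context not CG/CHG/CHH")

    df = pd.DataFrame({
        "chrom": raw["chrom"],
        "pos": raw["pos"].astype(np.int64) - 1,
        "strand": raw["strand"],
        "context": raw["context"].map(_FILE_CONTEXT),
        "n_meth": raw["n_meth"].astype(np.int64),
        "n_unmeth": raw["n_unmeth"].astype(np.int64),
        "trinucleotide": raw["trinucleotide"],
    })
    return CytosineCallSet(df, source_label or path.name)


def write_cytosine_report(calls: CytosineCallSet, path) -> None:
    """Write the 7-column, 1-based cytosine-report dialect."""
    out = calls.df.copy()
    out["pos"] = out["pos"] + 1
    out["context"] = out["context"].map(_MEM_CONTEXT)
    out[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context",
         "trinucleotide"]].to_csv(path, sep="\t", header=False, index=False)


_CGMAP_TRINUC = {"CpG": "CGN", "CHG": "CNG", "CHH": "CNN"}


def convert_cgmap_to_calls(path, source_label: str | None = None) -> CytosineCallSet:
    """Convert a BS-Seeker2 CGmap file to a :class:`CytosineCallSet`.

    CGmap columns: chrom, nucleotide (C on '+', G on '-'), 1-based pos,
    context, dinucleotide, level, methylated count, total count.  The
    strand is inferred from the nucleotide column and
    ``n_unmeth = total - methylated``.  CGmap carries no trinucleotide;
    a context-consistent placeholder containing N is emitted.
    """
    path = Path(path)
    with _open_text(path) as fh:
        raw = pd.read_csv(
            fh, sep="\t", header=None, dtype=str,
            names=["chrom", "nuc", "pos", "context", "dinuc", "level",
                   "n_meth", "n_total"],
            keep_default_na=False)
    if raw.empty:
        return CytosineCallSet(pd.DataFrame(columns=CALL_COLUMNS),
                               source_label or path.name)
    bad = ~raw["nuc"].isin(["C", "G"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ReportParseError(
            f"{path}, line {line}: unknown nucleotide "
            f"{raw.loc[bad, 'nuc'].iloc[0]!r}")
    bad = ~raw["context"].isin(_FILE_CONTEXT)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ReportParseError(f"{path}, line {line}: bad context")
    n_meth = raw["n_meth"].astype(np.int64)
    n_total = raw["n_total"].astype(np.int64)
    if (n_total < n_meth).any():
        raise ValidationError(f"{path}: total count below methylated count")
    context = raw["context"].map(_FILE_CONTEXT)
    df = pd.DataFrame({
        "chrom": raw["chrom"],
        "pos": raw["pos"].astype(np.int64) - 1,
        "strand": np.where(raw["nuc"] == "C", "+", "-"),
        "context": context,
        "n_meth": n_meth,
        "n_unmeth": n_total - n_meth,
        "trinucleotide": context.map(_CGMAP_TRINUC),
    })
    return CytosineCallSet(df, source_label or path.name)


def read_gene_annotation(path, dialect: str) -> list[GeneModel]:
    """Read transcript models from a genePred or BED12 file.

    Returns one :class:`GeneModel` per record, exons normalized to
    sorted non-overlapping 0-based half-open intervals.  Duplicate
    gene_ids are allowed (multiple transcripts of one gene).
    """
    if dialect not in ("genePred", "BED12"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if dialect == "genePred":
                    if len(f) < 10:
                        raise ValueError("expected >= 10 genePred columns")
                    name, chrom, strand = f[0], f[1], f[2]
                    tx_start, tx_end = int(f[3]), int(f[4])
                    starts = [int(x) for x in f[8].rstrip(",").split(",")]
                    ends = [int(x) for x in f[9].rstrip(",").split(",")]
                    exons = list(zip(starts, ends))
                else:
                    if len(f) < 12:
                        raise ValueError("expected 12 BED12 columns")
                    chrom, name, strand = f[0], f[3], f[5]
                    tx_start, tx_end = int(f[1]), int(f[2])
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offs = [int(x) for x in f[11].rstrip(",").split(",")]
                    if len(sizes) != len(offs) or len(sizes) != int(f[9]):
                        raise ValueError("blockCount mismatch")
                    exons = [(tx_start + o, tx_start + o + s)
                             for o, s in zip(offs, sizes)]
                genes.append(GeneModel(name, chrom, strand, tx_start, tx_end,
                                       exons))
            except (ValueError, IndexError) as exc:
                raise ReportParseError(
                    f"{path}, line {lineno}: {exc}") from exc
    return genes


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes file into an ordered dict."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 2:
                raise ReportParseError(
                    f"{path}, line {lineno}: expected 2 columns")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write a labeled interval table as BED (0-based half-open).

    ``intervals`` needs columns chrom/start/end/name and optionally a
    score in [0, 1000]; output is sorted by (chrom, start).
    """
    df = intervals.copy()
    if (df["start"] >= df["end"]).any():
        raise ValidationError("BED interval with start >= end")
    if "score" in df.columns:
        score = pd.to_numeric(df["score"])
        if ((score < 0) | (score > 1000)).any():
            raise ValidationError("BED score outside [0, 1000]")
        cols = ["chrom", "start", "end", "name", "score"]
        if "strand" in df.columns:
            cols.append("strand")
    else:
        cols = ["chrom", "start", "end", "name"]
    df = df.sort_values(["chrom", "start"], kind="stable")
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED back into a chrom/start/end/name[/score] frame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:4])
    df.columns = names[: df.shape[1]]
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write per-interval values as 4-column bedGraph.

    Intervals must be non-overlapping; rows with a missing (NaN) value
    are omitted, mirroring the no-data convention of genome browsers.
    """
    df = track[["chrom", "start", "end", "value"]].copy()
    df = df.sort_values(["chrom", "start"], kind="stable")
    prev_end = df.groupby("chrom")["end"].shift()
    if ((df["start"] < prev_end).fillna(False)).any():
        raise ValidationError("overlapping bedGraph intervals")
    df = df[df["value"].notna()]
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.6g")
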