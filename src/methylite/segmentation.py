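"""Hypomethylated-region segmentation of the destranded CpG track.

Two classes of hypomethylated regions (HMRs) are called: unmethylated
regions (UMRs), CpG-dense stretches at near-zero methylation such as
promoter CpG islands, and low-methylated regions (LMRs), CpG-poorer
stretches at intermediate (~30%) methylation.  Segmentation is an
explicit threshold-run scan: per-CpG levels are smoothed with a short
centered running mean, runs of smoothed levels below the LMR ceiling
with enough CpGs become segments, and each segment is classified by its
mean raw level.  The class boundaries are this toolkit's definitions,
chosen to match the field's verbal characterization of UMRs ("almost
zero") and LMRs ("around 30%"); all five tuning constants live in
:class:`~methylite.params.AnalysisParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import overlap_join
from .params import AnalysisParams
from .profiling import GenomicContexts, MethylationTrack

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["chrom", "start", "end", "kind", "n_cpg", "mean_level"]


@dataclass
class SegmentSet:
    """Non-overlapping UMR/LMR segments sorted by (chrom, start)."""

    df: pd.DataFrame  # SEGMENT_COLUMNS
    params: AnalysisParams

    def __len__(self) -> int:
        return len(self.df)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)

    def to_bed_frame(self) -> pd.DataFrame:
        df = self.df.copy()
        df["name"] = df["kind"]
        df["score"] = np.round(1000 * (1 - df["mean_level"])).astype(int)
        return df[["chrom", "start", "end", "name", "score"]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind in ("UMR", "LMR"):
            sub = self.of_kind(kind)
            rows.append({
                "kind": kind,
                "count": len(sub),
                "mean_length": float((sub["end"] - sub["start"]).mean())
                if len(sub) else float("nan"),
                "mean_n_cpg": float(sub["n_cpg"].mean())
                if len(sub) else float("nan"),
                "mean_level": float(sub["mean_level"].mean())
                if len(sub) else float("nan"),
            })
        return pd.DataFrame(rows)


def smooth_levels(levels: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over k consecutive values; edges shrink."""
    s = pd.Series(levels)
    return s.rolling(k, center=True, min_periods=1).mean().to_numpy()


def segment_hmrs(cpg_track: MethylationTrack,
                 params: AnalysisParams | None = None) -> SegmentSet:
    """Call UMR/LMR segments from a destranded CpG track.

    Only CpG units with coverage >= ``min_coverage`` are considered.
    Per chromosome: smooth levels with a centered running mean over
    ``seg_smooth_k`` CpGs, mark CpGs with smoothed level below
    ``lmr_max_level``, turn maximal marked runs of >= ``seg_min_cpgs``
    CpGs into segments spanning first to last CpG (half-open end), and
    classify by mean raw level: below ``umr_max_level`` -> UMR,
    otherwise LMR.  Chromosomes with fewer covered CpGs than the
    smoothing width are skipped with a warning.
    """
    params = params or AnalysisParams()
    df = cpg_track.df
    df = df[(df["context"] == "CpG")
            & (df["n_meth"] + df["n_unmeth"] >= params.min_coverage)
            & df["level"].notna()]
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        lvl = grp["level"].to_numpy()
        if len(pos) < params.seg_smooth_k:
            logger.warning("chromosome %s: only %d covered CpGs, skipped",
                           chrom, len(pos))
            continue
        marked = smooth_levels(lvl, params.seg_smooth_k) < params.lmr_max_level
        # maximal runs of marked CpGs
        edges = np.diff(np.concatenate([[0], marked.view(np.int8), [0]]))
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1)
        for a, b in zip(run_starts, run_ends):
            if b - a < params.seg_min_cpgs:
                continue
            mean_raw = float(lvl[a:b].mean())
            kind = "UMR" if mean_raw < params.umr_max_level else "LMR"
            rows.append((chrom, int(pos[a]), int(pos[b - 1]) + 1, kind,
                         int(b - a), mean_raw))
    out = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    out = out.sort_values(["chrom", "start"], kind="stable",
                          ignore_index=True)
    return SegmentSet(out, params)


def overlap_umrs_promoters(segments: SegmentSet,
                           contexts: GenomicContexts) -> pd.DataFrame:
    """UMRs overlapping a promoter by >= 1 bp, annotated with gene ids.

    Returns one row per overlapping UMR with a comma-joined ``gene_ids``
    column; ``len(result)`` is the reported count.
    """
    umrs = segments.of_kind("UMR")
    if len(umrs) == 0 or len(contexts.promoters) == 0:
        return pd.DataFrame(columns=[*SEGMENT_COLUMNS, "gene_ids"])
    pairs = overlap_join(umrs, contexts.promoters)
    if len(pairs) == 0:
        return pd.DataFrame(columns=[*SEGMENT_COLUMNS, "gene_ids"])
    prom = contexts.promoters.reset_index(drop=True)
    pairs["gene_id"] = prom["gene_id"].to_numpy()[pairs["right_index"]]
    gene_lists = (pairs.groupby("left_index")["gene_id"]
                  .apply(lambda s: ",".join(sorted(set(s)))))
    out = umrs.loc[gene_lists.index].copy()
    out["gene_ids"] = gene_lists
    return out.sort_values(["chrom", "start"], ignore_index=True)
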