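"""Sample-level methylation tracks and profiles.

The methylation level of a site is the ratio of methylated call counts
to total call counts at that site.  From a replicate-merged track the
module derives: per-CX-context summaries (mean level + 10% histogram),
fixed-width genome bins, the five genomic context classes (promoter,
gene, exon, intron, intergenic) with their mean levels, and TSS
sliding-window metaprofiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import mask_sites, merge_intervals, subtract_intervals
from .io import CONTEXTS, CytosineCallSet, GeneModel, ValidationError
from .params import AnalysisParams

TRACK_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth",
                 "level"]


@dataclass
class MethylationTrack:
    """Per-site methylation levels; ``level`` is NaN at zero coverage."""

    df: pd.DataFrame
    sample_label: str = ""

    def __len__(self) -> int:
        return len(self.df)

    @property
    def covered(self) -> pd.DataFrame:
        return self.df[self.df["level"].notna()]

    def filter_context(self, context: str) -> "MethylationTrack":
        return MethylationTrack(
            self.df[self.df["context"] == context].reset_index(drop=True),
            self.sample_label)


@dataclass
class ContextSummary:
    """Mean level, 10-bin level histogram and site count per CX context."""

    mean_level: dict[str, float]        # NaN when no covered sites
    histogram: dict[str, np.ndarray]    # 10 counts per context
    n_covered: dict[str, int]
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 11))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in CONTEXTS:
            rows.append({"context": ctx, "mean_level": self.mean_level[ctx],
                         "n_covered": self.n_covered[ctx]})
        return pd.DataFrame(rows)

    def histogram_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in CONTEXTS:
            for i in range(10):
                rows.append({
                    "context": ctx,
                    "bin_low": self.bin_edges[i],
                    "bin_high": self.bin_edges[i + 1],
                    "count": int(self.histogram[ctx][i]),
                })
        return pd.DataFrame(rows)


@dataclass
class BinnedTrack:
    """Fixed-size genome bins with per-bin mean level and site count.

    Bins tile every chromosome; a bin with no covered sites has NaN
    mean and ``n_sites`` 0.
    """

    df: pd.DataFrame  # chrom, start, end, n_sites, mean_level
    context: str
    bin_size: int

    def to_bedgraph_frame(self) -> pd.DataFrame:
        return self.df.rename(columns={"mean_level": "value"})[
            ["chrom", "start", "end", "value"]]


@dataclass
class GenomicContexts:
    """Promoter / gene / exon / intron / intergenic interval sets.

    Promoters and gene bodies carry gene_id and strand; exons and
    introns carry gene_id; intergenic is the genome minus transcripts.
    ``tss`` has one row per gene with the strand-aware TSS position.
    """

    chrom_sizes: dict[str, int]
    promoters: pd.DataFrame
    gene_bodies: pd.DataFrame
    merged_exons: pd.DataFrame
    introns: pd.DataFrame
    intergenic: pd.DataFrame
    tss: pd.DataFrame

    CLASSES = ("promoter", "gene", "exon", "intron", "intergenic")

    def class_intervals(self, cls: str) -> pd.DataFrame:
        return {"promoter": self.promoters, "gene": self.gene_bodies,
                "exon": self.merged_exons, "intron": self.introns,
                "intergenic": self.intergenic}[cls]


@dataclass
class MetaProfile:
    """TSS-relative sliding-window methylation profile.

    ``rel_starts[i]`` is the TSS-relative start of window i (window 1 is
    the most upstream regardless of strand); ``per_gene`` is an
    (n_genes, n_windows) array of window means (NaN where a gene has no
    covered site or the window leaves the chromosome); ``mean`` is the
    across-gene mean per window ignoring NaN.
    """

    rel_starts: np.ndarray
    window: int
    gene_ids: list[str]
    per_gene: np.ndarray
    mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"w{i + 1}": self.per_gene[:, i]
                for i in range(len(self.rel_starts))}
        df = pd.DataFrame({"gene_id": self.gene_ids, **cols})
        agg = pd.DataFrame([{"gene_id": "__mean__",
                             **{f"w{i + 1}": self.mean[i]
                                for i in range(len(self.rel_starts))}}])
        return pd.concat([df, agg], ignore_index=True)


# ---------------------------------------------------------------------------
# track construction

def merge_replicates(replicates: list[CytosineCallSet],
                     label: str = "") -> CytosineCallSet:
    """Sum call counts across replicates at identical (chrom, pos, strand).

    The context must agree across replicates at each position; the
    trinucleotide is taken from the first replicate carrying the site.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    if len(replicates) == 1:
        rep = replicates[0]
        return CytosineCallSet(rep.df.copy(), label or rep.source_label)
    cat = pd.concat([r.df for r in replicates], ignore_index=True)
    grouped = cat.groupby(["chrom", "pos", "strand"], sort=False)
    if (grouped["context"].nunique() > 1).any():
        n = grouped["context"].nunique()
        key = n[n > 1].index[0]
        raise ValidationError(
            f"context disagreement across replicates at {key}")
    out = grouped.agg(
        context=("context", "first"),
        n_meth=("n_meth", "sum"),
        n_unmeth=("n_unmeth", "sum"),
        trinucleotide=("trinucleotide", "first"),
    ).reset_index()
    return CytosineCallSet(out, label or "+".join(
        r.source_label for r in replicates))


def build_track(calls: CytosineCallSet) -> MethylationTrack:
    """Compute per-site levels; zero-coverage sites get NaN."""
    df = calls.df.copy()
    total = (df["n_meth"] + df["n_unmeth"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, df["n_meth"].to_numpy() / total, np.nan)
    df["level"] = level
    return MethylationTrack(df, calls.source_label)


def destrand_cpg(track: MethylationTrack) -> MethylationTrack:
    """Pool symmetric CpG strand pairs into one '+'-anchored unit.

    A '+' CpG at position p pairs with the '-' CpG at p+1; counts are
    summed and anchored at p.  Unpaired CpG sites and all non-CpG
    contexts pass through unchanged.
    """
    df = track.df
    is_cpg = df["context"] == "CpG"
    other = df[~is_cpg]
    plus = df[is_cpg & (df["strand"] == "+")].copy()
    minus = df[is_cpg & (df["strand"] == "-")].copy()
    minus["anchor"] = minus["pos"] - 1
    merged = plus.merge(
        minus, left_on=["chrom", "pos"], right_on=["chrom", "anchor"],
        how="outer", suffixes=("_p", "_m"), indicator=True)

    both = merged[merged["_merge"] == "both"]
    paired = pd.DataFrame({
        "chrom": both["chrom"],
        "pos": both["pos_p"].astype(np.int64),
        "strand": "+",
        "context": "CpG",
        "n_meth": (both["n_meth_p"] + both["n_meth_m"]).astype(np.int64),
        "n_unmeth": (both["n_unmeth_p"] + both["n_unmeth_m"]).astype(np.int64),
        "trinucleotide": both["trinucleotide_p"],
    })
    lone_p = merged[merged["_merge"] == "left_only"]
    lone_plus = pd.DataFrame({
        "chrom": lone_p["chrom"], "pos": lone_p["pos_p"].astype(np.int64),
        "strand": "+", "context": "CpG",
        "n_meth": lone_p["n_meth_p"].astype(np.int64),
        "n_unmeth": lone_p["n_unmeth_p"].astype(np.int64),
        "trinucleotide": lone_p["trinucleotide_p"],
    })
    lone_m = merged[merged["_merge"] == "right_only"]
    lone_minus = pd.DataFrame({
        "chrom": lone_m["chrom"], "pos": lone_m["pos_m"].astype(np.int64),
        "strand": "-", "context": "CpG",
        "n_meth": lone_m["n_meth_m"].astype(np.int64),
        "n_unmeth": lone_m["n_unmeth_m"].astype(np.int64),
        "trinucleotide": lone_m["trinucleotide_m"],
    })
    out = pd.concat(
        [other[["chrom", "pos", "strand", "context", "n_meth", "n_unmeth",
                "trinucleotide"]], paired, lone_plus, lone_minus],
        ignore_index=True)
    total = (out["n_meth"] + out["n_unmeth"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(total > 0,
                                out["n_meth"].to_numpy() / total, np.nan)
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable",
                          ignore_index=True)
    return MethylationTrack(out, track.sample_label)


# ---------------------------------------------------------------------------
# profiles

def summarize_contexts(track: MethylationTrack,
                       params: AnalysisParams | None = None) -> ContextSummary:
    """Per-context mean level and 10-bin histogram over covered sites.

    Histogram bins are left-closed right-open except the last, which is
    closed at 1.0 (numpy.histogram convention), so a fully methylated
    site counts in the [0.9, 1.0] bin.
    """
    params = params or AnalysisParams()
    edges = np.arange(0.0, 1.0 + params.hist_bin / 2, params.hist_bin)
    cov = track.covered
    means, hists, counts = {}, {}, {}
    for ctx in CONTEXTS:
        levels = cov.loc[cov["context"] == ctx, "level"].to_numpy()
        counts[ctx] = levels.size
        means[ctx] = float(levels.mean()) if levels.size else float("nan")
        hists[ctx] = np.histogram(levels, bins=edges)[0]
    return ContextSummary(means, hists, counts, edges)


def bin_genome(track: MethylationTrack, context: str,
               params: AnalysisParams, chrom_sizes: dict[str, int]
               ) -> BinnedTrack:
    """Mean level of covered sites of one context in fixed genome bins."""
    cov = track.covered
    cov = cov[cov["context"] == context]
    for chrom, grp in cov.groupby("chrom"):
        if chrom not in chrom_sizes:
            raise ValidationError(f"chromosome {chrom!r} not in chrom sizes")
        if (grp["pos"] >= chrom_sizes[chrom]).any():
            raise ValidationError(f"site beyond end of {chrom}")
    rows = []
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / params.bin_size)) if size else 0
        starts = np.arange(n_bins, dtype=np.int64) * params.bin_size
        ends = np.minimum(starts + params.bin_size, size)
        sums = np.zeros(n_bins)
        cnts = np.zeros(n_bins, dtype=np.int64)
        grp = cov[cov["chrom"] == chrom]
        if len(grp):
            idx = grp["pos"].to_numpy() // params.bin_size
            np.add.at(sums, idx, grp["level"].to_numpy())
            np.add.at(cnts, idx, 1)
        with np.errstate(invalid="ignore"):
            mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_sites": cnts, "mean_level": mean}))
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "mean_level"]))
    return BinnedTrack(df, context, params.bin_size)


def derive_genomic_contexts(genes: list[GeneModel],
                            chrom_sizes: dict[str, int],
                            params: AnalysisParams | None = None
                            ) -> GenomicContexts:
    """Derive the five genomic context classes from transcript models.

    A gene is the union span of all transcripts sharing a gene_id; its
    promoter is the strand-aware upstream window anchored at the 5'-most
    TSS, clamped to the chromosome.  Merged exons are the per-gene union
    of all transcripts' exons; introns are the gene span minus exons;
    intergenic is the genome minus all transcript spans.
    """
    params = params or AnalysisParams()
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValidationError(
                f"gene {g.gene_id} on {g.chrom!r} absent from chrom sizes")

    by_gene: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault((g.gene_id, g.chrom), []).append(g)

    prom_rows, body_rows, exon_rows, intron_rows, tss_rows = [], [], [], [], []
    for (gene_id, chrom), txs in sorted(by_gene.items()):
        strand = txs[0].strand
        if any(t.strand != strand for t in txs):
            raise ValidationError(f"gene {gene_id}: transcripts on both strands")
        span_s = min(t.tx_start for t in txs)
        span_e = max(t.tx_end for t in txs)
        size = chrom_sizes[chrom]
        if strand == "+":
            tss = span_s
            p_s, p_e = max(0, span_s - params.promoter_len), span_s
        else:
            tss = span_e - 1
            p_s, p_e = span_e, min(size, span_e + params.promoter_len)
        if p_s < p_e:
            prom_rows.append((chrom, p_s, p_e, gene_id, strand))
        body_rows.append((chrom, span_s, span_e, gene_id, strand))
        tss_rows.append((gene_id, chrom, tss, strand))
        ex_s, ex_e = merge_intervals(
            [s for t in txs for s, _ in t.exons],
            [e for t in txs for _, e in t.exons])
        for s, e in zip(ex_s, ex_e):
            exon_rows.append((chrom, int(s), int(e), gene_id))
        in_s, in_e = subtract_intervals(
            np.array([span_s]), np.array([span_e]), ex_s, ex_e)
        for s, e in zip(in_s, in_e):
            intron_rows.append((chrom, int(s), int(e), gene_id))

    def _frame(rows, cols):
        df = pd.DataFrame(rows, columns=cols)
        return df.sort_values(["chrom", "start"], kind="stable",
                              ignore_index=True)

    promoters = _frame(prom_rows, ["chrom", "start", "end", "gene_id",
                                   "strand"])
    gene_bodies = _frame(body_rows, ["chrom", "start", "end", "gene_id",
                                     "strand"])
    merged_exons = _frame(exon_rows, ["chrom", "start", "end", "gene_id"])
    introns = _frame(intron_rows, ["chrom", "start", "end", "gene_id"])

    inter_rows = []
    tx_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        tx_by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
    for chrom, size in chrom_sizes.items():
        spans = tx_by_chrom.get(chrom, [])
        s, e = subtract_intervals(
            np.array([0]), np.array([size]),
            np.array([x for x, _ in spans]), np.array([y for _, y in spans]))
        for a, b in zip(s, e):
            inter_rows.append((chrom, int(a), int(b)))
    intergenic = _frame(inter_rows, ["chrom", "start", "end"])
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"])
    return GenomicContexts(dict(chrom_sizes), promoters, gene_bodies,
                           merged_exons, introns, intergenic, tss)


def context_level_summary(track: MethylationTrack, contexts: GenomicContexts,
                          context: str = "CpG") -> pd.DataFrame:
    """Mean level of covered sites of one CX context per region class.

    Classes are non-exclusive except intergenic: a promoter site inside
    a neighboring gene counts in both classes, but the intergenic class
    excludes promoter positions so it stays free of gene-linked signal
    (the interval set itself is the plain transcript complement).
    """
    cov = track.covered
    cov = cov[cov["context"] == context].reset_index(drop=True)
    in_promoter = mask_sites(cov, contexts.promoters)
    rows = []
    for cls in GenomicContexts.CLASSES:
        iv = contexts.class_intervals(cls)
        mask = mask_sites(cov, iv)
        if cls == "intergenic":
            mask &= ~in_promoter
        levels = cov.loc[mask, "level"]
        rows.append({"region_class": cls,
                     "mean_level": float(levels.mean()) if len(levels)
                     else float("nan"),
                     "n_sites": int(mask.sum())})
    return pd.DataFrame(rows)


def tss_metaprofile(track: MethylationTrack, contexts: GenomicContexts,
                    params: AnalysisParams | None = None,
                    context: str = "CpG") -> MetaProfile:
    """Sliding-window methylation profile around every gene's TSS.

    Windows are oriented by strand: window 1 is the most upstream window
    for the gene regardless of genomic direction.  Windows that extend
    past a chromosome edge are missing for that gene, as are windows
    with no covered site.
    """
    params = params or AnalysisParams()
    nw = params.n_windows
    rel_starts = -params.tss_flank + params.step * np.arange(nw)
    cov = track.covered
    cov = cov[cov["context"] == context]
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in cov.groupby("chrom")}
    lvl_by_chrom = {}
    for c, g in cov.groupby("chrom"):
        order = np.argsort(g["pos"].to_numpy(), kind="stable")
        lvl_by_chrom[c] = g["level"].to_numpy()[order]

    gene_ids = contexts.tss["gene_id"].tolist()
    per_gene = np.full((len(gene_ids), nw), np.nan)
    for gi, row in enumerate(contexts.tss.itertuples(index=False)):
        size = contexts.chrom_sizes[row.chrom]
        pos = pos_by_chrom.get(row.chrom)
        for wi, rs in enumerate(rel_starts):
            re_ = rs + params.window
            if row.strand == "+":
                g_s, g_e = row.pos + rs, row.pos + re_
            else:
                # relative coordinate r = tss - g; r in [rs, re) maps to
                # g in [tss - re + 1, tss - rs + 1)
                g_s, g_e = row.pos - re_ + 1, row.pos - rs + 1
            if g_s < 0 or g_e > size:
                continue  # stays NaN: window leaves the chromosome
            if pos is None:
                continue
            lo = np.searchsorted(pos, g_s, side="left")
            hi = np.searchsorted(pos, g_e, side="left")
            if hi > lo:
                per_gene[gi, wi] = lvl_by_chrom[row.chrom][lo:hi].mean()
    ok = ~np.isnan(per_gene)
    n_ok = ok.sum(axis=0)
    sums = np.where(ok, per_gene, 0.0).sum(axis=0)
    mean = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)
    return MetaProfile(rel_starts, params.window, gene_ids, per_gene, mean)
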