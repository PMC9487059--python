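"""Per-cytosine differential methylation between two samples.

Each shared, sufficiently covered site is tested with a two-sided exact
test on the 2x2 table of methylated/unmethylated counts under the
hypergeometric null (the classic Fisher test, with the minimum-
likelihood two-sided rule).  P-values are adjusted with Benjamini-
Hochberg; sites passing the q-value and effect-size filters become
DMCs, which are clustered into DMRs under two rule-sets:

* ``gap_cluster`` — maximal same-direction chains of DMCs with at most
  ``dmr_max_gap`` bp between adjacent members and at least
  ``dmr_min_dmcs`` members;
* ``smooth_like`` — gap-cluster candidates additionally required to
  have >= 3 DMCs, mean |difference| >= 10 pp, >= 70 CpGs in the span
  and length >= 1 kb.

Differences are case minus control: a negative difference is
hypomethylation of the case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from ._intervals import mask_sites, overlap_join
from .params import AnalysisParams
from .profiling import GenomicContexts, MethylationTrack

logger = logging.getLogger(__name__)

DMC_COLUMNS = ["chrom", "pos", "strand", "context",
               "case_n_meth", "case_n_unmeth",
               "ctrl_n_meth", "ctrl_n_unmeth",
               "diff_pp", "p_value", "q_value", "direction"]

DMR_COLUMNS = ["chrom", "start", "end", "direction", "n_dmcs",
               "mean_abs_diff_pp", "n_cpgs_in_span", "rule", "positions"]


@dataclass
class DmcSet:
    df: pd.DataFrame  # DMC_COLUMNS, sorted by (chrom, pos, strand)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out["pos"] = out["pos"] + 1  # 1-based for display
        return out


@dataclass
class DmrSet:
    df: pd.DataFrame  # DMR_COLUMNS
    rule: str

    def __len__(self) -> int:
        return len(self.df)

    def to_bed_frame(self) -> pd.DataFrame:
        df = self.df.copy()
        df["name"] = df["direction"] + ":" + df["rule"]
        df["score"] = np.minimum(
            1000, np.round(10 * df["mean_abs_diff_pp"]).astype(int))
        return df[["chrom", "start", "end", "name", "score"]]


def fisher_exact_two_sided(case_meth, case_unmeth, ctrl_meth, ctrl_unmeth
                           ) -> np.ndarray:
    """Two-sided exact p-values for 2x2 tables under the hypergeometric null.

    The two-sided p is the total probability of all tables (with the
    observed margins) whose likelihood does not exceed the observed
    table's, the convention of the classic Fisher test.  Vectorized over
    table arrays.
    """
    a = np.atleast_1d(np.asarray(case_meth, dtype=np.int64))
    b = np.atleast_1d(np.asarray(case_unmeth, dtype=np.int64))
    c = np.atleast_1d(np.asarray(ctrl_meth, dtype=np.int64))
    d = np.atleast_1d(np.asarray(ctrl_unmeth, dtype=np.int64))
    N = a + b + c + d
    K = a + c          # total methylated
    n = a + b          # case total
    out = np.empty(len(a))
    for i in range(len(a)):
        kmin = max(0, n[i] + K[i] - N[i])
        kmax = min(n[i], K[i])
        k = np.arange(kmin, kmax + 1)
        logpmf = (gammaln(K[i] + 1) - gammaln(k + 1) - gammaln(K[i] - k + 1)
                  + gammaln(N[i] - K[i] + 1) - gammaln(n[i] - k + 1)
                  - gammaln(N[i] - K[i] - n[i] + k + 1)
                  + gammaln(n[i] + 1) + gammaln(N[i] - n[i] + 1)
                  - gammaln(N[i] + 1))
        pmf = np.exp(logpmf)
        p_obs = pmf[a[i] - kmin]
        out[i] = min(1.0, float(pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    return out


def test_dmc(case: MethylationTrack, control: MethylationTrack,
             params: AnalysisParams | None = None) -> pd.DataFrame:
    """Exact test at every site present in both tracks with enough coverage.

    Returns a frame with both samples' counts, ``diff_pp`` (case level
    minus control level in percentage points) and ``p_value``; empty
    (with a warning) when no site qualifies.
    """
    params = params or AnalysisParams()
    key = ["chrom", "pos", "strand", "context"]
    ca = case.df[key + ["n_meth", "n_unmeth"]].rename(
        columns={"n_meth": "case_n_meth", "n_unmeth": "case_n_unmeth"})
    co = control.df[key + ["n_meth", "n_unmeth"]].rename(
        columns={"n_meth": "ctrl_n_meth", "n_unmeth": "ctrl_n_unmeth"})
    m = ca.merge(co, on=key, how="inner")
    m = m[(m["case_n_meth"] + m["case_n_unmeth"] >= params.min_coverage)
          & (m["ctrl_n_meth"] + m["ctrl_n_unmeth"] >= params.min_coverage)]
    m = m.sort_values(["chrom", "pos", "strand"], kind="stable",
                      ignore_index=True)
    if len(m) == 0:
        logger.warning("no shared sites with coverage >= %d",
                       params.min_coverage)
        m["diff_pp"] = pd.Series(dtype=float)
        m["p_value"] = pd.Series(dtype=float)
        return m
    case_lvl = m["case_n_meth"] / (m["case_n_meth"] + m["case_n_unmeth"])
    ctrl_lvl = m["ctrl_n_meth"] / (m["ctrl_n_meth"] + m["ctrl_n_unmeth"])
    m["diff_pp"] = 100.0 * (case_lvl - ctrl_lvl)
    m["p_value"] = fisher_exact_two_sided(
        m["case_n_meth"].to_numpy(), m["case_n_unmeth"].to_numpy(),
        m["ctrl_n_meth"].to_numpy(), m["ctrl_n_unmeth"].to_numpy())
    return m


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_dmcs(tested: pd.DataFrame,
                params: AnalysisParams | None = None) -> DmcSet:
    """Retain sites with q <= q_cutoff and |diff| >= min_diff_pp.

    Adds ``q_value`` (computed here if absent) and ``direction`` (hypo
    when the case is lower than the control, hyper otherwise).
    """
    params = params or AnalysisParams()
    df = tested.copy()
    if "q_value" not in df.columns:
        df["q_value"] = adjust_fdr(df["p_value"].to_numpy())
    keep = ((df["q_value"] <= params.q_cutoff)
            & (df["diff_pp"].abs() >= params.min_diff_pp))
    df = df[keep].copy()
    df["direction"] = np.where(df["diff_pp"] < 0, "hypo", "hyper")
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable",
                        ignore_index=True)
    return DmcSet(df[DMC_COLUMNS])


def cluster_dmrs(dmcs: DmcSet,
                 params: AnalysisParams | None = None) -> DmrSet:
    """Gap-cluster DMCs into DMRs, separately per chromosome and direction.

    Maximal chains whose consecutive position gaps are <= ``dmr_max_gap``
    (inclusive) and that contain >= ``dmr_min_dmcs`` members become
    regions spanning first to last member DMC (+1 for the half-open
    end).
    """
    params = params or AnalysisParams()
    rows = []
    for (chrom, direction), grp in dmcs.df.groupby(["chrom", "direction"],
                                                   sort=True):
        pos = np.unique(grp["pos"].to_numpy())
        absdiff = grp.groupby("pos")["diff_pp"].first().abs()
        breaks = np.flatnonzero(np.diff(pos) > params.dmr_max_gap) + 1
        for chain in np.split(pos, breaks):
            if len(chain) < params.dmr_min_dmcs:
                continue
            rows.append((
                chrom, int(chain[0]), int(chain[-1]) + 1, direction,
                len(chain), float(absdiff.loc[chain].mean()),
                np.nan, "gap_cluster", chain.tolist()))
    df = pd.DataFrame(rows, columns=DMR_COLUMNS)
    df = df.sort_values(["chrom", "start", "direction"], kind="stable",
                        ignore_index=True)
    return DmrSet(df, "gap_cluster")


def filter_dmrs_smooth_like(dmrs: DmrSet, cpg_track: MethylationTrack,
                            params: AnalysisParams | None = None) -> DmrSet:
    """Apply the stricter smoothing-style rule to gap-cluster candidates.

    ``n_cpgs_in_span`` counts every destranded CpG unit of the track in
    the candidate span (coverage or not), not just the member DMCs.
    """
    params = params or AnalysisParams()
    cpg = cpg_track.df[cpg_track.df["context"] == "CpG"]
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in cpg.groupby("chrom")}
    df = dmrs.df.copy()
    n_cpgs = []
    for r in df.itertuples(index=False):
        pos = pos_by_chrom.get(r.chrom, np.empty(0, dtype=np.int64))
        n_cpgs.append(int(np.searchsorted(pos, r.end, side="left")
                          - np.searchsorted(pos, r.start, side="left")))
    df["n_cpgs_in_span"] = n_cpgs
    keep = ((df["n_dmcs"] >= params.smooth_min_dmcs)
            & (df["mean_abs_diff_pp"] >= params.smooth_min_diff_pp)
            & (df["n_cpgs_in_span"] >= params.smooth_min_cpgs)
            & (df["end"] - df["start"] >= params.smooth_min_len))
    out = df[keep].copy()
    out["rule"] = "smooth_like"
    return DmrSet(out.reset_index(drop=True), "smooth_like")


def summarize_dmcs(dmcs: DmcSet, contexts: GenomicContexts
                   ) -> dict[str, pd.DataFrame]:
    """Summary tables: direction counts, inter-DMC distances, TSS distances.

    ``counts``: per direction, total DMCs and DMCs inside promoters.
    ``adjacent_distances``: distance between consecutive DMCs per
    chromosome.  ``tss_distances``: per DMC, signed distance to the
    nearest TSS in gene orientation (negative = upstream); equidistant
    TSSs break the tie toward the lower coordinate.
    """
    df = dmcs.df.reset_index(drop=True)
    in_prom = mask_sites(df, contexts.promoters)
    counts = (pd.DataFrame({"direction": df["direction"],
                            "in_promoter": in_prom})
              .groupby("direction")
              .agg(n_total=("in_promoter", "size"),
                   n_in_promoter=("in_promoter", "sum"))
              .reset_index())

    dist_rows = []
    for chrom, grp in df.groupby("chrom"):
        pos = np.unique(grp["pos"].to_numpy())
        for p, dlt in zip(pos[1:], np.diff(pos)):
            dist_rows.append((chrom, int(p), int(dlt)))
    adjacent = pd.DataFrame(dist_rows, columns=["chrom", "pos", "distance"])

    tss_rows = []
    tss_by_chrom = {c: g.sort_values("pos").reset_index(drop=True)
                    for c, g in contexts.tss.groupby("chrom")}
    for r in df.itertuples(index=False):
        tg = tss_by_chrom.get(r.chrom)
        if tg is None or len(tg) == 0:
            continue
        tpos = tg["pos"].to_numpy()
        absd = np.abs(tpos - r.pos)
        best = int(np.argmin(absd))  # argmin takes the first = lowest coord
        t = tg.iloc[best]
        signed = int(r.pos - t.pos) if t.strand == "+" else int(t.pos - r.pos)
        tss_rows.append((r.chrom, int(r.pos), t.gene_id, signed))
    tss_distances = pd.DataFrame(
        tss_rows, columns=["chrom", "pos", "gene_id", "signed_distance"])
    return {"counts": counts, "adjacent_distances": adjacent,
            "tss_distances": tss_distances}


def associate_genes(features: DmcSet | DmrSet,
                    contexts: GenomicContexts) -> list[str]:
    """Genes whose promoter contains a DMC or overlaps a DMR (>= 1 bp).

    Returns sorted unique gene ids, the hand-off list for functional
    enrichment tools.
    """
    prom = contexts.promoters.reset_index(drop=True)
    if isinstance(features, DmcSet):
        df = features.df.reset_index(drop=True)
        genes: set[str] = set()
        for chrom, grp in df.groupby("chrom"):
            pg = prom[prom["chrom"] == chrom]
            for p in pg.itertuples(index=False):
                if ((grp["pos"] >= p.start) & (grp["pos"] < p.end)).any():
                    genes.add(p.gene_id)
        return sorted(genes)
    pairs = overlap_join(features.df[["chrom", "start", "end"]], prom)
    if len(pairs) == 0:
        return []
    return sorted(set(prom["gene_id"].to_numpy()[pairs["right_index"]]))
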