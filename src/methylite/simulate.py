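"""Synthetic methylome generator.

Builds a complete, download-free test bed for the toolkit: a random
genome with CpG-island-like promoters, a gene annotation, a true
per-cytosine methylation landscape with planted UMRs, LMRs and DMRs,
and binomially sampled cytosine-report files at Poisson coverage.

The landscape mimics the canonical mammalian picture: a high CpG
background (default 0.80, within the 70-90% commonly reported for
somatic tissue), essentially unmethylated promoter CpG islands, and
near-zero CHG/CHH methylation.  Planted DMRs shift the case condition
by an exact difference relative to the control so that recovery tests
have sharp ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import (CytosineCallSet, GeneModel, write_bed, write_chrom_sizes,
                 write_cytosine_report)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CONDITIONS = ("control", "case")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic methylome.

    Levels are methylation probabilities in [0, 1]; ``dmr_diff_pp`` is
    the planted case-control difference in percentage points; coverage
    is Poisson-distributed per site with the given mean.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 300_000
    n_genes: int = 40
    cpg_background_level: float = 0.80
    chg_chh_level: float = 0.01
    umr_at_promoter_prob: float = 0.5
    umr_level: float = 0.02
    lmr_count: int = 8
    lmr_level: float = 0.30
    lmr_width_cpgs: int = 15
    dmr_count: int = 20
    dmr_diff_pp: float = 40.0
    dmr_width_cpgs: int = 10
    coverage_mean: float = 30.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        for name in ("cpg_background_level", "chg_chh_level", "umr_level",
                     "lmr_level"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_chroms", "chrom_len", "n_genes", "lmr_count",
                     "dmr_count", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.dmr_diff_pp <= 100.0:
            raise ValueError("dmr_diff_pp must lie in [0, 100]")


@dataclass
class Reference:
    """Synthetic genome, transcript models and chromosome sizes."""

    genome: dict[str, str]
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]


@dataclass
class TrueLandscape:
    """Ground truth: per-site methylation probabilities + planted features.

    ``sites`` has one row per cytosine (both strands) with columns
    chrom/pos/strand/context/trinucleotide/p_control/p_case; inside a
    planted DMR the two probabilities differ by exactly the configured
    amount, elsewhere they are equal.  ``features`` lists planted
    intervals with kind in {UMR, LMR, DMR} and a direction for DMRs.
    """

    sites: pd.DataFrame
    features: pd.DataFrame  # chrom, start, end, kind, direction

    def cpg_unit_positions(self, chrom: str) -> np.ndarray:
        """Destranded CpG unit anchors ('+'-strand CpG positions)."""
        s = self.sites
        sel = s[(s["chrom"] == chrom) & (s["context"] == "CpG")
                & (s["strand"] == "+")]
        return np.sort(sel["pos"].to_numpy())

    def write_truth_beds(self, outdir) -> None:
        outdir = Path(outdir)
        for kind in ("UMR", "LMR", "DMR"):
            sub = self.features[self.features["kind"] == kind].copy()
            if kind == "DMR":
                sub["name"] = "DMR_" + sub["direction"]
            else:
                sub["name"] = kind
            path = outdir / f"truth_{kind.lower()}.bed"
            if len(sub):
                write_bed(sub[["chrom", "start", "end", "name"]], path)
            else:
                path.write_text("")


# ---------------------------------------------------------------------------
# reference simulation

def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return rng.choice(bases, size=n, p=[0.3, 0.2, 0.2, 0.3])


def _cpg_island_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """CpG-enriched sequence used at promoters (CpG-island mimic)."""
    out = np.empty(n, dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    i = 0
    while i < n:
        if rng.random() < 0.35 and i + 1 < n:
            out[i], out[i + 1] = b"C", b"G"
            i += 2
        else:
            out[i] = rng.choice(bases, p=[0.2, 0.3, 0.3, 0.2])
            i += 1
    return out


def _place_genes(rng: np.random.Generator, config: SimulationConfig
                 ) -> list[GeneModel]:
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = 2000
        placed = 0
        while placed < per_chrom[ci]:
            gap = int(rng.integers(1500, 4001))
            gene_len = int(rng.integers(2000, 6001))
            start = cursor + gap
            end = start + gene_len
            if end + 1500 > config.chrom_len:
                raise ValueError(
                    f"cannot place {config.n_genes} non-overlapping genes "
                    f"on chromosomes of {config.chrom_len} bp; "
                    "reduce n_genes or enlarge chrom_len")
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 6))
            # 2*n_ex - 1 alternating exon/intron pieces, each >= 50 bp
            n_pieces = 2 * n_ex - 1
            w = rng.dirichlet(np.ones(n_pieces))
            lens = np.maximum(50, np.round(w * gene_len).astype(int))
            lens[-1] = gene_len - lens[:-1].sum()
            if lens[-1] < 50:  # rebalance: take from the largest piece
                deficit = 50 - lens[-1]
                lens[np.argmax(lens[:-1])] -= deficit
                lens[-1] = 50
            bounds = np.concatenate([[0], np.cumsum(lens)]) + start
            exons = [(int(bounds[j]), int(bounds[j + 1]))
                     for j in range(0, n_pieces, 2)]
            gi += 1
            genes.append(GeneModel(f"g{gi:04d}", chrom, strand, start, end,
                                   exons))
            cursor = end
            placed += 1
    return genes


def _promoter_interval(gene: GeneModel, chrom_len: int,
                       promoter_len: int = 1000) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.tx_start - promoter_len), gene.tx_start
    return gene.tx_end, min(chrom_len, gene.tx_end + promoter_len)


def simulate_reference(config: SimulationConfig,
                       outdir=None) -> Reference:
    """Generate the genome, gene models and chromosome sizes.

    Promoter regions receive CpG-enriched sequence so that planted
    promoter UMRs sit on realistic CpG islands.  With ``outdir`` set,
    writes genome.fa, genes.genePred and chrom.sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes = _place_genes(rng, config) if config.n_genes else []
    genome: dict[str, str] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, config.chrom_len)
        for g in genes:
            if g.chrom != chrom:
                continue
            s, e = _promoter_interval(g, config.chrom_len)
            seq[s:e] = _cpg_island_sequence(rng, e - s)
        genome[chrom] = seq.tobytes().decode()
    sizes = {c: len(s) for c, s in genome.items()}
    ref = Reference(genome, genes, sizes)
    if outdir is not None:
        write_reference(ref, outdir)
    return ref


def write_reference(ref: Reference, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in ref.genome.items()]
    SeqIO.write(records, outdir / "genome.fa", "fasta")
    with open(outdir / "genes.genePred", "w") as fh:
        for g in ref.genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write("\t".join([
                g.gene_id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end),
                str(g.tx_start), str(g.tx_end), str(len(g.exons)),
                starts, ends]) + "\n")
    write_chrom_sizes(ref.chrom_sizes, outdir / "chrom.sizes")


# ---------------------------------------------------------------------------
# landscape simulation

def _cytosine_sites(chrom: str, seq: str) -> pd.DataFrame:
    """Every cytosine on either strand with its CX context and trinucleotide."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    pad = np.concatenate([[b"N", b"N"], arr, [b"N", b"N"]])

    plus_pos = np.flatnonzero(arr == b"C")
    p1 = pad[plus_pos + 3]   # pos + 1
    p2 = pad[plus_pos + 4]   # pos + 2
    plus_ctx = np.where(p1 == b"G", "CpG",
                        np.where(p2 == b"G", "CHG", "CHH"))
    plus_tri = (arr[plus_pos].astype("U1")
                + p1.astype("U1") + p2.astype("U1"))

    minus_pos = np.flatnonzero(arr == b"G")
    m1 = pad[minus_pos + 1]  # pos - 1
    m2 = pad[minus_pos + 0]  # pos - 2
    minus_ctx = np.where(m1 == b"C", "CpG",
                         np.where(m2 == b"C", "CHG", "CHH"))
    # trinucleotide read on the '-' strand: revcomp(seq[pos-2 : pos+1])
    rc = np.char.translate(
        m2.astype("U1") + m1.astype("U1") + arr[minus_pos].astype("U1"),
        _COMPLEMENT)
    minus_tri = np.array([t[::-1] for t in rc])

    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.concatenate([plus_pos, minus_pos]),
        "strand": np.concatenate([np.repeat("+", len(plus_pos)),
                                  np.repeat("-", len(minus_pos))]),
        "context": np.concatenate([plus_ctx, minus_ctx]),
        "trinucleotide": np.concatenate([plus_tri, minus_tri]),
    })
    return df.sort_values(["pos", "strand"], kind="stable",
                          ignore_index=True)


def _pick_unit_run(rng: np.random.Generator, units: np.ndarray,
                   width: int, forbidden: list[tuple[int, int]],
                   pad: int, retries: int = 500) -> tuple[int, int]:
    """Span of `width` consecutive CpG units clear of forbidden intervals."""
    if len(units) < width:
        raise ValueError("not enough CpG units to place a feature")
    for _ in range(retries):
        i = int(rng.integers(0, len(units) - width + 1))
        start, end = int(units[i]), int(units[i + width - 1]) + 2
        if all(end + pad <= fs or start >= fe + pad
               for fs, fe in forbidden):
            return start, end
    raise ValueError("could not place a planted feature without overlap; "
                     "reduce feature counts or enlarge the genome")


def simulate_landscape(ref: Reference, config: SimulationConfig
                       ) -> TrueLandscape:
    """Assign true methylation probabilities and plant UMR/LMR/DMR features.

    CpG sites get the background level, CHG/CHH the near-zero level.
    A configurable fraction of promoters becomes unmethylated (UMR,
    both conditions); LMRs are intermediate-level blocks outside genes
    and promoters; DMRs shift the case condition by exactly
    ``dmr_diff_pp`` percentage points (hyper DMRs lower the shared
    baseline first so the shift never clips at 1).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    frames = [_cytosine_sites(chrom, seq)
              for chrom, seq in ref.genome.items()]
    sites = pd.concat(frames, ignore_index=True)
    p = np.where(sites["context"] == "CpG",
                 config.cpg_background_level, config.chg_chh_level)
    p_control = p.astype(float).copy()
    p_case = p.astype(float).copy()

    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    is_cpg = (sites["context"] == "CpG").to_numpy()

    def _set_cpg(chrom, start, end, control=None, case=None):
        m = (chroms == chrom) & (pos >= start) & (pos < end) & is_cpg
        if control is not None:
            p_control[m] = control
        if case is not None:
            p_case[m] = case

    feature_rows = []
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in ref.genome}

    # UMRs at promoters
    for g in ref.genes:
        if rng.random() >= config.umr_at_promoter_prob:
            continue
        s, e = _promoter_interval(g, ref.chrom_sizes[g.chrom])
        _set_cpg(g.chrom, s, e, control=config.umr_level,
                 case=config.umr_level)
        feature_rows.append((g.chrom, s, e, "UMR", ""))
        forbidden[g.chrom].append((s, e))

    # LMRs stay clear of genes and promoters (CpG-poor background);
    # DMRs only of previously planted features
    feature_blocks = {c: list(forbidden[c]) for c in forbidden}
    blocked = {c: list(forbidden[c]) for c in forbidden}
    for g in ref.genes:
        blocked[g.chrom].append((g.tx_start, g.tx_end))
        blocked[g.chrom].append(_promoter_interval(
            g, ref.chrom_sizes[g.chrom]))

    unit_cache = {}
    for chrom in ref.genome:
        sel = is_cpg & (chroms == chrom) & \
            (sites["strand"].to_numpy() == "+")
        unit_cache[chrom] = np.sort(pos[sel])

    chrom_names = list(ref.genome)
    # LMRs: CpG-sparse intermediate-level blocks in intergenic space
    for _ in range(config.lmr_count):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        s, e = _pick_unit_run(rng, unit_cache[chrom], config.lmr_width_cpgs,
                              blocked[chrom], pad=600)
        _set_cpg(chrom, s, e, control=config.lmr_level, case=config.lmr_level)
        feature_rows.append((chrom, s, e, "LMR", ""))
        blocked[chrom].append((s, e))
        feature_blocks[chrom].append((s, e))

    # DMRs: exact case-control difference on CpG units.  DMRs may fall in
    # genes or (non-UMR) promoters — differential signal at promoters is
    # what the gene-association report exists for — but never on top of
    # other planted features.
    diff = config.dmr_diff_pp / 100.0
    for _ in range(config.dmr_count):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        s, e = _pick_unit_run(rng, unit_cache[chrom], config.dmr_width_cpgs,
                              feature_blocks[chrom], pad=600)
        direction = "hypo" if rng.random() < 0.5 else "hyper"
        if direction == "hypo":
            base = max(config.cpg_background_level, diff)
            _set_cpg(chrom, s, e, control=base, case=base - diff)
        else:
            base = min(config.cpg_background_level, 1.0 - diff)
            _set_cpg(chrom, s, e, control=base, case=base + diff)
        feature_rows.append((chrom, s, e, "DMR", direction))
        blocked[chrom].append((s, e))
        feature_blocks[chrom].append((s, e))

    sites = sites.copy()
    sites["p_control"] = p_control
    sites["p_case"] = p_case
    features = pd.DataFrame(
        feature_rows, columns=["chrom", "start", "end", "kind", "direction"])
    features = features.sort_values(["chrom", "start"], kind="stable",
                                    ignore_index=True)
    return TrueLandscape(sites, features)


# ---------------------------------------------------------------------------
# call sampling

def sample_calls(landscape: TrueLandscape, condition: str,
                 replicate_index: int, config: SimulationConfig
                 ) -> CytosineCallSet:
    """Draw one replicate's cytosine calls from the true landscape.

    Coverage is Poisson(``coverage_mean``) per site; methylated counts
    are binomial at the site's true probability.  The random stream is
    derived deterministically from (seed, condition, replicate).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    cond_idx = CONDITIONS.index(condition)
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 2, cond_idx, replicate_index]))
    s = landscape.sites
    prob = s["p_case" if condition == "case" else "p_control"].to_numpy()
    cov = rng.poisson(config.coverage_mean, size=len(s))
    n_meth = rng.binomial(cov, prob)
    df = pd.DataFrame({
        "chrom": s["chrom"], "pos": s["pos"], "strand": s["strand"],
        "context": s["context"], "n_meth": n_meth,
        "n_unmeth": cov - n_meth, "trinucleotide": s["trinucleotide"],
    })
    return CytosineCallSet(df, f"{condition}_rep{replicate_index + 1}")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: Reference
    landscape: TrueLandscape
    reports: dict[tuple[str, int], Path] = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig, outdir) -> SimulatedDataset:
    """Full fixture bundle: reference + truth + one report per replicate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(config, outdir)
    landscape = simulate_landscape(ref, config)
    landscape.write_truth_beds(outdir)
    ds = SimulatedDataset(config, ref, landscape)
    for condition in CONDITIONS:
        for rep in range(config.n_replicates):
            calls = sample_calls(landscape, condition, rep, config)
            path = outdir / f"{condition}_rep{rep + 1}.cx.txt"
            write_cytosine_report(calls, path)
            ds.reports[(condition, rep)] = path
    return ds
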