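import numpy as np
import pandas as pd
import pytest

from methylite import (AnalysisParams, CytosineCallSet, SimulationConfig,
                       build_track, simulate_landscape, simulate_reference)


def make_calls(rows, label="test"):
    """rows: (chrom, pos, strand, context, n_meth, n_unmeth[, trinuc])"""
    from methylite.io import CALL_COLUMNS
    if not rows:
        return CytosineCallSet(pd.DataFrame(columns=CALL_COLUMNS), label)
    recs = []
    for r in rows:
        tri = r[6] if len(r) > 6 else {"CpG": "CGA", "CHG": "CAG",
                                       "CHH": "CAT"}[r[3]]
        recs.append(dict(chrom=r[0], pos=r[1], strand=r[2], context=r[3],
                         n_meth=r[4], n_unmeth=r[5], trinucleotide=tri))
    return CytosineCallSet(pd.DataFrame(recs), label)


def make_cpg_track(positions, levels, chrom="chr1", coverage=20):
    """Destranded CpG track with given per-unit levels at fixed coverage."""
    rows = []
    for p, lv in zip(positions, levels):
        n_meth = int(round(lv * coverage))
        rows.append(("chr1" if chrom is None else chrom, int(p), "+", "CpG",
                     n_meth, coverage - n_meth))
    return build_track(make_calls(rows))


@pytest.fixture(scope="session")
def default_params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated reference + landscape shared across tests."""
    cfg = SimulationConfig(seed=7, n_chroms=1, chrom_len=100_000, n_genes=8,
                           lmr_count=4, dmr_count=6)
    ref = simulate_reference(cfg)
    landscape = simulate_landscape(ref, cfg)
    return cfg, ref, landscape
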