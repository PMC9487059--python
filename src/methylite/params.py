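"""Analysis parameters shared across the toolkit.

Every numeric constant of the downstream analyses lives here so a run is
fully described by one :class:`AnalysisParams` instance.  Defaults follow
the conventions of the WGBS literature: a promoter is the 1 kb region
upstream of a gene's TSS, genome tracks are binned at 100 kb, methylation
histograms use 10% bins, and TSS metaprofiles slide a 500 bp window in
100 bp steps across +/-1500 bp of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable constants for profiling, segmentation and differential calling.

    Attributes
    ----------
    promoter_len
        Length in bp of the strand-aware upstream promoter window.
    bin_size
        Genome-bin width in bp for binned methylation tracks.
    hist_bin
        Width of the methylation-level histogram bins (fraction of 1).
    tss_flank, window, step
        TSS metaprofile design: flanking distance, sliding-window width
        and step, all in bp.  The defaults yield 26 windows per gene.
    min_coverage
        Minimum per-site call count (methylated + unmethylated) for a site
        to enter segmentation or differential testing.
    q_cutoff, min_diff_pp
        DMC filters: maximum BH-adjusted q-value and minimum absolute
        methylation difference in percentage points.
    dmr_max_gap, dmr_min_dmcs
        Gap-clustering DMR rule: maximum distance between adjacent member
        DMCs (inclusive) and minimum DMC count per region.
    smooth_min_dmcs, smooth_min_diff_pp, smooth_min_cpgs, smooth_min_len
        The stricter smoothing-style DMR rule applied on top of the
        gap-cluster candidates.
    umr_max_level, lmr_max_level
        Segment class boundaries: segments with mean level below
        ``umr_max_level`` are UMRs, below ``lmr_max_level`` LMRs.
    seg_min_cpgs, seg_smooth_k
        Minimum CpG count per segment and the running-mean smoothing
        width (in CpGs) used before thresholding.
    """

    promoter_len: int = 1000
    bin_size: int = 100_000
    hist_bin: float = 0.10
    tss_flank: int = 1500
    window: int = 500
    step: int = 100
    min_coverage: int = 5
    q_cutoff: float = 0.5
    min_diff_pp: float = 25.0
    dmr_max_gap: int = 500
    dmr_min_dmcs: int = 2
    smooth_min_dmcs: int = 3
    smooth_min_diff_pp: float = 10.0
    smooth_min_cpgs: int = 70
    smooth_min_len: int = 1000
    umr_max_level: float = 0.10
    lmr_max_level: float = 0.50
    seg_min_cpgs: int = 4
    seg_smooth_k: int = 3

    def __post_init__(self) -> None:
        for name in ("promoter_len", "bin_size", "tss_flank", "window", "step",
                     "dmr_max_gap", "smooth_min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hist_bin", "q_cutoff", "umr_max_level", "lmr_max_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        """Number of TSS metaprofile windows implied by the design."""
        return (2 * self.tss_flank - self.window) // self.step + 1

    def replace(self, **overrides) -> "AnalysisParams":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(overrides)
        return AnalysisParams(**vals)
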