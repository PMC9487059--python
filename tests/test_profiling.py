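"""Tracks, summaries, genomic contexts and TSS metaprofiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylite import (AnalysisParams, GeneModel, bin_genome, build_track,
                       context_level_summary, derive_genomic_contexts,
                       destrand_cpg, merge_replicates, summarize_contexts,
                       tss_metaprofile)
from methylite.io import ValidationError
from methylite._intervals import merge_intervals, points_in_intervals
from tests.conftest import make_calls, make_cpg_track


class TestMergeReplicates:
    def test_counts_sum_at_shared_sites(self):
        r1 = make_calls([("chr1", 104, "+", "CpG", 3, 1)])
        r2 = make_calls([("chr1", 104, "+", "CpG", 2, 2)])
        m = merge_replicates([r1, r2])
        assert m.df.iloc[0].n_meth == 5 and m.df.iloc[0].n_unmeth == 3

    def test_single_replicate_is_identity(self):
        r1 = make_calls([("chr1", 104, "+", "CpG", 3, 1)])
        assert merge_replicates([r1]) == r1

    def test_union_semantics_for_private_sites(self):
        r1 = make_calls([("chr1", 104, "+", "CpG", 3, 1)])
        r2 = make_calls([("chr2", 50, "-", "CHH", 1, 4)])
        m = merge_replicates([r1, r2])
        assert len(m) == 2
        assert m.df.set_index("chrom").loc["chr2"].n_unmeth == 4

    def test_context_disagreement_rejected(self):
        r1 = make_calls([("chr1", 104, "+", "CpG", 3, 1)])
        r2 = make_calls([("chr1", 104, "+", "CHG", 2, 2)])
        with pytest.raises(ValidationError, match="context disagreement"):
            merge_replicates([r1, r2])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(
        st.lists(st.tuples(st.integers(0, 50), st.integers(0, 20),
                           st.integers(0, 20)),
                 max_size=20, unique_by=lambda r: r[0]),
        min_size=1, max_size=4))
    def test_total_calls_conserved(self, reps):
        sets = [make_calls([("chr1", p, "+", "CpG", a, b) for p, a, b in rep])
                for rep in reps]
        merged = merge_replicates(sets)
        total_in = sum(a + b for rep in reps for _, a, b in rep)
        assert (merged.df["n_meth"] + merged.df["n_unmeth"]).sum() == total_in


class TestTrackAndDestrand:
    def test_level_is_ratio_and_missing_at_zero_coverage(self):
        t = build_track(make_calls([("chr1", 1, "+", "CpG", 3, 1),
                                    ("chr1", 5, "+", "CpG", 0, 0),
                                    ("chr1", 9, "+", "CpG", 5, 0)]))
        lv = t.df["level"].tolist()
        assert lv[0] == 0.75 and np.isnan(lv[1]) and lv[2] == 1.0

    def test_symmetric_pair_pooled_at_plus_anchor(self):
        t = build_track(make_calls([("chr1", 100, "+", "CpG", 3, 1),
                                    ("chr1", 101, "-", "CpG", 1, 3)]))
        d = destrand_cpg(t)
        assert len(d) == 1
        r = d.df.iloc[0]
        assert (r.pos, r.strand, r.n_meth, r.n_unmeth, r.level) == \
            (100, "+", 4, 4, 0.5)

    def test_unpaired_and_non_cpg_pass_through(self):
        t = build_track(make_calls([("chr1", 200, "+", "CpG", 2, 0),
                                    ("chr1", 300, "-", "CpG", 1, 1),
                                    ("chr1", 400, "+", "CHG", 1, 1)]))
        d = destrand_cpg(t)
        assert len(d) == 3
        assert d.df["pos"].tolist() == [200, 300, 400]

    def test_destrand_is_idempotent_and_conserves_counts(self):
        t = build_track(make_calls(
            [("chr1", 100, "+", "CpG", 3, 1), ("chr1", 101, "-", "CpG", 1, 3),
             ("chr1", 150, "-", "CpG", 2, 5), ("chr2", 10, "+", "CHH", 1, 0)]))
        d1 = destrand_cpg(t)
        d2 = destrand_cpg(d1)
        pd.testing.assert_frame_equal(d1.df, d2.df)
        assert (d1.df["n_meth"].sum(), d1.df["n_unmeth"].sum()) == (7, 9)
        n_cpg_in = (t.df["context"] == "CpG").sum()
        n_cpg_out = (d1.df["context"] == "CpG").sum()
        assert n_cpg_in / 2 <= n_cpg_out <= n_cpg_in


class TestContextSummary:
    def test_mean_and_histogram_partition(self):
        t = build_track(make_calls(
            [("chr1", i * 10, "+", "CpG", m, 10 - m)
             for i, m in enumerate([2, 4, 6])]))
        s = summarize_contexts(t)
        assert s.mean_level["CpG"] == pytest.approx(0.4)
        assert s.histogram["CpG"].sum() == s.n_covered["CpG"] == 3
        assert np.isnan(s.mean_level["CHH"])
        assert s.histogram["CHH"].sum() == 0

    def test_full_methylation_counted_in_last_bin(self):
        t = build_track(make_calls([("chr1", 0, "+", "CpG", 7, 0)]))
        s = summarize_contexts(t)
        assert s.histogram["CpG"][9] == 1


class TestBinGenome:
    def test_tiling_and_truncated_last_bin(self, default_params):
        t = make_cpg_track([5, 150_000], [0.5, 0.5])
        b = bin_genome(t, "CpG", default_params, {"chr1": 250_000})
        assert b.df[["start", "end"]].values.tolist() == \
            [[0, 100_000], [100_000, 200_000], [200_000, 250_000]]
        assert b.df["n_sites"].tolist() == [1, 1, 0]
        assert np.isnan(b.df["mean_level"].iloc[2])

    def test_constant_track_gives_constant_bins(self, default_params):
        t = make_cpg_track(np.arange(0, 300_000, 5000), 0.8 * np.ones(60))
        b = bin_genome(t, "CpG", default_params, {"chr1": 300_000})
        assert np.allclose(b.df["mean_level"], 0.8)

    def test_weighted_bin_mean_equals_global_mean(self, default_params):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(400_000, 500, replace=False))
        lv = rng.random(500)
        t = make_cpg_track(pos, lv, coverage=100)
        b = bin_genome(t, "CpG", default_params, {"chr1": 400_000})
        covered = b.df[b.df["n_sites"] > 0]
        weighted = np.average(covered["mean_level"], weights=covered["n_sites"])
        assert weighted == pytest.approx(t.covered["level"].mean(), abs=1e-12)

    def test_site_beyond_chromosome_end_rejected(self, default_params):
        t = make_cpg_track([150], [0.5])
        with pytest.raises(ValidationError, match="beyond"):
            bin_genome(t, "CpG", default_params, {"chr1": 100})


def _contexts_for(genes, sizes, params=None):
    return derive_genomic_contexts(genes, sizes, params or AnalysisParams())


class TestGenomicContexts:
    def test_plus_strand_promoter_upstream(self):
        g = GeneModel("g1", "chr1", "+", 2000, 5000, [(2000, 5000)])
        ctx = _contexts_for([g], {"chr1": 10_000})
        assert ctx.promoters.iloc[0][["start", "end"]].tolist() == [1000, 2000]
        assert ctx.tss.iloc[0].pos == 2000

    def test_minus_strand_promoter_mirrored(self):
        g = GeneModel("g1", "chr1", "-", 2000, 5000, [(2000, 5000)])
        ctx = _contexts_for([g], {"chr1": 10_000})
        assert ctx.promoters.iloc[0][["start", "end"]].tolist() == [5000, 6000]
        assert ctx.tss.iloc[0].pos == 4999

    def test_promoter_clamped_at_chromosome_start(self):
        g = GeneModel("g1", "chr1", "+", 300, 900, [(300, 900)])
        ctx = _contexts_for([g], {"chr1": 10_000})
        assert ctx.promoters.iloc[0][["start", "end"]].tolist() == [0, 300]

    def test_gene_absent_from_chrom_sizes_rejected(self):
        g = GeneModel("g1", "chrX", "+", 100, 900, [(100, 900)])
        with pytest.raises(ValidationError, match="chrX"):
            _contexts_for([g], {"chr1": 10_000})

    def test_multi_transcript_gene_merges_exons_and_span(self):
        t1 = GeneModel("g1", "chr1", "+", 2000, 5000, [(2000, 2500)])
        t2 = GeneModel("g1", "chr1", "+", 2400, 6000, [(2400, 3000),
                                                       (5500, 6000)])
        ctx = _contexts_for([t1, t2], {"chr1": 10_000})
        assert ctx.gene_bodies.iloc[0][["start", "end"]].tolist() == \
            [2000, 6000]
        assert ctx.merged_exons[["start", "end"]].values.tolist() == \
            [[2000, 3000], [5500, 6000]]
        assert ctx.introns[["start", "end"]].values.tolist() == \
            [[3000, 5500]]
        assert ctx.promoters.iloc[0][["start", "end"]].tolist() == \
            [1000, 2000]

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_partition_invariants_on_random_annotations(self, data):
        size = data.draw(st.integers(3000, 30_000))
        n_genes = data.draw(st.integers(0, 5))
        genes = []
        cursor = 0
        for i in range(n_genes):
            start = cursor + data.draw(st.integers(10, 500))
            length = data.draw(st.integers(100, 2000))
            end = start + length
            if end >= size:
                break
            strand = data.draw(st.sampled_from("+-"))
            n_ex = data.draw(st.integers(1, 3))
            cuts = sorted(data.draw(
                st.lists(st.integers(start + 1, end - 1),
                         min_size=2 * (n_ex - 1), max_size=2 * (n_ex - 1),
                         unique=True)))
            bounds = [start] + cuts + [end]
            exons = [(bounds[j], bounds[j + 1])
                     for j in range(0, len(bounds) - 1, 2)]
            genes.append(GeneModel(f"g{i}", "chr1", strand, start, end,
                                   exons))
            cursor = end
        ctx = _contexts_for(genes, {"chr1": size})
        for gid, body in ctx.gene_bodies.groupby("gene_id"):
            span = (body.iloc[0].start, body.iloc[0].end)
            ex = ctx.merged_exons[ctx.merged_exons.gene_id == gid]
            inx = ctx.introns[ctx.introns.gene_id == gid]
            both_s, both_e = merge_intervals(
                np.concatenate([ex["start"], inx["start"]]),
                np.concatenate([ex["end"], inx["end"]]))
            # exon union intron = gene span, and they are disjoint
            assert both_s.tolist() == [span[0]] and both_e.tolist() == [span[1]]
            total = (ex["end"] - ex["start"]).sum() + \
                (inx["end"] - inx["start"]).sum()
            assert total == span[1] - span[0]
        # intergenic disjoint from transcripts and coverage complete
        tx_len_s, tx_len_e = merge_intervals(
            ctx.gene_bodies["start"].to_numpy(),
            ctx.gene_bodies["end"].to_numpy())
        inter_len = (ctx.intergenic["end"] - ctx.intergenic["start"]).sum()
        tx_len = (tx_len_e - tx_len_s).sum()
        assert inter_len + tx_len == size
        mids = (ctx.intergenic["start"] + ctx.intergenic["end"]) // 2
        assert not points_in_intervals(
            mids.to_numpy(), tx_len_s, tx_len_e).any()


class TestContextLevelSummary:
    def _fixture(self):
        genes = [GeneModel("g1", "chr1", "+", 2000, 5000,
                           [(2000, 3000), (4000, 5000)])]
        ctx = _contexts_for(genes, {"chr1": 10_000})
        pos = [1500, 2500, 3500, 6000]  # promoter, exon, intron, intergenic
        t = make_cpg_track(pos, [0.5, 0.5, 0.5, 0.5])
        return ctx, t

    def test_constant_track_constant_class_means(self):
        ctx, t = self._fixture()
        out = context_level_summary(t, ctx, "CpG").set_index("region_class")
        assert (out["mean_level"] == 0.5).all()

    def test_exon_site_counts_in_gene_too(self):
        ctx, t = self._fixture()
        out = context_level_summary(t, ctx, "CpG").set_index("region_class")
        assert out.loc["exon", "n_sites"] == 1
        assert out.loc["gene", "n_sites"] == 2  # exon + intron sites

    def test_intergenic_exclusive(self):
        ctx, t = self._fixture()
        out = context_level_summary(t, ctx, "CpG").set_index("region_class")
        assert out.loc["intergenic", "n_sites"] == 1


class TestTssMetaprofile:
    def test_default_design_has_26_windows(self, default_params):
        assert default_params.n_windows == 26
        g = GeneModel("g1", "chr1", "+", 5000, 8000, [(5000, 8000)])
        ctx = _contexts_for([g], {"chr1": 20_000})
        t = make_cpg_track(np.arange(3000, 7000, 50), [0.7] * 80)
        prof = tss_metaprofile(t, ctx, default_params)
        assert prof.per_gene.shape == (1, 26)
        assert len(prof.rel_starts) == 26

    def test_constant_track_gives_constant_profile(self, default_params):
        g = GeneModel("g1", "chr1", "+", 5000, 8000, [(5000, 8000)])
        ctx = _contexts_for([g], {"chr1": 20_000})
        t = make_cpg_track(np.arange(3000, 7000, 50), [0.7] * 80)
        prof = tss_metaprofile(t, ctx, default_params)
        assert np.allclose(prof.mean, 0.7)

    def test_minus_gene_equals_mirrored_plus_computation(self, default_params):
        # mirror the chromosome around position M: site p -> M - p
        M = 20_000
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(2000, 9000), 150, replace=False))
        lv = rng.random(150)
        gp = GeneModel("g", "chr1", "+", 5000, 8000, [(5000, 8000)])
        ctx_p = _contexts_for([gp], {"chr1": M + 1})
        t_p = make_cpg_track(pos, lv, coverage=1000)
        prof_p = tss_metaprofile(t_p, ctx_p, default_params)
        # '-' gene with TSS at M - 5000; mirrored sites carry the same levels
        gm = GeneModel("g", "chr1", "-", M - 8000, M - 5000 + 1,
                       [(M - 8000, M - 5000 + 1)])
        ctx_m = _contexts_for([gm], {"chr1": M + 1})
        t_m = make_cpg_track(M - pos, lv, coverage=1000)
        prof_m = tss_metaprofile(t_m, ctx_m, default_params)
        np.testing.assert_allclose(prof_m.per_gene, prof_p.per_gene)

    def test_windows_past_chromosome_edge_missing(self, default_params):
        g = GeneModel("g1", "chr1", "+", 500, 3000, [(500, 3000)])
        ctx = _contexts_for([g], {"chr1": 20_000})
        t = make_cpg_track(np.arange(0, 3000, 20), [0.5] * 150)
        prof = tss_metaprofile(t, ctx, default_params)
        # windows starting before position 0 (rel start < -500) are missing
        assert np.isnan(prof.per_gene[0, 0])
        assert not np.isnan(prof.per_gene[0, 25])

    def test_linear_track_recovers_window_midpoint(self, default_params):
        # level rises linearly with position; uniformly spaced covered sites
        # => each window mean is the level at the window midpoint
        g = GeneModel("g1", "chr1", "+", 10_000, 14_000, [(10_000, 14_000)])
        ctx = _contexts_for([g], {"chr1": 30_000})
        pos = np.arange(8000, 12_000, 10)
        slope = 1.0 / 20_000
        lv = pos * slope
        t = make_cpg_track(pos, lv, coverage=20_000)
        prof = tss_metaprofile(t, ctx, default_params)
        for wi, rs in enumerate(prof.rel_starts):
            mid_pos = 10_000 + rs + (default_params.window - 10) / 2
            assert prof.per_gene[0, wi] == pytest.approx(
                mid_pos * slope, abs=1e-9)
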