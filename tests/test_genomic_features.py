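"""The 60-value genomic feature block: units per group + extraction invariants."""

import math

import numpy as np
import pytest

from lncm6a.features import (
    CandidateSite,
    DEFAULT_CATALOG,
    FeatureExtractor,
    ZScoreStats,
    attribute_overlap_flags,
    clustering_features,
    conservation_features,
    gc_fraction,
    region_length_features,
    structure_features,
    zscore_features,
)
from lncm6a.tracks import (
    BedInterval,
    IntervalTrack,
    ScoreTrack,
    StructureProvider,
    TrackBundle,
)
from lncm6a.transcripts import Mode, TranscriptModel


def make_site(model, tx_pos, mode=Mode.FULL, motif="GGACU"):
    return CandidateSite(
        chrom=model.chrom, gpos=model.transcript_to_genomic(tx_pos, mode),
        strand=model.strand, transcript_id=model.transcript_id,
        gene_id=model.gene_id, tx_pos=tx_pos, mode=Mode(mode), motif=motif,
    )


class TestRegionLength:
    def test_single_exon_1024(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 1024)])
        assert region_length_features(m, 500, Mode.FULL) == (10.0, 10.0)

    def test_exon_within_longer_transcript(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 256), (500, 1267)])
        assert region_length_features(m, 100, Mode.MATURE) == (8.0, 10.0)

    def test_length_one_region(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(10, 10), (100, 1122)])
        assert region_length_features(m, 1, Mode.MATURE)[0] == 0.0


class TestClustering:
    def test_lone_candidate(self):
        assert clustering_features(100, [100]) == (0, 0, 0, 2000)

    def test_two_candidates_10nt(self):
        for site, other in ((100, 110), (110, 100)):
            assert clustering_features(site, [100, 110]) == (1, 1, 1, 10)

    def test_counts_nested_and_monotone(self, rng):
        cands = sorted(rng.choice(10_000, size=120, replace=False))
        for site in cands[:25]:
            n50, n500, n2000, nearest = clustering_features(site, cands)
            assert n50 <= n500 <= n2000
            others = [c for c in cands if c != site]
            assert n50 == sum(abs(c - site) <= 50 for c in others)
            assert nearest == min(min(abs(c - site) for c in others), 2000)


class TestConservation:
    def _setup(self, tracks):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        return m, make_site(m, 250)

    def test_constant_track(self):
        tr = ScoreTrack.from_intervals([("chr1", 0, 500, 0.7)])
        bundle = TrackBundle(score_tracks=[tr, tr, tr, tr])
        m, site = self._setup(bundle)
        assert conservation_features(site, m, bundle) == pytest.approx([0.7] * 4)

    def test_all_missing_imputes_zero(self):
        bundle = TrackBundle.empty()
        m, site = self._setup(bundle)
        assert conservation_features(site, m, bundle) == [0.0] * 4

    def test_window_mean_matches_brute_force(self, rng):
        vals = rng.random(500)
        tr = ScoreTrack.from_intervals(
            [("chr1", i, i + 1, v) for i, v in enumerate(vals)])
        bundle = TrackBundle(score_tracks=[tr] * 4)
        m, site = self._setup(bundle)
        expected = vals[250 - 11 : 250 + 10].mean()  # genomic 240..260
        assert conservation_features(site, m, bundle)[0] == pytest.approx(expected)


class TestStructure:
    def test_all_dots(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        site = make_site(m, 250)
        provider = StructureProvider({"t:200": "." * 101}, use_fold=False)
        bundle = TrackBundle(structure=provider)
        win = "A" * 101
        assert structure_features(site, m, win, bundle) == (0, 0.0)

    def test_paired_site_and_fraction(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        site = make_site(m, 250)
        db = ["."] * 101
        db[50] = "("
        db[80] = ")"
        for i in range(10, 29):
            db[i] = "(" if i < 19 else "."
        for i in range(90, 99):
            db[i] = ")"
        db = "".join(db)
        n_paired = sum(c in "()" for c in db)
        provider = StructureProvider({"t:200": db}, use_fold=False)
        bundle = TrackBundle(structure=provider)
        paired, frac = structure_features(site, m, "A" * 101, bundle)
        assert paired == 1
        assert frac == pytest.approx(n_paired / 101)

    def test_builtin_folder_on_toy_window(self):
        # GGGAAACCC pairs 3 bases each side -> paired fraction 6/9
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 9)])
        site = make_site(m, 5)
        bundle = TrackBundle()  # default provider folds
        paired, frac = structure_features(site, m, "GGGAAACCC", bundle, flank=4)
        assert frac == pytest.approx(6 / 9)
        assert paired == 0  # the central A sits in the hairpin loop


class TestOverlapFlags:
    def test_empty_bundle_all_zero(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        site = make_site(m, 250)
        assert attribute_overlap_flags(site, m, TrackBundle.empty()) == [0] * 14

    def test_single_registered_interval(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        site = make_site(m, 250)
        hit = IntervalTrack.from_intervals(
            [BedInterval("chr1", 200, 300, "x", 0, "+")], "slot_45")
        bundle = TrackBundle(interval_tracks=(
            [IntervalTrack(f"slot_{i}") for i in (43, 44)] + [hit]
            + [IntervalTrack(f"slot_{i}") for i in range(46, 56)]))
        flags = attribute_overlap_flags(site, m, bundle)
        assert sum(flags) == 1 and flags[2] == 1

    def test_strand_respected(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        site = make_site(m, 250)
        minus = IntervalTrack.from_intervals(
            [BedInterval("chr1", 200, 300, "x", 0, "-")], "slot_43")
        bundle = TrackBundle(interval_tracks=[minus])
        assert sum(attribute_overlap_flags(site, m, bundle)) == 0

    def test_agreement_with_linear_scan(self, rng):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 2000)])
        ivs = [BedInterval("chr1", int(s), int(s) + int(w), ".", 0, "+")
               for s, w in zip(rng.integers(0, 1900, 40), rng.integers(5, 80, 40))]
        track = IntervalTrack.from_intervals(ivs, "slot_43")
        bundle = TrackBundle(interval_tracks=[track])
        for tx_pos in rng.integers(1, 2000, 60):
            site = make_site(m, int(tx_pos))
            got = attribute_overlap_flags(site, m, bundle)[0]
            want = int(any(iv.start < site.gpos <= iv.end for iv in ivs))
            assert got == want

    def test_mirna_target_is_gene_level(self):
        m = TranscriptModel("t", "g", "chr1", "+", [(1, 500)])
        site = make_site(m, 10)  # far from the interval below
        mirna = IntervalTrack.from_intervals(
            [BedInterval("chr1", 400, 450, "g", 0, "+")], "mirna")
        bundle = TrackBundle(mirna_targets=mirna)
        assert attribute_overlap_flags(site, m, bundle)[13] == 1


class TestZScores:
    def _stats(self):
        gene_values = {
            f"g{v}": {"isoform_num": v, "exon_num": v, "gc_gene": v / 10}
            for v in (2, 4, 6)
        }
        return ZScoreStats.fit(gene_values, local_gcs=[0.2, 0.4, 0.6])

    def test_mean_value_is_zero(self):
        stats = self._stats()
        assert stats.z("isoform_num", 4) == 0.0

    def test_population_sd_convention(self):
        stats = self._stats()
        pop_sd = math.sqrt(8 / 3)  # n-denominator sd of {2,4,6}
        assert stats.z("isoform_num", 6) == pytest.approx(2 / pop_sd)

    def test_constant_population_gives_zero(self):
        gene_values = {f"g{i}": {"isoform_num": 3, "exon_num": 3, "gc_gene": 0.5}
                       for i in range(4)}
        stats = ZScoreStats.fit(gene_values, [0.5] * 4)
        vals = zscore_features(
            {"isoform_num": 3, "exon_num": 3, "gc_gene": 0.5, "gc_101": 0.5}, stats)
        assert vals == [0.0] * 4

    def test_gc_fraction_ignores_ambiguous(self):
        assert gc_fraction("GGCCNNNN") == 1.0
        assert gc_fraction("NNN") == 0.0
        assert gc_fraction("ACGU") == 0.5


class TestExtraction:
    def test_vector_shapes_and_onehot(self, small_fixture):
        fx = small_fixture
        ex = FeatureExtractor(fx.genome, fx.genes_of("lncRNA"), fx.tracks, Mode.FULL)
        model = next(iter(ex.chosen.values()))
        cands = ex.candidates(model)
        sites = [ex.make_site(model, p) for p in cands[:5]]
        ex.fit_population(sites)
        for s in sites:
            g = ex.genomic_vector(s)
            assert g.shape == (60,)
            assert g[14:32].sum() == 1.0  # motif one-hot block
            full = ex.full_vector(s)
            assert full.shape == (144,)
        # the selected "first 134 features" of the published model fit inside
        assert len(DEFAULT_CATALOG.full_names) == 144 >= 134

    def test_dummies_binary_distances_capped(self, small_fixture):
        fx = small_fixture
        ex = FeatureExtractor(fx.genome, fx.genes_of("mRNA"), fx.tracks, Mode.MATURE)
        model = next(iter(ex.chosen.values()))
        sites = [ex.make_site(model, p) for p in ex.candidates(model)[:10]]
        ex.fit_population(sites)
        cat = DEFAULT_CATALOG
        for s in sites:
            g = ex.genomic_vector(s)
            for i, group in enumerate(cat.groups):
                if group in ("region", "motif", "overlap") or \
                        cat.names[i] == "struct_site_paired":
                    assert g[i] in (0.0, 1.0)
            for name in ("dist_sj_5_p2000", "dist_sj_3_p2000", "dist_nearest_p2000"):
                assert 0 <= g[cat.index(name)] <= 2000

    def test_invariant_to_gene_insertion_order(self, small_fixture):
        fx = small_fixture
        genes = fx.genes_of("lncRNA")
        rev = dict(reversed(list(genes.items())))
        ex1 = FeatureExtractor(fx.genome, genes, fx.tracks, Mode.FULL)
        ex2 = FeatureExtractor(fx.genome, rev, fx.tracks, Mode.FULL)
        model = ex1.chosen[sorted(genes)[0]]
        site1 = ex1.make_site(model, ex1.candidates(model)[0])
        site2 = ex2.make_site(ex2.chosen[model.gene_id], site1.tx_pos)
        ex1.fit_population([site1])
        ex2.fit_population([site2])
        assert np.allclose(ex1.genomic_vector(site1), ex2.genomic_vector(site2))

    def test_zscore_block_standardized_over_genes(self, small_fixture):
        fx = small_fixture
        ex = FeatureExtractor(fx.genome, fx.genes_of("mRNA"), fx.tracks, Mode.FULL)
        ex.fit_population([])
        gv = ex.gene_values()
        for name in ("isoform_num", "exon_num", "gc_gene"):
            zs = np.array([ex.zstats.z(name, v[name]) for v in gv.values()])
            assert abs(zs.mean()) < 1e-9
            assert abs(zs.std() - 1) < 1e-9

    def test_unfitted_population_refused(self, small_fixture):
        fx = small_fixture
        ex = FeatureExtractor(fx.genome, fx.genes_of("lncRNA"), fx.tracks, Mode.FULL)
        model = next(iter(ex.chosen.values()))
        site = ex.make_site(model, ex.candidates(model)[0])
        with pytest.raises(RuntimeError, match="fit_population"):
            ex.genomic_vector(site)
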