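"""Fusion/SV curation: partitioning, filter battery, recurrence."""

from collections import defaultdict

import pytest

from metdrive.core import GenomicInterval
from metdrive.fusion import (
    Breakpoint,
    SvCandidate,
    curate,
    family_classify,
    family_filter,
    met_specific_set,
    readthrough_filter,
    recurrence_and_fraction,
    repeat_classify,
    support_and_distance_filter,
)


def cand(sample="lm1", g1="gA", g2="gB", pos1=1000, pos2=50000, chrom1="chr1",
         chrom2="chr1", reads=5, source="rna", total=None, sv_type=None):
    return SvCandidate(
        sample_id=sample,
        source=source,
        breakpoint1=Breakpoint(chrom1, pos1),
        breakpoint2=Breakpoint(chrom2, pos2),
        sv_type=sv_type or ("fusion" if chrom1 == chrom2 else "interchromosomal"),
        read_count=reads,
        gene1=g1,
        gene2=g2,
        gene_read_total=total,
    )


class TestMetSpecificSet:
    def test_cohort_arithmetic(self):
        """71 LM candidates with 17 gene pairs shared with PT leave 54."""
        lm = [cand(sample="lm", g1=f"x{i}", g2=f"y{i}") for i in range(71)]
        pt = [cand(sample="pt", g1=f"x{i}", g2=f"y{i}") for i in range(17)]
        parts = met_specific_set(lm, pt)
        assert len(parts["shared"]) == 17
        assert len(parts["lm_only"]) == 54

    def test_disjoint_pairs_share_nothing(self):
        lm = [cand(g1="a", g2="b")]
        pt = [cand(sample="pt", g1="c", g2="d")]
        assert met_specific_set(lm, pt)["shared"] == []

    def test_unordered_pair_identity(self):
        lm = [cand(g1="a", g2="b")]
        pt = [cand(sample="pt", g1="b", g2="a", pos1=999999, pos2=1999999)]
        assert len(met_specific_set(lm, pt)["shared"]) == 1

    def test_breakpoint_matching_without_genes(self):
        lm = [cand(g1=None, g2=None, pos1=1000, pos2=50000)]
        pt_near = [cand(sample="pt", g1=None, g2=None, pos1=1050, pos2=49990)]
        pt_far = [cand(sample="pt", g1=None, g2=None, pos1=2000, pos2=50000)]
        assert len(met_specific_set(lm, pt_near, match_tolerance=100)["shared"]) == 1
        assert len(met_specific_set(lm, pt_far, match_tolerance=100)["shared"]) == 0

    def test_partition_conservation_random(self, rng):
        for _ in range(100):
            lm = [
                cand(sample="lm", g1=f"g{int(rng.integers(0, 8))}", g2=f"g{int(rng.integers(8, 16))}")
                for _ in range(int(rng.integers(0, 12)))
            ]
            pt = [
                cand(sample="pt", g1=f"g{int(rng.integers(0, 8))}", g2=f"g{int(rng.integers(8, 16))}")
                for _ in range(int(rng.integers(0, 12)))
            ]
            parts = met_specific_set(lm, pt)
            assert len(parts["shared"]) + len(parts["lm_only"]) == len(lm)
            assert len(parts["pt_only"]) <= len(pt)
            pt_pairs = {c.gene_pair for c in pt}
            for c in parts["lm_only"]:
                assert c.gene_pair not in pt_pairs
            for c in parts["shared"]:
                assert c.gene_pair in pt_pairs


class TestReadthrough:
    def test_planted_readthrough_removed(self, noisy_result):
        """Generator-planted read-through artifacts are exactly the RNA
        candidates the filter removes."""
        truth = {
            t["uid"]: t["class"] for t in noisy_result.truth["fusions"]
        }
        kept, removed = readthrough_filter(noisy_result.rna_candidates, noisy_result.genes)
        assert {c.uid for c in removed} == {
            u for u, k in truth.items() if k == "read_through"
            and any(c.uid == u for c in noisy_result.rna_candidates)
        }
        for c in kept:
            assert truth[c.uid] != "read_through"

    def test_opposite_strand_neighbors_kept(self, noisy_result):
        genes = noisy_result.genes
        by = {g.gene_symbol: g for g in genes}
        c = cand(
            g1="rtA1", g2="rtA2",
            pos1=by["rtA1"].exons[0].start + 5, pos2=by["rtA2"].exons[0].start + 5,
        )
        # same-strand adjacent: removed
        assert readthrough_filter([c], genes)[0] == []
        # wgs source: read-through is an RNA phenomenon
        c_wgs = cand(
            g1="rtA1", g2="rtA2", source="wgs", sv_type="DEL",
            pos1=by["rtA1"].exons[0].start + 5, pos2=by["rtA2"].exons[0].start + 5,
        )
        assert readthrough_filter([c_wgs], genes)[0] == [c_wgs]


class TestSupportAndDistance:
    GENES = None

    def _genes(self):
        from conftest import make_gene
        return [
            make_gene(symbol="gA", chrom="chr1", exon_starts=(500,), exon_seqs=("ATG" * 400,)),
            make_gene(symbol="gB", chrom="chr1", exon_starts=(45000,), exon_seqs=("ATG" * 400,)),
        ]

    def test_read_floor(self):
        genes = self._genes()
        kept, audit = support_and_distance_filter([cand(reads=2)], genes)
        assert kept == [] and audit[cand(reads=2).uid]["min_reads"] is False
        kept, _ = support_and_distance_filter([cand(reads=3)], genes)
        assert len(kept) == 1

    def test_distance_boundary_closed(self):
        genes = self._genes()
        near = cand(pos1=45000, pos2=45000 + 9_999)
        at = cand(pos1=45000, pos2=45000 + 10_000)
        kept, _ = support_and_distance_filter([near, at], genes, gene_flank=100_000)
        assert [c.uid for c in kept] == [at.uid]

    def test_interchromosomal_passes_distance(self):
        genes = self._genes()
        c = cand(chrom1="chrT", chrom2="chrU", pos1=600, pos2=700)
        genes[1] = genes[1]
        kept, audit = support_and_distance_filter([c], genes, gene_flank=10**9)
        assert audit[c.uid]["partner_distance"] is True

    def test_random_candidates_match_predicate_conjunction(self, rng):
        genes = self._genes()
        spans = [(g.span.chrom, g.span.start, g.span.end) for g in genes]
        flank = 2000
        cands = [
            cand(pos1=int(rng.integers(1, 60000)), pos2=int(rng.integers(1, 60000)),
                 reads=int(rng.integers(0, 8)))
            for _ in range(300)
        ]
        kept, audit = support_and_distance_filter(
            cands, genes, min_reads=3, min_partner_distance=10_000, gene_flank=flank
        )

        def near(chrom, pos):
            return any(
                c == chrom and s - flank <= pos - 1 < e + flank for c, s, e in spans
            )

        expect = [
            c for c in cands
            if c.read_count >= 3
            and abs(c.breakpoint2.pos - c.breakpoint1.pos) >= 10_000
            and near(c.breakpoint1.chrom, c.breakpoint1.pos)
            and near(c.breakpoint2.chrom, c.breakpoint2.pos)
        ]
        assert [c.uid for c in kept] == [c.uid for c in expect]

    def test_monotone_in_thresholds(self, rng):
        genes = self._genes()
        cands = [
            cand(pos1=int(rng.integers(1, 60000)), pos2=int(rng.integers(1, 60000)),
                 reads=int(rng.integers(0, 8)))
            for _ in range(200)
        ]
        sizes = [
            len(support_and_distance_filter(cands, genes, min_reads=r,
                                            min_partner_distance=d, gene_flank=10**6)[0])
            for r, d in [(1, 1000), (3, 10000), (5, 20000)]
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestRepeatClassify:
    REPEATS = [GenomicInterval("chr1", 900, 1100), GenomicInterval("chr1", 49900, 50100)]

    def test_both_and_neither(self):
        both = cand(pos1=1000, pos2=50000)
        neither = cand(pos1=5000, pos2=60000)
        classes = repeat_classify([both, neither], self.REPEATS)
        assert classes[both.uid] == "both_repeat"
        assert classes[neither.uid] == "single_copy"

    def test_one_repeat(self):
        c = cand(pos1=1000, pos2=60000)
        assert repeat_classify([c], self.REPEATS)[c.uid] == "one_repeat"

    def test_random_matches_point_in_interval(self, rng):
        track = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 100000, size=15)
        ]
        for _ in range(100):
            c = cand(pos1=int(rng.integers(1, 100000)), pos2=int(rng.integers(1, 100000)))
            got = repeat_classify([c], track)[c.uid]
            n = sum(
                1
                for bp in (c.breakpoint1, c.breakpoint2)
                if any(iv.start <= bp.pos - 1 < iv.end for iv in track)
            )
            assert got == {2: "both_repeat", 1: "one_repeat", 0: "single_copy"}[n]


class TestFamilyFilter:
    FAM = {"famA_1": "famA", "famA_2": "famA", "famB_1": "famB"}

    def test_same_family_excluded(self):
        c = cand(g1="famA_1", g2="famA_2")
        kept, classes = family_filter([c], self.FAM)
        assert kept == [] and classes[c.uid] == "same_family"

    def test_unassigned_kept(self):
        c = cand(g1="famA_1", g2="mystery")
        kept, classes = family_filter([c], self.FAM)
        assert kept == [c] and classes[c.uid] == "unassigned"

    def test_different_family_kept(self):
        c = cand(g1="famA_1", g2="famB_1")
        kept, classes = family_filter([c], self.FAM)
        assert kept == [c] and classes[c.uid] == "different_family"

    def test_heuristic_fallback_strips_digits(self):
        c = cand(g1="Hba1", g2="Hba2")
        assert family_classify([c], {}, heuristic_fallback=True)[c.uid] == "same_family"
        assert family_classify([c], {})[c.uid] == "unassigned"

    def test_planted_family_artifacts_all_flagged(self, noisy_result):
        truth = {t["uid"]: t["class"] for t in noisy_result.truth["fusions"]}
        allc = noisy_result.rna_candidates + noisy_result.wgs_candidates
        classes = family_classify(allc, noisy_result.family_map)
        for c in allc:
            if truth[c.uid] == "gene_family":
                assert classes[c.uid] == "same_family"
            elif truth[c.uid] == "true_event":
                assert classes[c.uid] != "same_family"


class TestRecurrenceAndFraction:
    S2A = {"lm_a1": "a1", "lm_a2": "a2", "lm2_a1": "a1"}

    def test_same_pair_two_animals(self):
        cands = [cand(sample="lm_a1"), cand(sample="lm_a2")]
        rec, _ = recurrence_and_fraction(cands, self.S2A)
        assert all(v == "multi_animal" for v in rec.values())

    def test_multiple_partners_one_animal(self):
        cands = [cand(sample="lm_a1", g1="hub", g2="p1"),
                 cand(sample="lm2_a1", g1="hub", g2="p2")]
        rec, _ = recurrence_and_fraction(cands, self.S2A)
        assert all(v == "multi_partner" for v in rec.values())

    def test_fraction_and_low_flag(self):
        c = cand(total=1000)
        c2 = cand(g1="q1", g2="q2", total=None)
        rec, frac = recurrence_and_fraction([c, c2], self.S2A)
        assert frac[c.uid] == pytest.approx(5 / 1000)
        assert frac[c.uid] < 0.01
        assert frac[c2.uid] is None


class TestCurateEndToEnd:
    def test_audit_completeness_and_planted_truth(self, nf_run):
        """Every LM candidate appears exactly once with a full filter
        vector; noise-free survivors are exactly the planted true events."""
        _, res = nf_run
        truth = {t["uid"]: t for t in res.truth["fusions"]}
        lm_ids = {r.sample_id for r in res.cohort if r.tissue == "LM"}
        for source, cands in (("rna", res.rna_candidates), ("wgs", res.wgs_candidates)):
            lm = [c for c in cands if c.sample_id in lm_ids]
            pt = [c for c in cands if c.sample_id not in lm_ids]
            reports = curate(
                lm, pt, res.genes, res.repeats, res.family_map,
                res.cohort.sample_to_animal,
            )
            assert sorted(r.candidate.uid for r in reports) == sorted(c.uid for c in lm)
            for r in reports:
                assert set(r.filters) == {
                    "readthrough", "min_reads", "partner_distance",
                    "gene_proximity", "gene_family",
                }
            survivors = {r.candidate.uid for r in reports if r.passes_all}
            expect = {
                c.uid for c in lm
                if truth[c.uid]["class"] == "true_event" and truth[c.uid]["lm_only"]
            }
            assert survivors == expect
            # artifact classes flagged as constructed
            for r in reports:
                klass = truth[r.candidate.uid]["class"]
                if klass == "repeat_breakpoint":
                    assert r.repeat_class == "both_repeat"
                if klass == "gene_family":
                    assert r.family_class == "same_family"
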