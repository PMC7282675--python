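"""Consensus SNV screen: filters, intersection, enrichment, recurrence."""

from collections import defaultdict

import numpy as np
import pytest

from metdrive.core import Cohort, GenomicSite, SampleRecord
from metdrive.snv import (
    CALLER_IDS,
    ConsensusSnv,
    MetEnrichedSnv,
    SnvCall,
    cell_fraction,
    classify_recurrence,
    cross_platform_validate,
    filter_calls,
    intersect_callers,
    met_enrichment_filter,
    mutual_exclusivity_report,
)


def call(chrom="chr1", pos=100, ref="A", alt="G", sample="s1", caller="mpileup",
         qual=50.0, ref_n=20, alt_n=20):
    return SnvCall(GenomicSite(chrom, pos, ref, alt), sample, caller, qual, ref_n, alt_n)


def consensus(sample="s1", pos=100, ref_n=20, alt_n=20, gene=None, codon=None, aa=None):
    return ConsensusSnv(
        site=GenomicSite("chr1", pos, "A", "G"),
        sample_id=sample,
        supporting_callers=frozenset(CALLER_IDS),
        max_qual=60.0,
        ref_count=ref_n,
        alt_count=alt_n,
        gene=gene,
        codon=codon,
        aa_change=aa,
    )


def pair_cohort(n_animals=1, n_lm=1):
    recs = []
    for a in range(n_animals):
        recs.append(SampleRecord(f"a{a}_PT", f"a{a}", "PT", "F1", "CAST/EiJ"))
        for m in range(n_lm):
            recs.append(SampleRecord(f"a{a}_LM{m}", f"a{a}", "LM", "F1", "CAST/EiJ"))
    return Cohort(recs)


class TestFilterCalls:
    def test_quality_floor_is_strict(self):
        assert filter_calls([call(qual=29.9)]) == []
        kept = filter_calls([call(qual=30.0)])
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_calls([]) == []

    def test_random_calls_match_brute_force(self, rng):
        calls = [
            call(pos=int(rng.integers(1, 200)), qual=float(rng.uniform(0, 60)),
                 ref=("A" if p % 2 else "C"), alt=("G" if p % 2 else "T"))
            for p in range(1000)
        ]
        poly = {
            ("chr1", int(rng.integers(1, 200)), r, a)
            for r, a in (("A", "G"), ("C", "T"))
            for _ in range(30)
        }
        expected = [c for c in calls if c.qual >= 30 and c.site.key not in poly]
        assert filter_calls(calls, 30, poly) == expected

    def test_monotone_in_min_qual(self, rng):
        calls = [call(pos=p + 1, qual=float(rng.uniform(0, 60))) for p in range(200)]
        survivors = [len(filter_calls(calls, q)) for q in (10, 30, 50)]
        assert survivors == sorted(survivors, reverse=True)


class TestIntersectCallers:
    def _calls_for(self, sample, site_sets):
        out = []
        for caller, positions in zip(CALLER_IDS, site_sets):
            for p in positions:
                out.append(call(pos=p, sample=sample, caller=caller))
        return out

    def test_two_of_three_excluded(self):
        calls = self._calls_for("s1", [{10, 20}, {10}, {10, 30}])
        cons = intersect_callers(calls)
        assert [c.site.pos for c in cons] == [10]
        assert cons[0].supporting_callers == frozenset(CALLER_IDS)

    def test_identical_sets_idempotent(self):
        sites = {5, 15, 25}
        cons = intersect_callers(self._calls_for("s1", [sites] * 3))
        assert {c.site.pos for c in cons} == sites

    def test_missing_caller_errors_with_sample(self):
        calls = self._calls_for("sX", [{10}, {10}, set()])
        with pytest.raises(ValueError, match="sX"):
            intersect_callers(calls)

    def test_random_sets_match_set_algebra(self, rng):
        for _ in range(100):
            sets = [set(rng.integers(1, 40, size=rng.integers(1, 15))) for _ in range(3)]
            sets = [s or {1} for s in sets]
            cons = intersect_callers(self._calls_for("s1", sets))
            assert {c.site.pos for c in cons} == sets[0] & sets[1] & sets[2]

    def test_pooled_counts_from_deepest_caller(self):
        calls = [
            call(caller="mpileup", ref_n=10, alt_n=5),
            call(caller="mutect2", ref_n=30, alt_n=12),
            call(caller="strelka", ref_n=20, alt_n=9),
        ]
        cons = intersect_callers(calls)[0]
        assert (cons.ref_count, cons.alt_count) == (30, 12)


class TestMetEnrichment:
    def test_boundary_enumeration(self):
        """Closed VAF window and the PT alt-read ceiling, against the
        stated predicate evaluated directly."""
        cohort = pair_cohort()
        for vaf, pt_alt, expect in [
            (0.30, 0, True),
            (0.50, 0, True),
            (0.29, 0, False),
            (0.51, 0, False),
            (0.40, 1, True),
            (0.40, 2, False),
            (0.40, 5, False),
        ]:
            alt = int(round(vaf * 100))
            lm = [consensus(sample="a0_LM0", ref_n=100 - alt, alt_n=alt)]
            pt = (
                [call(sample="a0_PT", ref_n=40 - pt_alt, alt_n=pt_alt)] if pt_alt else []
            )
            kept, _ = met_enrichment_filter(lm, pt, cohort)
            assert bool(kept) is expect, (vaf, pt_alt)

    def test_cell_fraction_grid(self):
        grid = [0.0, 0.25, 0.3, 0.5, 0.6]
        assert [cell_fraction(v) for v in grid] == [0.0, 0.5, 0.6, 1.0, 1.0]

    def test_cell_fraction_reported(self):
        cohort = pair_cohort()
        kept, _ = met_enrichment_filter(
            [consensus(sample="a0_LM0", ref_n=70, alt_n=30)], [], cohort
        )
        assert kept[0].cell_fraction == pytest.approx(0.6)

    def test_lm_without_pt_excluded_with_warning(self):
        cohort = Cohort([SampleRecord("x_LM", "x", "LM", "F1", "CAST/EiJ")])
        kept, warnings = met_enrichment_filter(
            [consensus(sample="x_LM", ref_n=60, alt_n=40)], [], cohort
        )
        assert kept == [] and len(warnings) == 1

    def test_pt_evidence_unions_over_multiple_pts(self):
        recs = [
            SampleRecord("a_PT1", "a", "PT", "F1", "CAST/EiJ"),
            SampleRecord("a_PT2", "a", "PT", "F1", "CAST/EiJ"),
            SampleRecord("a_LM", "a", "LM", "F1", "CAST/EiJ"),
        ]
        cohort = Cohort(recs)
        lm = [consensus(sample="a_LM", ref_n=60, alt_n=40)]
        pt = [call(sample="a_PT1", alt_n=0, ref_n=40), call(sample="a_PT2", alt_n=7, ref_n=33)]
        kept, _ = met_enrichment_filter(lm, pt, cohort)
        assert kept == []

    def test_narrowing_window_monotone(self, rng):
        cohort = pair_cohort()
        lm = [
            consensus(sample="a0_LM0", pos=p + 1, ref_n=100 - a, alt_n=a)
            for p, a in enumerate(rng.integers(0, 101, size=200))
        ]
        wide, _ = met_enrichment_filter(lm, [], cohort, vaf_low=0.2, vaf_high=0.6)
        narrow, _ = met_enrichment_filter(lm, [], cohort, vaf_low=0.3, vaf_high=0.5)
        wide_keys = {(m.site.pos) for m in wide}
        assert {(m.site.pos) for m in narrow} <= wide_keys


def _met(sample, pos, gene, codon, aa):
    return MetEnrichedSnv(
        consensus=consensus(sample=sample, pos=pos, gene=gene, codon=codon, aa=aa),
        vaf_lm=0.4, vaf_pt=0.0, pt_alt_reads=0, cell_fraction=0.8,
    )


class TestRecurrence:
    def test_same_codon_across_animals(self):
        """Two animals sharing a codon make the gene same-codon recurrent;
        a third animal at another codon is listed in the same report."""
        cohort = pair_cohort(n_animals=3)
        met = [
            _met("a0_LM0", 100, "krasT", 12, "G12D"),
            _met("a1_LM0", 100, "krasT", 12, "G12D"),
            _met("a2_LM0", 247, "krasT", 61, "Q61R"),
        ]
        reports = classify_recurrence(met, cohort)
        (rep,) = [r for r in reports if r.gene == "krasT"]
        assert rep.recurrence_class == "same_codon_recurrent"
        assert len(rep.events) == 3

    def test_same_codon_different_substitutions(self):
        cohort = pair_cohort(n_animals=3)
        met = [
            _met("a0_LM0", 561, "shc1T", 561, "P561S"),
            _met("a1_LM0", 561, "shc1T", 561, "P561T"),
            _met("a2_LM0", 562, "shc1T", 561, "P561H"),
        ]
        (rep,) = classify_recurrence(met, cohort)
        assert rep.recurrence_class == "same_codon_recurrent"

    def test_two_lesions_one_animal_is_singleton(self):
        cohort = pair_cohort(n_animals=1, n_lm=2)
        met = [
            _met("a0_LM0", 100, "g", 12, "G12D"),
            _met("a0_LM1", 100, "g", 12, "G12D"),
        ]
        (rep,) = classify_recurrence(met, cohort)
        assert rep.recurrence_class == "singleton"

    def test_different_codons_two_animals(self):
        cohort = pair_cohort(n_animals=2)
        met = [_met("a0_LM0", 10, "g", 3, "A3T"), _met("a1_LM0", 40, "g", 9, "R9H")]
        (rep,) = classify_recurrence(met, cohort)
        assert rep.recurrence_class == "diff_codon_recurrent"

    def test_unannotated_sites_bucketed_not_dropped(self):
        cohort = pair_cohort()
        met = [_met("a0_LM0", 999, None, None, None)]
        reports = classify_recurrence(met, cohort)
        assert reports[0].gene == "non-coding/unassigned"
        assert len(reports[0].events) == 1


class TestCrossPlatform:
    def test_truth_table(self, rng):
        """Statuses match construction: masked sites absent, untranscribed
        genes unevaluable, everything else validated."""
        cohort_sample = "s1"
        sites = [GenomicSite("chr1", int(p), "A", "G") for p in range(1, 51)]
        masked = set(rng.choice(50, size=10, replace=False).tolist())
        untranscribed_idx = {i for i in masked if i % 2 == 0}
        met = []
        for i, s in enumerate(sites):
            gene = f"g{i}"
            met.append(
                MetEnrichedSnv(
                    consensus=ConsensusSnv(
                        site=s, sample_id=cohort_sample,
                        supporting_callers=frozenset(CALLER_IDS), max_qual=60,
                        ref_count=60, alt_count=40, gene=gene, codon=1, aa_change="A1T",
                    ),
                    vaf_lm=0.4, vaf_pt=0.0, pt_alt_reads=0, cell_fraction=0.8,
                )
            )
        other = {
            cohort_sample: [
                call(pos=s.pos, sample=cohort_sample) for i, s in enumerate(sites)
                if i not in masked
            ]
        }
        transcribed = {f"g{i}": i not in untranscribed_idx for i in range(50)}
        statuses = dict()
        for m, status in cross_platform_validate(met, other, transcribed):
            statuses[m.site.pos - 1] = status
        for i in range(50):
            if i not in masked:
                assert statuses[i] == "validated"
            elif i in untranscribed_idx:
                assert statuses[i] == "not_transcribed"
            else:
                assert statuses[i] == "absent"

    def test_no_data_platform(self):
        met = [_met("s9", 5, "g", 1, "A1T")]
        assert cross_platform_validate(met, {}, {})[0][1] == "no_data"


class TestMutualExclusivity:
    def test_no_cooccurrence(self):
        met = [_met("a0_LM0", 1, "kras", 12, "G12D"), _met("a1_LM0", 2, "ctnnb1", 45, "S45P")]
        table, flag = mutual_exclusivity_report(met, {"kras", "ctnnb1"})
        assert not flag
        assert set(table["n_recurrent_genes"]) == {1}

    def test_cooccurrence_detected(self):
        met = [_met("a0_LM0", 1, "kras", 12, "G12D"), _met("a0_LM0", 2, "ctnnb1", 45, "S45P")]
        table, flag = mutual_exclusivity_report(met, {"kras", "ctnnb1"})
        assert flag
        assert table.loc[0, "n_recurrent_genes"] == 2

    def test_random_assignment_matches_counting(self, rng):
        genes = [f"g{i}" for i in range(6)]
        recurrent = set(genes[:3])
        met = []
        per_lesion = defaultdict(set)
        for k in range(200):
            sample = f"LM{int(rng.integers(0, 20))}"
            gene = genes[int(rng.integers(0, 6))]
            met.append(_met(sample, k + 1, gene, 1, "A1T"))
            if gene in recurrent:
                per_lesion[sample].add(gene)
        table, flag = mutual_exclusivity_report(met, recurrent)
        expect_flag = any(len(v) >= 2 for v in per_lesion.values())
        assert flag == expect_flag
        for _, row in table.iterrows():
            assert row["n_recurrent_genes"] == len(per_lesion[row["sample_id"]])
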