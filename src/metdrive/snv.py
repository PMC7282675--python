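"""Two-criterion metastasis-driver SNV screen.

A candidate metastasis driver must (1) be enriched in the metastasis but
absent from the matched primary tumor and (2) be present in the metastatic
seeding cell, operationalized as a heterozygous variant carried by at least
60% of cells in the lesion (variant allele fraction 0.3-0.5).  Candidate
calls first pass a quality / known-polymorphism filter and a three-caller
consensus; survivors are classified by cross-animal recurrence and checked
for mutual exclusivity of recurrent genes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .core import Cohort, GeneModel, GenomicSite, site_to_codon

logger = logging.getLogger("metdrive")

CALLER_IDS = ("mpileup", "mutect2", "strelka")

UNASSIGNED_GENE = "non-coding/unassigned"


@dataclass(frozen=True)
class SnvCall:
    """A caller-attributed variant call at one site in one sample."""

    site: GenomicSite
    sample_id: str
    caller_id: str
    qual: float
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("negative read counts")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        d = self.depth
        return self.alt_count / d if d else 0.0


@dataclass
class ConsensusSnv:
    """A site supported by all three callers in one sample.

    Pooled counts come from the supporting caller with the highest depth
    at the site (ties broken by fixed caller-label order).
    """

    site: GenomicSite
    sample_id: str
    supporting_callers: frozenset[str]
    max_qual: float
    ref_count: int
    alt_count: int
    is_known_polymorphism: bool = False
    tri_supported: bool = True
    gene: str | None = None
    codon: int | None = None
    aa_change: str | None = None

    @property
    def vaf(self) -> float:
        d = self.ref_count + self.alt_count
        return self.alt_count / d if d else 0.0


@dataclass
class MetEnrichedSnv:
    """A consensus LM SNV passing the metastasis-enrichment filter."""

    consensus: ConsensusSnv
    vaf_lm: float
    vaf_pt: float
    pt_alt_reads: int
    cell_fraction: float

    @property
    def site(self) -> GenomicSite:
        return self.consensus.site

    @property
    def sample_id(self) -> str:
        return self.consensus.sample_id


@dataclass
class RecurrenceReport:
    gene: str
    recurrence_class: str  # same_codon_recurrent | diff_codon_recurrent | singleton
    events: list[tuple] = field(default_factory=list)  # (animal, sample, codon, aa, platform)

    @property
    def animals(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev[0] not in seen:
                seen.append(ev[0])
        return seen


def cell_fraction(vaf: float) -> float:
    """Fraction of cells carrying a heterozygous variant at a diploid locus.

    Each carrying cell contributes one alt and one ref allele, so the
    carrier fraction is twice the allele fraction, clipped at 1.
    """
    return min(1.0, 2.0 * vaf)


def filter_calls(
    calls: list[SnvCall],
    min_qual: float = 30.0,
    polymorphism_set: set[tuple[str, int, str, str]] | None = None,
) -> list[SnvCall]:
    """Drop calls below the Phred quality floor or at known polymorphisms."""
    poly = polymorphism_set or set()
    return [c for c in calls if c.qual >= min_qual and c.site.key not in poly]


def _pool_counts(group: list[SnvCall]) -> tuple[int, int]:
    order = {cid: i for i, cid in enumerate(CALLER_IDS)}
    best = max(group, key=lambda c: (c.depth, -order.get(c.caller_id, len(order))))
    return best.ref_count, best.alt_count


def intersect_callers(
    calls: list[SnvCall],
    mode: str = "site",
    genes: list[GeneModel] | None = None,
    require_three: bool = True,
) -> list[ConsensusSnv]:
    """Keep calls supported by all three callers.

    mode="site": the exact (sample, chrom, pos, ref, alt) must appear in
    all 3 call sets.  mode="gene": a site survives if its gene has at least
    one call from each caller in the sample; sites not themselves
    tri-supported are flagged (``tri_supported=False``).
    """
    if mode not in ("site", "gene"):
        raise ValueError(f"unknown mode {mode!r}")
    by_sample: dict[str, list[SnvCall]] = defaultdict(list)
    for c in calls:
        by_sample[c.sample_id].append(c)
    if require_three:
        for sid, group in sorted(by_sample.items()):
            callers = {c.caller_id for c in group}
            if len(callers) < 3:
                raise ValueError(
                    f"sample {sid} has calls from {sorted(callers)}; 3 callers required"
                )

    gene_of = None
    if mode == "gene":
        if genes is None:
            raise ValueError("gene mode requires gene models")
        gene_of = _site_gene_lookup(genes)

    out: list[ConsensusSnv] = []
    for sid in sorted(by_sample):
        by_site: dict[tuple, list[SnvCall]] = defaultdict(list)
        for c in by_sample[sid]:
            by_site[c.site.key].append(c)
        if mode == "site":
            for key in sorted(by_site):
                group = by_site[key]
                callers = frozenset(c.caller_id for c in group)
                if len(callers) == 3:
                    ref, alt = _pool_counts(group)
                    out.append(
                        ConsensusSnv(
                            site=group[0].site,
                            sample_id=sid,
                            supporting_callers=callers,
                            max_qual=max(c.qual for c in group),
                            ref_count=ref,
                            alt_count=alt,
                        )
                    )
        else:
            callers_per_gene: dict[str | None, set[str]] = defaultdict(set)
            for key, group in by_site.items():
                g = gene_of(group[0].site)
                for c in group:
                    callers_per_gene[g].add(c.caller_id)
            for key in sorted(by_site):
                group = by_site[key]
                g = gene_of(group[0].site)
                if g is not None and len(callers_per_gene[g]) == 3:
                    callers = frozenset(c.caller_id for c in group)
                    ref, alt = _pool_counts(group)
                    out.append(
                        ConsensusSnv(
                            site=group[0].site,
                            sample_id=sid,
                            supporting_callers=callers,
                            max_qual=max(c.qual for c in group),
                            ref_count=ref,
                            alt_count=alt,
                            tri_supported=len(callers) == 3,
                        )
                    )
    return out


def annotate_consensus(consensus: list[ConsensusSnv], genes: list[GeneModel]) -> None:
    """Attach gene / codon / amino-acid-change annotation in place."""
    lookup = _gene_interval_index(genes)
    for rec in consensus:
        gene = lookup(rec.site)
        if gene is None:
            continue
        rec.gene = gene.gene_symbol
        try:
            hit = site_to_codon(rec.site, gene)
        except ValueError:
            hit = None
        if hit is not None:
            rec.codon, rec.aa_change = hit


def _gene_interval_index(genes: list[GeneModel]):
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.span.chrom].append(g)

    def lookup(site: GenomicSite) -> GeneModel | None:
        for g in by_chrom.get(site.chrom, ()):
            if g.span.contains(site.chrom, site.pos - 1):
                return g
        return None

    return lookup


def _site_gene_lookup(genes: list[GeneModel]):
    idx = _gene_interval_index(genes)

    def gene_of(site: GenomicSite) -> str | None:
        g = idx(site)
        return g.gene_symbol if g is not None else None

    return gene_of


def met_enrichment_filter(
    consensus_lm: list[ConsensusSnv],
    pt_calls: list[SnvCall] | list[ConsensusSnv],
    cohort: Cohort,
    vaf_low: float = 0.3,
    vaf_high: float = 0.5,
    pt_max_alt_reads: int = 1,
) -> tuple[list[MetEnrichedSnv], list[str]]:
    """Apply the two driver criteria to LM consensus SNVs.

    Criterion 1 (metastasis-specific): at most ``pt_max_alt_reads`` alt
    reads at the site in the matched animal's primary tumors, taking the
    maximum over all PT samples and callers (multiple PTs of one animal are
    pooled as a union of evidence).  Criterion 2 (seeding cell): LM VAF in
    the closed window [vaf_low, vaf_high], i.e. the variant is carried by
    at least ``2*vaf_low`` of cells in the lesion.

    LM samples without any matched PT are excluded with a warning: the
    metastasis-specificity criterion is unevaluable for them.
    """
    s2a = cohort.sample_to_animal
    pt_evidence: dict[tuple[str, tuple], int] = defaultdict(int)
    for call in pt_calls:
        animal = s2a.get(call.sample_id)
        if animal is None:
            continue
        key = (animal, call.site.key)
        pt_evidence[key] = max(pt_evidence[key], call.alt_count)

    kept: list[MetEnrichedSnv] = []
    warnings: list[str] = []
    for rec in consensus_lm:
        animal = s2a.get(rec.sample_id)
        if animal is None or not cohort.pt_samples_of_animal(animal):
            msg = f"LM {rec.sample_id} has no matched PT; {rec.site.chrom}:{rec.site.pos} excluded"
            warnings.append(msg)
            logger.warning(msg)
            continue
        if not (vaf_low <= rec.vaf <= vaf_high):
            continue
        pt_alt = pt_evidence.get((animal, rec.site.key), 0)
        if pt_alt > pt_max_alt_reads:
            continue
        pt_depth_vaf = 0.0  # reported VAF in PT from the max-evidence record
        for call in pt_calls:
            if s2a.get(call.sample_id) == animal and call.site.key == rec.site.key:
                if call.alt_count == pt_alt and (call.ref_count + call.alt_count) > 0:
                    pt_depth_vaf = call.alt_count / (call.ref_count + call.alt_count)
                    break
        kept.append(
            MetEnrichedSnv(
                consensus=rec,
                vaf_lm=rec.vaf,
                vaf_pt=pt_depth_vaf,
                pt_alt_reads=pt_alt,
                cell_fraction=cell_fraction(rec.vaf),
            )
        )
    return kept, warnings


def classify_recurrence(
    met_snvs: list[MetEnrichedSnv],
    cohort: Cohort,
    platform: str = "exome",
    extra_events: list[tuple] | None = None,
) -> list[RecurrenceReport]:
    """Partition genes by cross-animal recurrence of their mutated codons.

    Recurrence counts distinct animals, never lesions: two metastases of
    one animal are one independent observation.  ``extra_events`` allows
    merging events from another platform as (gene, animal, sample, codon,
    aa_change, platform) tuples.  Sites without a gene/codon annotation are
    reported under a dedicated unassigned bucket, never dropped.
    """
    s2a = cohort.sample_to_animal
    events_by_gene: dict[str, list[tuple]] = defaultdict(list)
    for snv in met_snvs:
        gene = snv.consensus.gene if snv.consensus.codon is not None else None
        bucket = gene if gene is not None else UNASSIGNED_GENE
        events_by_gene[bucket].append(
            (
                s2a.get(snv.sample_id, snv.sample_id),
                snv.sample_id,
                snv.consensus.codon,
                snv.consensus.aa_change,
                platform,
            )
        )
    for ev in extra_events or []:
        gene, animal, sample, codon, aa, plat = ev
        events_by_gene[gene or UNASSIGNED_GENE].append((animal, sample, codon, aa, plat))

    reports: list[RecurrenceReport] = []
    for gene in sorted(events_by_gene):
        events = sorted(events_by_gene[gene], key=lambda e: (e[0], e[1], e[2] or 0))
        if gene == UNASSIGNED_GENE:
            reports.append(RecurrenceReport(gene, "singleton", events))
            continue
        animals_by_codon: dict[int, set[str]] = defaultdict(set)
        all_animals: set[str] = set()
        for animal, _s, codon, _aa, _p in events:
            all_animals.add(animal)
            if codon is not None:
                animals_by_codon[codon].add(animal)
        if any(len(a) >= 2 for a in animals_by_codon.values()):
            cls = "same_codon_recurrent"
        elif len(all_animals) >= 2:
            cls = "diff_codon_recurrent"
        else:
            cls = "singleton"
        reports.append(RecurrenceReport(gene, cls, events))
    return reports


def cross_platform_validate(
    met_snvs: list[MetEnrichedSnv],
    other_platform_calls: dict[str, list[SnvCall]],
    transcribed: dict[str, bool],
) -> list[tuple[MetEnrichedSnv, str]]:
    """Check each event against an orthogonal platform's call sets.

    validated: the same site is called in the same sample on the other
    platform.  not_transcribed: the gene is not expressed, so absence is
    unevaluable.  absent: transcribed but not called.  no_data: the sample
    has no call set on the other platform.
    """
    out: list[tuple[MetEnrichedSnv, str]] = []
    for snv in met_snvs:
        calls = other_platform_calls.get(snv.sample_id)
        if calls is None:
            out.append((snv, "no_data"))
            continue
        if any(c.site.key == snv.site.key for c in calls):
            out.append((snv, "validated"))
            continue
        gene = snv.consensus.gene
        if gene is not None and not transcribed.get(gene, True):
            out.append((snv, "not_transcribed"))
        else:
            out.append((snv, "absent"))
    return out


def mutual_exclusivity_report(
    met_snvs: list[MetEnrichedSnv],
    recurrent_genes: set[str],
) -> tuple[pd.DataFrame, bool]:
    """Per-lesion count of distinct recurrent genes mutated.

    Returns the per-LM table and whether any lesion carries events in two
    or more distinct recurrent genes (co-occurrence).
    """
    per_lesion: dict[str, set[str]] = defaultdict(set)
    for snv in met_snvs:
        gene = snv.consensus.gene
        if gene in recurrent_genes:
            per_lesion[snv.sample_id].add(gene)
    rows = [
        {
            "sample_id": sid,
            "n_recurrent_genes": len(genes),
            "genes": ",".join(sorted(genes)),
        }
        for sid, genes in sorted(per_lesion.items())
    ]
    table = pd.DataFrame(rows, columns=["sample_id", "n_recurrent_genes", "genes"])
    any_cooccurrence = bool((table["n_recurrent_genes"] >= 2).any()) if len(table) else False
    return table, any_cooccurrence
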