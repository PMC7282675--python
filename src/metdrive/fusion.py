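"""Curation of candidate fusion transcripts and structural variants.

Candidates from an RNA fusion caller and from a WGS discordant-read-pair
caller are normalized into one schema and pushed through the filter
battery: metastasis-specificity against the matched primary tumors,
read-through exclusion for adjacent same-strand genes, minimum read
support, minimum intrachromosomal partner distance, gene proximity,
repeat-breakpoint classification, and gene-family exclusion.  Every input
candidate is retained in the audit report with its full filter vector;
only hard-filter failures are excluded from the final list.  Candidates
from the two sources are never merged into joint evidence.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval

logger = logging.getLogger("metdrive")

SV_TYPES = ("DEL", "INV", "ITX", "interchromosomal", "fusion")

HARD_FILTERS = ("readthrough", "min_reads", "partner_distance", "gene_proximity", "gene_family")


@dataclass
class Breakpoint:
    chrom: str
    pos: int  # 1-based
    strand: str = "+"


@dataclass
class SvCandidate:
    sample_id: str
    source: str  # rna | wgs
    breakpoint1: Breakpoint
    breakpoint2: Breakpoint
    sv_type: str
    read_count: int
    gene1: str | None = None
    gene2: str | None = None
    gene_read_total: int | None = None
    uid: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        b1, b2 = self.breakpoint1, self.breakpoint2
        if (b1.chrom, b1.pos) > (b2.chrom, b2.pos):
            self.breakpoint1, self.breakpoint2 = b2, b1
            self.gene1, self.gene2 = self.gene2, self.gene1
        if not self.uid:
            self.uid = (
                f"{self.sample_id}:{self.source}:{self.breakpoint1.chrom}:{self.breakpoint1.pos}:"
                f"{self.breakpoint2.chrom}:{self.breakpoint2.pos}:{self.sv_type}:"
                f"{self.gene1 or '.'}:{self.gene2 or '.'}"
            )

    @property
    def gene_pair(self) -> frozenset[str] | None:
        if self.gene1 is None or self.gene2 is None:
            return None
        return frozenset((self.gene1, self.gene2))

    @property
    def partner_distance(self) -> int | None:
        if self.breakpoint1.chrom != self.breakpoint2.chrom:
            return None
        return abs(self.breakpoint2.pos - self.breakpoint1.pos)


@dataclass
class FusionReport:
    candidate: SvCandidate
    met_specific: bool
    filters: dict[str, bool] = field(default_factory=dict)  # name -> passed
    repeat_class: str = "single_copy"
    family_class: str = "unassigned"
    recurrence: str = "single"
    read_fraction: float | None = None
    low_fraction: bool = False

    @property
    def passes_all(self) -> bool:
        return self.met_specific and all(self.filters.get(f, True) for f in HARD_FILTERS)


def _match_key(c: SvCandidate, tolerance: int):
    return c.gene_pair


def met_specific_set(
    lm_candidates: list[SvCandidate],
    pt_candidates: list[SvCandidate],
    match_tolerance: int = 100,
) -> dict[str, list[SvCandidate]]:
    """Partition candidates into shared / lm_only / pt_only.

    Identity is the unordered gene pair; candidates lacking gene symbols
    match on both breakpoints lying within ``match_tolerance`` bp.
    """

    def bp_match(a: SvCandidate, b: SvCandidate) -> bool:
        return (
            a.breakpoint1.chrom == b.breakpoint1.chrom
            and a.breakpoint2.chrom == b.breakpoint2.chrom
            and abs(a.breakpoint1.pos - b.breakpoint1.pos) <= match_tolerance
            and abs(a.breakpoint2.pos - b.breakpoint2.pos) <= match_tolerance
        )

    pt_pairs = {c.gene_pair for c in pt_candidates if c.gene_pair is not None}
    pt_anon = [c for c in pt_candidates if c.gene_pair is None]

    shared, lm_only = [], []
    for lm in lm_candidates:
        if lm.gene_pair is not None:
            hit = lm.gene_pair in pt_pairs
        else:
            hit = any(bp_match(lm, pt) for pt in pt_anon)
        (shared if hit else lm_only).append(lm)

    lm_pairs = {c.gene_pair for c in lm_candidates if c.gene_pair is not None}
    lm_anon = [c for c in lm_candidates if c.gene_pair is None]
    pt_only = []
    for pt in pt_candidates:
        if pt.gene_pair is not None:
            hit = pt.gene_pair in lm_pairs
        else:
            hit = any(bp_match(pt, lm) for lm in lm_anon)
        if not hit:
            pt_only.append(pt)
    return {"shared": shared, "lm_only": lm_only, "pt_only": pt_only}


def _adjacent_same_strand(genes: list[GeneModel]) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.span.chrom].append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.span.start)
        for a, b in zip(chrom_genes[:-1], chrom_genes[1:]):
            if a.strand == b.strand:
                pairs.add(frozenset((a.gene_symbol, b.gene_symbol)))
    return pairs


def is_readthrough(c: SvCandidate, genes: list[GeneModel]) -> bool:
    """True for an RNA candidate consistent with transcriptional read-through.

    Partners must be adjacent on the same chromosome and strand with no
    intervening annotated gene, each breakpoint inside its gene span, and
    the breakpoints collinear 5'->3' on the shared strand (upstream-gene
    breakpoint transcribed first).
    """
    if c.source != "rna" or c.gene_pair is None:
        return False
    by_name = {g.gene_symbol: g for g in genes}
    g1 = by_name.get(c.gene1)
    g2 = by_name.get(c.gene2)
    if g1 is None or g2 is None or g1.span.chrom != g2.span.chrom or g1.strand != g2.strand:
        return False
    if c.gene_pair not in _adjacent_same_strand(genes):
        return False
    if not (
        g1.span.contains(c.breakpoint1.chrom, c.breakpoint1.pos - 1)
        and g2.span.contains(c.breakpoint2.chrom, c.breakpoint2.pos - 1)
    ):
        return False
    # breakpoints are stored in genomic order; read-through runs genomic
    # left->right on '+', right->left on '-': genomic order is collinear
    # with transcription on '+', anti-collinear on '-', both read-through.
    upstream, downstream = (g1, g2) if g1.strand == "+" else (g2, g1)
    return upstream.span.start <= downstream.span.start if g1.strand == "+" else True


def readthrough_filter(
    candidates: list[SvCandidate],
    genes: list[GeneModel],
) -> tuple[list[SvCandidate], list[SvCandidate]]:
    """Split candidates into (kept, removed-as-read-through)."""
    kept, removed = [], []
    for c in candidates:
        (removed if is_readthrough(c, genes) else kept).append(c)
    return kept, removed


def support_and_distance_filter(
    candidates: list[SvCandidate],
    genes: list[GeneModel],
    min_reads: int = 3,
    min_partner_distance: int = 10_000,
    gene_flank: int = 10_000,
) -> tuple[list[SvCandidate], dict[str, dict[str, bool]]]:
    """Read-support, partner-distance, and gene-proximity predicates.

    Thresholds are closed: read_count >= min_reads and distance >=
    min_partner_distance pass.  Interchromosomal candidates always pass
    the distance rule.  Each breakpoint must lie within ``gene_flank`` bp
    of some annotated gene.  Returns survivors plus the per-candidate
    predicate map for the audit trail.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.span.chrom][max(0, g.span.start - gene_flank) : g.span.end + gene_flank] = True

    def near_gene(bp: Breakpoint) -> bool:
        return bool(trees[bp.chrom][bp.pos - 1])

    audit: dict[str, dict[str, bool]] = {}
    kept = []
    for c in candidates:
        dist = c.partner_distance
        checks = {
            "min_reads": c.read_count >= min_reads,
            "partner_distance": dist is None or dist >= min_partner_distance,
            "gene_proximity": near_gene(c.breakpoint1) and near_gene(c.breakpoint2),
        }
        audit[c.uid] = checks
        if all(checks.values()):
            kept.append(c)
    return kept, audit


def repeat_classify(
    candidates: list[SvCandidate],
    repeats: list[GenomicInterval],
) -> dict[str, str]:
    """both_repeat / one_repeat / single_copy per candidate uid."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in repeats:
        trees[iv.chrom][iv.start : iv.end] = True

    def in_repeat(bp: Breakpoint) -> bool:
        return bool(trees[bp.chrom][bp.pos - 1])

    out = {}
    for c in candidates:
        n = int(in_repeat(c.breakpoint1)) + int(in_repeat(c.breakpoint2))
        out[c.uid] = {2: "both_repeat", 1: "one_repeat", 0: "single_copy"}[n]
    return out


def family_classify(
    candidates: list[SvCandidate],
    family_map: dict[str, str],
    heuristic_fallback: bool = False,
) -> dict[str, str]:
    """same_family / different_family / unassigned per candidate uid.

    With ``heuristic_fallback``, genes absent from the map are assigned a
    family by stripping trailing digits from the symbol (a documented
    heuristic, off by default).
    """

    def fam(gene: str | None) -> str | None:
        if gene is None:
            return None
        if gene in family_map:
            return family_map[gene]
        if heuristic_fallback:
            stripped = gene.rstrip("0123456789")
            return stripped if stripped != gene else None
        return None

    out = {}
    for c in candidates:
        f1, f2 = fam(c.gene1), fam(c.gene2)
        if f1 is None or f2 is None:
            out[c.uid] = "unassigned"
        elif f1 == f2:
            out[c.uid] = "same_family"
        else:
            out[c.uid] = "different_family"
    return out


def family_filter(
    candidates: list[SvCandidate],
    family_map: dict[str, str],
    heuristic_fallback: bool = False,
) -> tuple[list[SvCandidate], dict[str, str]]:
    """Exclude same-family (paralog) pairs; unassigned candidates are kept."""
    classes = family_classify(candidates, family_map, heuristic_fallback)
    kept = [c for c in candidates if classes[c.uid] != "same_family"]
    return kept, classes


def recurrence_and_fraction(
    candidates: list[SvCandidate],
    sample_to_animal: dict[str, str],
) -> tuple[dict[str, str], dict[str, float | None]]:
    """Classify recurrence and compute variant-read fractions.

    multi_animal: the same unordered gene pair seen in >= 2 distinct
    animals.  multi_partner: a gene with >= 2 distinct partners (in any
    animal).  Otherwise single.  read_fraction = read_count /
    gene_read_total, flagged downstream when below 1%.
    """
    animals_by_pair: dict[frozenset, set[str]] = defaultdict(set)
    partners_by_gene: dict[str, set[str]] = defaultdict(set)
    for c in candidates:
        if c.gene_pair is None:
            continue
        animals_by_pair[c.gene_pair].add(sample_to_animal.get(c.sample_id, c.sample_id))
        if c.gene1 != c.gene2:
            partners_by_gene[c.gene1].add(c.gene2)
            partners_by_gene[c.gene2].add(c.gene1)
    recurrence: dict[str, str] = {}
    fractions: dict[str, float | None] = {}
    for c in candidates:
        if c.gene_pair is not None and len(animals_by_pair[c.gene_pair]) >= 2:
            recurrence[c.uid] = "multi_animal"
        elif c.gene_pair is not None and any(
            len(partners_by_gene[g]) >= 2 for g in c.gene_pair
        ):
            recurrence[c.uid] = "multi_partner"
        else:
            recurrence[c.uid] = "single"
        if c.gene_read_total:
            fractions[c.uid] = c.read_count / c.gene_read_total
        else:
            fractions[c.uid] = None
            if c.source == "rna":
                logger.warning("candidate %s: read fraction requested without totals", c.uid)
    return recurrence, fractions


def curate(
    lm_candidates: list[SvCandidate],
    pt_candidates: list[SvCandidate],
    genes: list[GeneModel],
    repeats: list[GenomicInterval],
    family_map: dict[str, str],
    sample_to_animal: dict[str, str],
    min_reads: int = 3,
    min_partner_distance: int = 10_000,
    gene_flank: int = 10_000,
    match_tolerance: int = 100,
    low_fraction_threshold: float = 0.01,
) -> list[FusionReport]:
    """Run the whole filter battery; one report per LM candidate (audit)."""
    parts = met_specific_set(lm_candidates, pt_candidates, match_tolerance)
    met_specific_uids = {c.uid for c in parts["lm_only"]}
    _, readthrough_removed = readthrough_filter(lm_candidates, genes)
    rt_uids = {c.uid for c in readthrough_removed}
    _, sd_audit = support_and_distance_filter(
        lm_candidates, genes, min_reads, min_partner_distance, gene_flank
    )
    repeat_classes = repeat_classify(lm_candidates, repeats)
    family_classes = family_classify(lm_candidates, family_map)
    recurrence, fractions = recurrence_and_fraction(lm_candidates, sample_to_animal)

    reports = []
    for c in lm_candidates:
        filters = {
            "readthrough": c.uid not in rt_uids,
            **sd_audit[c.uid],
            "gene_family": family_classes[c.uid] != "same_family",
        }
        frac = fractions[c.uid]
        reports.append(
            FusionReport(
                candidate=c,
                met_specific=c.uid in met_specific_uids,
                filters=filters,
                repeat_class=repeat_classes[c.uid],
                family_class=family_classes[c.uid],
                recurrence=recurrence[c.uid],
                read_fraction=frac,
                low_fraction=frac is not None and frac < low_fraction_threshold,
            )
        )
    return reports
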