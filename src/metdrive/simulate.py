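"""Synthetic matched PT/LM cohorts with planted ground truth.

The generator emulates the data the screen consumes, starting at the
call level (no reads): per-sample, per-caller SNV call sets; allele-count
tracks at strain-informative heterozygous SNPs reflecting planted
allele-specific segments; RNA-fusion and WGS-SV candidate lists mixing
true events with the three artifact classes (read-through,
repeat-breakpoint, gene-family); and the annotation, repeat, family and
polymorphism side files.  Truth is serialized alongside the outputs.

Statistical model: per-site depth is Poisson(mean_depth) (shot noise
around the published average coverage); alt counts are
Binomial(depth, v) where v is the true variant allele fraction.  A
truncal heterozygous somatic variant in a lesion of tumor purity p has
v = p/2, so the default purity window [0.6, 0.95] realizes the 0.3-0.5
driver-VAF window.  ``count_model="expected"`` replaces both draws with
their rounded expectations — the generator's deterministic limit, used
for exact end-to-end recovery checks.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import expected_baf, expected_depth_factor
from .core import Cohort, GeneModel, GenomicInterval, GenomicSite, SampleRecord, site_to_codon
from .fusion import Breakpoint, SvCandidate
from .snv import CALLER_IDS, SnvCall
from . import io as mio

_BASES = "ACGT"

DEFAULT_STRAINS = ("C57BL/6J", "C57BL/10J", "CAST/EiJ", "MOLF/EiJ")


@dataclass
class SimConfig:
    n_animals: int = 6
    mets_per_animal: int = 4
    strains: tuple[str, ...] = DEFAULT_STRAINS
    mean_depth: float = 40.0
    purity_range: tuple[float, float] = (0.6, 0.95)
    driver_vaf_range: tuple[float, float] = (0.3, 0.5)
    caller_fp_rate: float = 0.02
    caller_fn_rate: float = 0.02
    snp_density: float = 2.5  # informative het SNPs per kb
    segment_length_range: tuple[int, int] = (60_000, 160_000)
    fusion_artifact_mix: dict = field(
        default_factory=lambda: {
            "read_through": 0.25,
            "repeat_breakpoint": 0.25,
            "gene_family": 0.25,
            "true_event": 0.25,
        }
    )
    seed: int = 0
    # generator internals (documented defaults, not dials)
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_600_000, "chr2": 4_000_000}
    )
    polyclonal_fraction: float = 0.4  # 2 of 5 animals in the study design
    n_markers_per_subclone: int = 12
    n_truncal_snvs: int = 5
    n_subclonal_per_lm: int = 4
    n_polymorphisms: int = 10
    n_decoy_sites: int = 200
    n_fusion_candidates: int = 8
    count_model: str = "binomial"  # binomial | expected

    def __post_init__(self) -> None:
        for p in (self.caller_fp_rate, self.caller_fn_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("caller rates must be probabilities")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for rng_pair in (self.purity_range, self.driver_vaf_range, self.segment_length_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError(f"range {rng_pair} not ordered")
        if self.count_model not in ("binomial", "expected"):
            raise ValueError("count_model must be 'binomial' or 'expected'")
        lo, hi = self.purity_range
        if not (self.driver_vaf_range[0] <= lo / 2 and hi / 2 <= self.driver_vaf_range[1]):
            raise ValueError(
                "purity_range must place truncal heterozygous VAF (purity/2) "
                "inside driver_vaf_range"
            )


@dataclass
class SimResult:
    """In-memory view of one simulated cohort plus its truth record."""

    cohort: Cohort
    calls: dict  # (sample_id, caller_id) -> list[SnvCall]
    allele_counts: dict  # sample_id -> DataFrame
    rna_candidates: list
    wgs_candidates: list
    genes: list
    repeats: list
    family_map: dict
    polymorphisms: set
    expression: dict
    purity: dict
    truth: dict


# ------------------------------------------------------------ gene layout

def _make_gene(
    symbol: str,
    chrom: str,
    start: int,
    strand: str,
    rng: np.random.Generator,
    family: str | None = None,
    n_exons: int = 2,
    exon_len: int = 120,
    intron_len: int = 2000,
) -> GeneModel:
    exons, seqs = [], []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len))
        seqs.append("".join(rng.choice(list(_BASES), size=exon_len)))
        pos += exon_len + intron_len
    span = GenomicInterval(chrom, start, pos - intron_len)
    return GeneModel(
        gene_symbol=symbol,
        family_id=family,
        strand=strand,
        span=span,
        exons=exons,
        exon_seqs=seqs,
        transcript_id=f"NM_{zlib.crc32(symbol.encode()) % 100000:05d}",
    )


def build_annotation(rng: np.random.Generator, chrom: str = "chr1"):
    """Deterministic gene layout on one chromosome.

    Driver genes, two paralog families, two adjacent same-strand pairs
    (read-through hosts), repeat-hosting genes, true-fusion partners and
    plain passengers, spaced so every fusion artifact class is decidable
    by construction.
    """
    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []
    cursor = 10_000

    def place(symbol, strand="+", family=None, gap=30_000, host_repeat=False):
        nonlocal cursor
        g = _make_gene(symbol, chrom, cursor, strand, rng, family=family)
        genes.append(g)
        if host_repeat:
            # repeat element inside the intron
            intron_start = g.exons[0].end + 200
            repeats.append(GenomicInterval(chrom, intron_start, intron_start + 800))
        cursor = g.span.end + gap
        return g

    place("drvA")
    place("drvB")
    place("drvC")
    # family members interleaved so paralog pairs are never adjacent
    # (adjacency is the read-through signature, a distinct artifact class)
    for sym in ("famA_1", "famB_1", "famA_2", "famB_2", "famA_3", "famB_3"):
        place(sym, family=sym[:4], gap=30_000)
    # adjacent same-strand pairs, 2 kb apart: read-through hosts
    place("rtA1", strand="+", gap=2_000)
    place("rtA2", strand="+", gap=40_000)
    place("rtB1", strand="-", gap=2_000)
    place("rtB2", strand="-", gap=40_000)
    for i in range(1, 5):
        place(f"rpt{i}", host_repeat=True, gap=40_000)
    for i in range(1, 7):
        place(f"tf{i}", gap=50_000)
    for i in range(1, 5):
        place(f"px{i}", gap=25_000)
    # intergenic repeats as well
    repeats.append(GenomicInterval(chrom, cursor + 5_000, cursor + 6_000))
    family_map = {g.gene_symbol: g.family_id for g in genes if g.family_id}
    return genes, repeats, family_map


def genomic_pos_of_cds_index(gene: GeneModel, ci: int) -> int:
    """1-based genomic position of CDS index ``ci`` (0-based, coding strand)."""
    total = sum(len(e) for e in gene.exons)
    fwd = ci if gene.strand == "+" else total - 1 - ci
    offset = 0
    for ex in gene.exons:
        if fwd < offset + len(ex):
            return ex.start + (fwd - offset) + 1
        offset += len(ex)
    raise ValueError("CDS index outside gene")


def _driver_site(gene: GeneModel, codon_index: int, codon_offset: int, alt_shift: int) -> GenomicSite:
    ci = (codon_index - 1) * 3 + codon_offset
    pos = genomic_pos_of_cds_index(gene, ci)
    # reference base on the genome-forward strand at pos
    for ex, seq in zip(gene.exons, gene.exon_seqs):
        if ex.start < pos <= ex.end:
            ref = seq[pos - 1 - ex.start]
            break
    alts = [b for b in _BASES if b != ref]
    return GenomicSite(gene.span.chrom, pos, ref, alts[alt_shift % 3])


# ------------------------------------------------------------ cohort plan

def _plan_cohort(config: SimConfig) -> Cohort:
    records = []
    strains = list(config.strains)
    for a in range(config.n_animals):
        animal = f"A{a + 1:03d}"
        partner = strains[a % len(strains)]
        records.append(
            SampleRecord(
                sample_id=f"{animal}_PT1",
                animal_id=animal,
                tissue="PT",
                strain_cross="F1",
                partner_strain=partner,
                platforms=frozenset({"exome", "rna", "wgs"}),
            )
        )
        for m in range(config.mets_per_animal):
            records.append(
                SampleRecord(
                    sample_id=f"{animal}_LM{m + 1}",
                    animal_id=animal,
                    tissue="LM",
                    strain_cross="F1",
                    partner_strain=partner,
                    platforms=frozenset({"exome", "rna", "wgs"}),
                )
            )
    return Cohort(records)


def _draw_counts(rng, depth_mean: float, vaf: float, config: SimConfig) -> tuple[int, int]:
    if config.count_model == "expected":
        depth = max(1, round(depth_mean))
        alt = round(depth * vaf)
    else:
        depth = max(1, int(rng.poisson(depth_mean)))
        alt = int(rng.binomial(depth, vaf))
    return depth - alt, alt


def generate(config: SimConfig) -> SimResult:
    """Build one cohort entirely in memory."""
    rng = np.random.default_rng(config.seed)
    genes, repeats, family_map = build_annotation(rng)
    by_symbol = {g.gene_symbol: g for g in genes}
    cohort = _plan_cohort(config)
    animals = cohort.animals()
    purity = {
        r.sample_id: float(rng.uniform(*config.purity_range)) for r in cohort
    }

    n_poly_animals = int(round(config.polyclonal_fraction * len(animals)))
    poly_animals = set(
        a for a in animals[len(animals) - n_poly_animals :] if config.mets_per_animal >= 2
    )

    # ---- plan SNVs -------------------------------------------------
    truth_snvs: list[dict] = []
    used_positions: set[tuple[str, int]] = set()

    def register(site, kind, carriers, gene=None, met_specific=False):
        annot = {}
        if gene is not None:
            hit = site_to_codon(site, by_symbol[gene])
            if hit:
                annot = {"codon": hit[0], "aa_change": hit[1]}
        truth_snvs.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "kind": kind,
                "gene": gene,
                "met_specific": met_specific,
                "carriers": carriers,  # sample_id -> true vaf
                **annot,
            }
        )
        used_positions.add((site.chrom, site.pos))
        return site

    def lm_samples(animal, subclone=None):
        lms = [r.sample_id for r in cohort if r.animal_id == animal and r.tissue == "LM"]
        if animal not in poly_animals or subclone is None:
            return lms
        half = max(1, len(lms) // 2)
        return lms[:half] if subclone == 0 else lms[half:]

    def truncal_vaf(sample_id):
        return purity[sample_id] / 2.0

    # recurrent drivers: same codon in 2 animals (drvA), same codon with
    # different substitutions in 2 more (drvB), different codons in 2 (drvC)
    driver_plan: list[tuple[str, GenomicSite, str]] = []  # (animal, site, gene)
    if len(animals) >= 2:
        site = _driver_site(by_symbol["drvA"], codon_index=12, codon_offset=1, alt_shift=0)
        for a in animals[:2]:
            driver_plan.append((a, site, "drvA"))
    if len(animals) >= 4:
        for shift, a in zip((0, 1), animals[2:4]):
            site = _driver_site(by_symbol["drvB"], codon_index=8, codon_offset=0, alt_shift=shift)
            driver_plan.append((a, site, "drvB"))
    if len(animals) >= 6:
        for codon, a in zip((5, 17), animals[4:6]):
            site = _driver_site(by_symbol["drvC"], codon_index=codon, codon_offset=2, alt_shift=0)
            driver_plan.append((a, site, "drvC"))
    for animal, site, gene in driver_plan:
        carriers = {s: truncal_vaf(s) for s in lm_samples(animal, subclone=0)}
        register(site, "driver", carriers, gene=gene, met_specific=True)

    def random_site(chrom: str, lo: int, hi: int) -> GenomicSite:
        while True:
            pos = int(rng.integers(lo, hi))
            if (chrom, pos) in used_positions:
                continue
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            return GenomicSite(chrom, pos, str(ref), str(alt))

    chrom1_len = config.chrom_lengths["chr1"]
    intergenic_lo = max(g.span.end for g in genes) + 10_000

    for animal in animals:
        subclones = (0, 1) if animal in poly_animals else (0,)
        for sc in subclones:
            carriers_s = lm_samples(animal, subclone=sc)
            for _ in range(config.n_markers_per_subclone):
                site = random_site("chr1", intergenic_lo, chrom1_len)
                register(
                    site, "marker", {s: truncal_vaf(s) for s in carriers_s}, met_specific=True
                )
        pt_and_lm = [r.sample_id for r in cohort if r.animal_id == animal]
        for _ in range(config.n_truncal_snvs):
            site = random_site("chr1", intergenic_lo, chrom1_len)
            register(site, "truncal", {s: truncal_vaf(s) for s in pt_and_lm})
        for lm in lm_samples(animal):
            for _ in range(config.n_subclonal_per_lm):
                site = random_site("chr1", intergenic_lo, chrom1_len)
                cf = float(rng.uniform(0.1, 0.4))
                register(site, "subclonal", {lm: purity[lm] * cf / 2.0})

    polymorphisms: set[tuple[str, int, str, str]] = set()
    all_samples = [r.sample_id for r in cohort]
    for _ in range(config.n_polymorphisms):
        site = random_site("chr1", intergenic_lo, chrom1_len)
        register(site, "polymorphism", {s: 0.5 for s in all_samples})
        polymorphisms.add(site.key)

    decoys = [random_site("chr1", intergenic_lo, chrom1_len) for _ in range(config.n_decoy_sites)]

    # ---- emit caller call sets -------------------------------------
    calls: dict[tuple[str, str], list[SnvCall]] = {
        (s, c): [] for s in all_samples for c in CALLER_IDS
    }
    for entry in truth_snvs:
        site = GenomicSite(entry["chrom"], entry["pos"], entry["ref"], entry["alt"])
        for sample_id in sorted(entry["carriers"]):
            vaf = entry["carriers"][sample_id]
            for caller in CALLER_IDS:
                if config.caller_fn_rate and rng.random() < config.caller_fn_rate:
                    continue
                ref_n, alt_n = _draw_counts(rng, config.mean_depth, vaf, config)
                if alt_n == 0:
                    continue
                qual = min(99.0, 3.0 * alt_n)
                if config.count_model == "binomial":
                    qual = min(99.0, qual + float(rng.uniform(0, 1)))
                calls[(sample_id, caller)].append(
                    SnvCall(site, sample_id, caller, qual, ref_n, alt_n)
                )
    if config.caller_fp_rate:
        for sample_id in all_samples:
            for caller in CALLER_IDS:
                for decoy in decoys:
                    if rng.random() < config.caller_fp_rate:
                        alt_n = int(rng.integers(2, 5))
                        depth = max(alt_n + 1, int(rng.poisson(config.mean_depth)))
                        qual = float(rng.uniform(10.0, 60.0))
                        calls[(sample_id, caller)].append(
                            SnvCall(decoy, sample_id, caller, qual, depth - alt_n, alt_n)
                        )

    # ---- plan CNV segments -----------------------------------------
    chrom2 = "chr2"
    chrom2_len = config.chrom_lengths[chrom2]
    cursor = {"v": 20_000}

    def next_slot(length: int) -> GenomicInterval:
        start = cursor["v"]
        if start + length > chrom2_len - 10_000:
            raise ValueError("chr2 too short for planned segments; enlarge chrom_lengths")
        cursor["v"] = start + length + 20_000
        return GenomicInterval(chrom2, start, start + length)

    def seg_len() -> int:
        lo, hi = config.segment_length_range
        return int(rng.integers(lo, hi + 1))

    truth_segments: dict[str, list[dict]] = {s: [] for s in all_samples}

    def lost_allele(partner: str) -> str:
        # MOLF crosses preferentially lose FVB; other partners lose the
        # partner allele (the direction pattern seen in these crosses)
        return "FVB" if partner == "MOLF/EiJ" else "partner"

    def plant(samples: list[str], interval: GenomicInterval, state: str, allele: str, met: bool):
        for s in samples:
            truth_segments[s].append(
                {
                    "chrom": interval.chrom,
                    "start": interval.start,
                    "end": interval.end,
                    "state": state,
                    "allele": allele,
                    "met_specific": met,
                }
            )

    # two cohort-level recurrent loss regions; each is carried by two
    # monoclonal animals, and polyclonal animals carry R1 in one subclone
    # and R2 in the other so their lesions split across cohort clades
    region1 = next_slot(120_000)
    region2 = next_slot(120_000)
    region_carriers: dict[int, list[str]] = {0: [], 1: []}
    mono_animals = [a for a in animals if a not in poly_animals]
    for i, animal in enumerate(mono_animals):
        which = i % 2
        iv = region1 if which == 0 else region2
        partner = cohort.pt_samples_of_animal(animal)[0].partner_strain
        plant(lm_samples(animal), iv, "loss", lost_allele(partner), True)
        region_carriers[which].append(animal)
    for animal in sorted(poly_animals):
        partner = cohort.pt_samples_of_animal(animal)[0].partner_strain
        plant(lm_samples(animal, subclone=0), region1, "loss", lost_allele(partner), True)
        plant(lm_samples(animal, subclone=1), region2, "loss", lost_allele(partner), True)
        region_carriers[0].append(animal)
        region_carriers[1].append(animal)

    for animal in animals:
        partner = cohort.pt_samples_of_animal(animal)[0].partner_strain
        pt_ids = [r.sample_id for r in cohort.pt_samples_of_animal(animal)]
        shared = next_slot(seg_len())
        plant(pt_ids + lm_samples(animal), shared, "loss", lost_allele(partner), False)
        subclones = (0, 1) if animal in poly_animals else (0,)
        for sc in subclones:
            iv = next_slot(seg_len())
            plant(lm_samples(animal, subclone=sc), iv, "loss", lost_allele(partner), True)
            if partner == "MOLF/EiJ":
                iv2 = next_slot(seg_len())
                plant(lm_samples(animal, subclone=sc), iv2, "gain", "partner", True)

    # ---- allele-count tracks ---------------------------------------
    snp_positions: dict[str, np.ndarray] = {}
    for chrom, length in sorted(config.chrom_lengths.items()):
        n_snps = int(length / 1000 * config.snp_density)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))
        snp_positions[chrom] = pos

    allele_counts: dict[str, pd.DataFrame] = {}
    for sample_id in all_samples:
        p = purity[sample_id]
        rows = []
        segs = truth_segments[sample_id]
        for chrom in sorted(snp_positions):
            for pos in snp_positions[chrom]:
                state = "neutral"
                for sg in segs:
                    if sg["chrom"] == chrom and sg["start"] < pos <= sg["end"]:
                        which = "B" if sg["allele"] == "partner" else "A"
                        state = f"{sg['state']}_of_{which}"
                        break
                baf = expected_baf(p, state)
                depth_mean = config.mean_depth * expected_depth_factor(p, state)
                if config.count_model == "expected":
                    depth = max(1, round(depth_mean))
                    count_b = round(depth * baf)
                else:
                    depth = max(1, int(rng.poisson(depth_mean)))
                    count_b = int(rng.binomial(depth, baf))
                rows.append((chrom, int(pos), depth - count_b, count_b))
        allele_counts[sample_id] = pd.DataFrame(
            rows, columns=["chrom", "pos", "count_A", "count_B"]
        )

    # ---- fusion / SV candidates ------------------------------------
    # pairs chosen so each class fails (or is flagged by) exactly its own
    # rule: read-through pairs are adjacent same-strand; repeat and true
    # pairs are non-adjacent and far apart; family pairs share family_id
    class_pools = {
        "read_through": [("rtA1", "rtA2"), ("rtB2", "rtB1")],
        "repeat_breakpoint": [("rpt1", "rpt3"), ("rpt2", "rpt4")],
        "gene_family": [("famA_1", "famA_2"), ("famA_2", "famA_3"), ("famB_1", "famB_3")],
        "true_event": [("tf1", "tf4"), ("tf2", "tf5"), ("tf3", "tf6")],
    }
    repeat_by_host: dict[str, GenomicInterval] = {}
    for g in genes:
        for iv in repeats:
            if g.span.start <= iv.start and iv.end <= g.span.end:
                repeat_by_host[g.gene_symbol] = iv

    def breakpoint_in(gene_symbol: str, klass: str) -> Breakpoint:
        g = by_symbol[gene_symbol]
        if klass == "repeat_breakpoint":
            iv = repeat_by_host[gene_symbol]
            pos = int(rng.integers(iv.start + 1, iv.end + 1))
        else:
            ex = g.exons[0]
            pos = int(rng.integers(ex.start + 1, ex.end + 1))
        return Breakpoint(g.span.chrom, pos, g.strand)

    rna_candidates: list[SvCandidate] = []
    wgs_candidates: list[SvCandidate] = []
    truth_fusions: list[dict] = []
    mix_names = sorted(config.fusion_artifact_mix)
    mix_p = np.array([config.fusion_artifact_mix[k] for k in mix_names], dtype=float)
    mix_p = mix_p / mix_p.sum()

    def emit(sample_id: str, klass: str, source: str, shared_pt: str | None):
        pair = class_pools[klass][int(rng.integers(len(class_pools[klass])))]
        reads = int(rng.integers(3, 16))
        bp1 = breakpoint_in(pair[0], klass)
        bp2 = breakpoint_in(pair[1], klass)
        if source == "rna":
            flagged_low = klass == "true_event" and rng.random() < 0.5
            total = reads * 500 if flagged_low else reads * 30
            cand = SvCandidate(
                sample_id, "rna", bp1, bp2, "fusion", reads, pair[0], pair[1], total
            )
            rna_candidates.append(cand)
        else:
            sv_type = str(rng.choice(["DEL", "INV", "ITX"]))
            cand = SvCandidate(sample_id, "wgs", bp1, bp2, sv_type, reads, pair[0], pair[1])
            wgs_candidates.append(cand)
        truth_fusions.append(
            {
                "uid": cand.uid,
                "sample_id": sample_id,
                "source": source,
                "class": klass,
                "gene1": cand.gene1,
                "gene2": cand.gene2,
                "lm_only": shared_pt is None,
            }
        )
        if shared_pt is not None:
            pt_reads = int(rng.integers(3, 16))
            if source == "rna":
                ptc = SvCandidate(
                    shared_pt, "rna", bp1, bp2, "fusion", pt_reads, pair[0], pair[1],
                    pt_reads * 30,
                )
                rna_candidates.append(ptc)
            else:
                ptc = SvCandidate(
                    shared_pt, "wgs", bp1, bp2, cand.sv_type, pt_reads, pair[0], pair[1]
                )
                wgs_candidates.append(ptc)
            truth_fusions.append(
                {
                    "uid": ptc.uid,
                    "sample_id": shared_pt,
                    "source": source,
                    "class": klass,
                    "gene1": ptc.gene1,
                    "gene2": ptc.gene2,
                    "lm_only": False,
                }
            )

    for animal in animals:
        pt_id = cohort.pt_samples_of_animal(animal)[0].sample_id
        for lm in lm_samples(animal):
            counts = rng.multinomial(config.n_fusion_candidates, mix_p)
            for klass, n in zip(mix_names, counts):
                for _ in range(int(n)):
                    source = "rna" if klass == "read_through" else str(
                        rng.choice(["rna", "wgs"])
                    )
                    shared = None
                    if klass != "true_event" and rng.random() < 0.5:
                        shared = pt_id
                    emit(lm, klass, source, shared)

    # ---- expression flags ------------------------------------------
    expression = {g.gene_symbol: True for g in genes}
    expression["px3"] = False
    expression["px4"] = False

    clonality_truth = {
        a: ("polyclonal_seeding" if a in poly_animals else "monoclonal_seeding")
        if config.mets_per_animal >= 2
        else "indeterminate"
        for a in animals
    }

    truth = {
        "seed": config.seed,
        "purity": {k: round(v, 6) for k, v in sorted(purity.items())},
        "snvs": truth_snvs,
        "segments": truth_segments,
        "recurrent_regions": [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "state": "loss",
                "animals": sorted(region_carriers[which]),
            }
            for which, iv in ((0, region1), (1, region2))
        ],
        "fusions": truth_fusions,
        "clonality": clonality_truth,
    }
    return SimResult(
        cohort=cohort,
        calls=calls,
        allele_counts=allele_counts,
        rna_candidates=rna_candidates,
        wgs_candidates=wgs_candidates,
        genes=genes,
        repeats=repeats,
        family_map=family_map,
        polymorphisms=polymorphisms,
        expression=expression,
        purity=purity,
        truth=truth,
    )


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate a cohort and write the full run directory.

    Layout: sample_sheet.tsv, genes.tsv, repeats.bed, family_map.tsv,
    polymorphisms.tsv, expression.tsv, calls/<sample>.<caller>.vcf,
    allele_counts/<sample>.tsv, fusions/{rna,wgs}_candidates.tsv,
    truth.json.  Byte-identical for a fixed seed and config.
    """
    result = generate(config)
    out = Path(out_dir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    (out / "allele_counts").mkdir(exist_ok=True)
    (out / "fusions").mkdir(exist_ok=True)

    with open(out / "sample_sheet.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tanimal_id\ttissue\tstrain_cross\tpartner_strain\tplatforms\n")
        for r in result.cohort:
            fh.write(
                f"{r.sample_id}\t{r.animal_id}\t{r.tissue}\t{r.strain_cross}\t"
                f"{r.partner_strain or ''}\t{','.join(sorted(r.platforms))}\n"
            )
    mio.write_gene_annotation(result.genes, out / "genes.tsv")
    mio.write_bed(result.repeats, out / "repeats.bed")
    with open(out / "family_map.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\tfamily\n")
        for gene in sorted(result.family_map):
            fh.write(f"{gene}\t{result.family_map[gene]}\n")
    with open(out / "polymorphisms.tsv", "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(result.polymorphisms):
            fh.write("\t".join(str(x) for x in key) + "\n")
    with open(out / "expression.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene\ttranscribed\n")
        for gene in sorted(result.expression):
            fh.write(f"{gene}\t{int(result.expression[gene])}\n")
    for (sample_id, caller), call_list in sorted(result.calls.items()):
        mio.write_vcf(call_list, out / "calls" / f"{sample_id}.{caller}.vcf", sample_id, caller)
    for sample_id in sorted(result.allele_counts):
        mio.write_allele_counts(
            result.allele_counts[sample_id], out / "allele_counts" / f"{sample_id}.tsv"
        )
    mio.write_fusion_rna(result.rna_candidates, out / "fusions" / "rna_candidates.tsv")
    mio.write_sv_wgs(result.wgs_candidates, out / "fusions" / "wgs_candidates.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(result.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "sim_config.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True, default=list)
        fh.write("\n")
    return result
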