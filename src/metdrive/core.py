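"""Shared domain types and coordinate conventions.

Variant sites are stored 1-based (VCF convention); all interval arithmetic
is 0-based half-open (BED convention).  Only single-nucleotide substitutions
are modeled.  Each gene carries one canonical transcript; codon indices are
always reported against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

logger = logging.getLogger("metdrive")

BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TISSUES = ("PT", "LM")
STRAIN_CROSSES = ("FVB_homozygous", "F1")
PLATFORMS = ("exome", "rna", "wgs")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single-base substitution site, 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def to_interval(self) -> "GenomicInterval":
        """Length-1 interval in 0-based half-open coordinates."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def to_site(self, ref: str, alt: str) -> GenomicSite:
        """Inverse of :meth:`GenomicSite.to_interval` for length-1 intervals."""
        if len(self) != 1:
            raise ValueError("only length-1 intervals convert to a site")
        return GenomicSite(self.chrom, self.start + 1, ref, alt)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    animal_id: str
    tissue: str  # PT | LM
    strain_cross: str  # FVB_homozygous | F1
    partner_strain: str | None = None
    platforms: frozenset[str] = frozenset({"exome"})

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for sample {self.sample_id}")
        if self.strain_cross not in STRAIN_CROSSES:
            raise ValueError(
                f"unknown strain_cross {self.strain_cross!r} for sample {self.sample_id}"
            )
        if self.strain_cross == "F1" and not self.partner_strain:
            raise ValueError(f"F1 sample {self.sample_id} needs a partner_strain")
        bad = set(self.platforms) - set(PLATFORMS)
        if bad:
            raise ValueError(f"unknown platforms {sorted(bad)} for sample {self.sample_id}")


class Cohort:
    """Validated sample collection with matched-pair bookkeeping.

    Iterating yields :class:`SampleRecord` in sheet order.  ``warnings``
    holds non-fatal validation messages (e.g. an LM without any matched PT,
    which makes the metastasis-enrichment criterion unevaluable for it).
    """

    def __init__(self, records: list[SampleRecord]):
        seen: set[str] = set()
        for r in records:
            if r.sample_id in seen:
                raise ValueError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
        self.records = list(records)
        self.warnings: list[str] = []
        pt_animals = {r.animal_id for r in records if r.tissue == "PT"}
        for r in records:
            if r.tissue == "LM" and r.animal_id not in pt_animals:
                msg = f"LM sample {r.sample_id} (animal {r.animal_id}) has no matched PT"
                self.warnings.append(msg)
                logger.warning(msg)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sample(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    @property
    def sample_to_animal(self) -> dict[str, str]:
        return {r.sample_id: r.animal_id for r in self.records}

    def by_tissue(self, tissue: str) -> list[SampleRecord]:
        return [r for r in self.records if r.tissue == tissue]

    def pt_samples_of_animal(self, animal_id: str) -> list[SampleRecord]:
        return [r for r in self.records if r.animal_id == animal_id and r.tissue == "PT"]

    def animals(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.animal_id not in out:
                out.append(r.animal_id)
        return out


def load_sample_sheet(path: str | Path) -> Cohort:
    """Read a TSV sample sheet into a validated :class:`Cohort`.

    Required header: sample_id, animal_id, tissue, strain_cross,
    partner_strain, platforms (comma-joined tokens).
    """
    path = Path(path)
    records: list[SampleRecord] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        required = ["sample_id", "animal_id", "tissue", "strain_cross", "partner_strain", "platforms"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: sample sheet missing columns {missing}")
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                partner = parts[idx["partner_strain"]] or None
                platforms = frozenset(
                    tok for tok in parts[idx["platforms"]].split(",") if tok
                )
                records.append(
                    SampleRecord(
                        sample_id=parts[idx["sample_id"]],
                        animal_id=parts[idx["animal_id"]],
                        tissue=parts[idx["tissue"]],
                        strain_cross=parts[idx["strain_cross"]],
                        partner_strain=partner,
                        platforms=platforms,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return Cohort(records)


@dataclass
class GeneModel:
    """One gene with a single canonical transcript.

    ``exons`` are coding exons in genomic order; ``exon_seqs`` hold the
    genome-forward (plus-strand) reference sequence of each exon so the
    coding sequence can be spliced without an external FASTA.  ``frames``
    are the reading-frame offsets at each exon's transcription-order start.
    """

    gene_symbol: str
    strand: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    exon_seqs: list[str]
    frames: list[int] = field(default_factory=list)
    family_id: str | None = None
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_symbol}")
        if len(self.exons) != len(self.exon_seqs):
            raise ValueError(f"{self.gene_symbol}: exon/seq count mismatch")
        prev_end = None
        for ex, seq in zip(self.exons, self.exon_seqs):
            if ex.chrom != self.span.chrom or ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"{self.gene_symbol}: exon {ex} outside span {self.span}")
            if len(seq) != len(ex):
                raise ValueError(f"{self.gene_symbol}: exon sequence length mismatch at {ex}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_symbol}: exons overlap or unordered")
            prev_end = ex.end
        if not self.frames:
            self.frames = self._derived_frames()
        elif self.frames != self._derived_frames():
            raise ValueError(f"{self.gene_symbol}: frame offsets inconsistent with exon lengths")

    def _derived_frames(self) -> list[int]:
        order = self.exons if self.strand == "+" else self.exons[::-1]
        frames_tx = []
        cum = 0
        for ex in order:
            frames_tx.append(cum % 3)
            cum += len(ex)
        return frames_tx if self.strand == "+" else frames_tx[::-1]

    @property
    def cds(self) -> str:
        """Spliced coding sequence in transcription order (coding strand)."""
        seq = "".join(self.exon_seqs)
        return seq if self.strand == "+" else revcomp(seq)

    def cds_index(self, site: GenomicSite) -> int | None:
        """0-based position of ``site`` within the CDS, or None if non-coding."""
        if not self.span.contains(site.chrom, site.pos - 1):
            raise ValueError(f"site not in gene: {site.chrom}:{site.pos} vs {self.gene_symbol}")
        p0 = site.pos - 1
        offset = 0
        for ex in self.exons:
            if ex.start <= p0 < ex.end:
                fwd = offset + (p0 - ex.start)
                if self.strand == "+":
                    return fwd
                return sum(len(e) for e in self.exons) - 1 - fwd
            offset += len(ex)
        return None


def site_to_codon(site: GenomicSite, gene: GeneModel) -> tuple[int, str] | None:
    """Map a substitution to (codon_index, amino-acid change like "G12D").

    Returns None for sites inside the gene span but outside coding exons
    (intronic/UTR).  Raises ValueError for sites outside the gene span.
    The change is computed on the coding strand with the standard code;
    stop codons are written ``*``.
    """
    ci = gene.cds_index(site)
    if ci is None:
        return None
    cds = gene.cds
    ref_base = site.ref if gene.strand == "+" else site.ref.translate(_COMPLEMENT)
    alt_base = site.alt if gene.strand == "+" else site.alt.translate(_COMPLEMENT)
    if cds[ci] != ref_base:
        raise ValueError(
            f"reference mismatch at {site.chrom}:{site.pos} in {gene.gene_symbol}: "
            f"annotation has {cds[ci]}, site ref is {ref_base} (coding strand)"
        )
    codon_index = ci // 3 + 1
    start = (codon_index - 1) * 3
    codon = cds[start : start + 3]
    if len(codon) < 3:
        return None  # trailing partial codon in annotation
    mutant = codon[: ci - start] + alt_base + codon[ci - start + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    return codon_index, f"{aa_ref}{codon_index}{aa_alt}"
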