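"""Readers and writers for the pipeline's external formats.

VCF 4.2 call sets (one sample, one caller per file; FORMAT AD/DP), BED
intervals, the 12-column gene-annotation table with embedded exon
sequences, allele-count tracks at strain-informative SNPs, the RNA-fusion
and WGS-SV TSV dialects, family maps, expression flags, and polymorphism
site lists.  Output TSVs carry a header comment with the config hash and
tool version so every result file names the run that produced it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .core import BASES, GeneModel, GenomicInterval, GenomicSite
from .fusion import Breakpoint, SvCandidate
from .snv import SnvCall

logger = logging.getLogger("metdrive")

__version__ = "0.1.0"


# ---------------------------------------------------------------- VCF

def write_vcf(
    calls: list[SnvCall],
    path: str | Path,
    sample_id: str,
    caller_id: str,
) -> None:
    """Write SNV calls as a minimal single-sample VCF 4.2 with AD/DP."""
    chroms = sorted({c.site.chrom for c in calls})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={caller_id}",
        *[f"##contig=<ID={ch}>" for ch in chroms],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    for c in sorted(calls, key=lambda c: (c.site.chrom, c.site.pos, c.site.alt)):
        lines.append(
            f"{c.site.chrom}\t{c.site.pos}\t.\t{c.site.ref}\t{c.site.alt}\t"
            f"{c.qual:.1f}\tPASS\t.\tGT:AD:DP\t"
            f"0/1:{c.ref_count},{c.alt_count}:{c.ref_count + c.alt_count}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vcf(path: str | Path, caller_id: str | None = None) -> list[SnvCall]:
    """Read a single-sample VCF into SnvCall records.

    Multiallelic records are split into one call per alt allele; non-SNV
    records are skipped (count logged).  caller_id defaults to the VCF's
    ##source header.  Missing AD is an error naming the record.
    """
    path = str(path)
    vcf = VCF(path)
    if caller_id is None:
        for line in vcf.raw_header.splitlines():
            if line.startswith("##source="):
                caller_id = line.split("=", 1)[1].strip()
                break
    if caller_id is None:
        raise ValueError(f"{path}: no caller_id given and no ##source header")
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected exactly one sample, got {vcf.samples}")
    sample_id = vcf.samples[0]
    calls: list[SnvCall] = []
    skipped = 0
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {var.CHROM}:{var.POS} lacks FORMAT/AD")
        ad = ad[0]
        ref_count = int(ad[0])
        for i, alt in enumerate(var.ALT):
            if len(var.REF) != 1 or len(alt) != 1 or alt not in BASES:
                skipped += 1
                continue
            calls.append(
                SnvCall(
                    site=GenomicSite(var.CHROM, var.POS, var.REF, alt),
                    sample_id=sample_id,
                    caller_id=caller_id,
                    qual=round(float(var.QUAL), 4) if var.QUAL is not None else 0.0,
                    ref_count=ref_count,
                    alt_count=int(ad[i + 1]) if i + 1 < len(ad) else 0,
                )
            )
    if skipped:
        logger.info("%s: skipped %d non-SNV allele records", path, skipped)
    return calls


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path, names=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            name = f"\t{names[i]}" if names else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


# ------------------------------------------------- gene annotation

ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "gene", "family", "strand", "transcript",
    "n_exons", "exon_starts", "exon_sizes", "frames", "exon_seqs",
]


def write_gene_annotation(genes: list[GeneModel], path: str | Path) -> None:
    """12-column BED-like table; exon sequences are genome-forward strings."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            sizes = ",".join(str(len(e)) for e in g.exons)
            frames = ",".join(str(f) for f in g.frames)
            seqs = ",".join(g.exon_seqs)
            fh.write(
                f"{g.span.chrom}\t{g.span.start}\t{g.span.end}\t{g.gene_symbol}\t"
                f"{g.family_id or '.'}\t{g.strand}\t{g.transcript_id or '.'}\t"
                f"{len(g.exons)}\t{starts}\t{sizes}\t{frames}\t{seqs}\n"
            )


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            try:
                chrom, start, end = p[0], int(p[1]), int(p[2])
                starts = [int(x) for x in p[8].split(",") if x]
                sizes = [int(x) for x in p[9].split(",") if x]
                frames = [int(x) for x in p[10].split(",") if x]
                seqs = [x for x in p[11].split(",") if x]
                genes.append(
                    GeneModel(
                        gene_symbol=p[3],
                        family_id=None if p[4] == "." else p[4],
                        strand=p[5],
                        transcript_id="" if p[6] == "." else p[6],
                        span=GenomicInterval(chrom, start, end),
                        exons=[
                            GenomicInterval(chrom, s, s + sz)
                            for s, sz in zip(starts, sizes)
                        ],
                        frames=frames,
                        exon_seqs=seqs,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed annotation: {exc}") from exc
    return genes


# ------------------------------------------------- simple TSV tracks

def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Allele-count TSV: chrom, pos (1-based), count_A (FVB), count_B (partner)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "count_A", "count_B"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: allele-count table missing columns {sorted(missing)}")
    return df


def write_allele_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_family_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["gene"], df["family"]))


def read_expression_flags(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {g: bool(t) for g, t in zip(df["gene"], df["transcribed"])}


def read_polymorphism_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Known-polymorphism sites from a TSV (chrom, pos, ref, alt) or a VCF."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz"):
        out = set()
        for var in VCF(str(path)):
            for alt in var.ALT:
                if len(var.REF) == 1 and len(alt) == 1:
                    out.add((var.CHROM, var.POS, var.REF, alt))
        return out
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
    }


# ------------------------------------------------- fusion / SV dialects

RNA_FUSION_COLUMNS = [
    "sample", "gene1", "gene2", "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2", "split_reads", "gene_read_total",
]
SV_WGS_COLUMNS = ["Sample", "Chr1", "Pos1", "Chr2", "Pos2", "Type", "num_Reads"]


def read_fusion_rna(path: str | Path) -> list[SvCandidate]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for i, r in enumerate(df.itertuples(index=False), 2):
        try:
            total = getattr(r, "gene_read_total", None)
            total = None if pd.isna(total) else int(total)
            out.append(
                SvCandidate(
                    sample_id=r.sample,
                    source="rna",
                    breakpoint1=Breakpoint(r.chrom1, int(r.pos1), r.strand1),
                    breakpoint2=Breakpoint(r.chrom2, int(r.pos2), r.strand2),
                    sv_type="fusion" if r.chrom1 == r.chrom2 else "interchromosomal",
                    read_count=int(r.split_reads),
                    gene1=None if pd.isna(r.gene1) else r.gene1,
                    gene2=None if pd.isna(r.gene2) else r.gene2,
                    gene_read_total=total,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: malformed RNA fusion row: {exc}") from exc
    return out


def read_sv_wgs(path: str | Path) -> list[SvCandidate]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for i, r in enumerate(df.itertuples(index=False), 2):
        try:
            out.append(
                SvCandidate(
                    sample_id=r.Sample,
                    source="wgs",
                    breakpoint1=Breakpoint(r.Chr1, int(r.Pos1)),
                    breakpoint2=Breakpoint(r.Chr2, int(r.Pos2)),
                    sv_type=r.Type if r.Chr1 == r.Chr2 else "interchromosomal",
                    read_count=int(r.num_Reads),
                    gene1=getattr(r, "Gene1", None),
                    gene2=getattr(r, "Gene2", None),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: malformed SV row: {exc}") from exc
    return out


def write_fusion_rna(candidates: list[SvCandidate], path: str | Path) -> None:
    rows = []
    for c in candidates:
        rows.append(
            {
                "sample": c.sample_id,
                "gene1": c.gene1,
                "gene2": c.gene2,
                "chrom1": c.breakpoint1.chrom,
                "pos1": c.breakpoint1.pos,
                "strand1": c.breakpoint1.strand,
                "chrom2": c.breakpoint2.chrom,
                "pos2": c.breakpoint2.pos,
                "strand2": c.breakpoint2.strand,
                "split_reads": c.read_count,
                "gene_read_total": c.gene_read_total,
            }
        )
    pd.DataFrame(rows, columns=RNA_FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_sv_wgs(candidates: list[SvCandidate], path: str | Path) -> None:
    rows = []
    for c in candidates:
        rows.append(
            {
                "Sample": c.sample_id,
                "Chr1": c.breakpoint1.chrom,
                "Pos1": c.breakpoint1.pos,
                "Chr2": c.breakpoint2.chrom,
                "Pos2": c.breakpoint2.pos,
                "Type": c.sv_type,
                "num_Reads": c.read_count,
                "Gene1": c.gene1,
                "Gene2": c.gene2,
            }
        )
    pd.DataFrame(rows, columns=SV_WGS_COLUMNS + ["Gene1", "Gene2"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------- stamped outputs

def write_output_tsv(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """Write a result table with a provenance header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metdrive {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
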