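"""Allele-specific copy number from F1-hybrid allele counts.

F1 hybrids of FVB/NJ x partner-strain crosses are heterozygous at every
strain-informative SNP, so each SNP phases reads to a parental allele.
The B-allele frequency (BAF, fraction of reads supporting the partner
allele) deviates from 0.5 wherever one parental allele is lost or gained;
the read-depth ratio against the genome median separates loss from gain.

For a one-copy event in a tumor-cell fraction p (purity), the expected
BAF of the mixture is

    loss of B:  (1 - p) / (2 - p)
    gain of B:  (1 + p) / (2 + p)        (and symmetric for allele A)

Homozygous-background (FVB x FVB) samples carry no informative SNPs and
are refused rather than called at low confidence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, SampleRecord


@dataclass
class CnvSegment:
    sample_id: str
    interval: GenomicInterval
    state: str  # loss | neutral | gain
    affected_allele: str  # FVB | partner | undetermined
    mean_baf: float
    mean_depth_ratio: float
    n_snps: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.state == "neutral" and self.affected_allele != "undetermined":
            raise ValueError("neutral segments have no affected allele")


@dataclass
class RecurrentRegion:
    interval: GenomicInterval
    state: str
    overlap_length: int
    freq: int  # distinct animals
    supporters: list[str]  # sample ids, sorted


def expected_baf(purity: float, state: str) -> float:
    """Closed-form BAF of a tumor/normal mixture for a one-copy event.

    ``state`` is one of loss_of_B, neutral, gain_of_B; B is the partner
    allele.  A pure tumor (purity 1) with loss_of_B has BAF 0; an all
    normal sample has BAF 0.5 regardless of state.
    """
    if not (0.0 <= purity <= 1.0):
        raise ValueError(f"purity must be in [0,1], got {purity}")
    if state == "neutral":
        return 0.5
    if state == "loss_of_B":
        return (1.0 - purity) / (2.0 - purity)
    if state == "gain_of_B":
        return (1.0 + purity) / (2.0 + purity)
    if state == "loss_of_A":
        return 1.0 - expected_baf(purity, "loss_of_B")
    if state == "gain_of_A":
        return 1.0 - expected_baf(purity, "gain_of_B")
    raise ValueError(f"unknown state {state!r}")


def expected_depth_factor(purity: float, state: str) -> float:
    """Total-copy scaling of read depth for the same mixture."""
    if state == "neutral":
        return 1.0
    if state.startswith("loss"):
        return (2.0 - purity) / 2.0
    return (2.0 + purity) / 2.0


def bin_allele_counts(
    counts: pd.DataFrame,
    bin_size: int = 4000,
    min_snps: int = 3,
) -> pd.DataFrame:
    """Aggregate per-SNP allele counts into fixed genomic tiles.

    ``counts`` columns: chrom, pos (1-based), count_A (FVB), count_B
    (partner).  Bins are 0-based half-open tiles [k*bin, (k+1)*bin); a SNP
    at 1-based pos falls in bin (pos-1)//bin_size.  Bins with fewer than
    ``min_snps`` SNPs are flagged uninformative.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = counts.copy()
    df["bin_start"] = ((df["pos"] - 1) // bin_size) * bin_size
    grouped = (
        df.groupby(["chrom", "bin_start"], sort=True)
        .agg(
            n_snps=("pos", "size"),
            sum_A=("count_A", "sum"),
            sum_B=("count_B", "sum"),
        )
        .reset_index()
    )
    total = grouped["sum_A"] + grouped["sum_B"]
    grouped["baf"] = np.where(total > 0, grouped["sum_B"] / total.replace(0, 1), np.nan)
    grouped["depth"] = total / grouped["n_snps"]
    grouped["informative"] = grouped["n_snps"] >= min_snps
    grouped["bin_size"] = bin_size
    return grouped


def call_segments(
    bins: pd.DataFrame,
    purity: float,
    baf_delta_threshold: float = 0.1,
    min_consecutive_bins: int = 5,
    depth_ratio_tie: float = 0.05,
    bridge_uninformative: int = 2,
    sample_id: str = "",
) -> list[CnvSegment]:
    """Merge runs of BAF-shifted bins into allele-attributed segments.

    A run of >= min_consecutive_bins adjacent informative bins with
    |BAF - 0.5| > baf_delta_threshold, all shifted in the same direction,
    becomes one segment.  Up to ``bridge_uninformative`` consecutive
    uninformative (sparse) bins may be bridged inside a run: they carry
    no evidence in either direction.  BAF below 0.5 means the partner (B) allele is
    under-represented; combined with a depth ratio below 1 this is a loss
    of the partner allele, with a ratio above 1 a gain of the FVB allele
    (and symmetrically for BAF above 0.5).  When the depth ratio sits
    within ``depth_ratio_tie`` of 1 the loss interpretation is kept but
    the allele is reported undetermined and the segment flagged
    low-confidence.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    segments: list[CnvSegment] = []
    info = bins[bins["informative"]].copy()
    if info.empty:
        return segments
    median_depth = float(info["depth"].median())
    bin_size = int(bins["bin_size"].iloc[0])
    for chrom, chrom_bins in info.groupby("chrom", sort=True):
        chrom_bins = chrom_bins.sort_values("bin_start")
        run: list[pd.Series] = []
        run_sign = 0

        def flush(run: list[pd.Series], sign: int) -> None:
            if len(run) < min_consecutive_bins:
                return
            mean_baf = float(np.mean([b["baf"] for b in run]))
            depth_ratio = float(np.mean([b["depth"] for b in run])) / median_depth
            under = "partner" if sign < 0 else "FVB"
            over = "FVB" if sign < 0 else "partner"
            low_conf = False
            if depth_ratio < 1.0 - depth_ratio_tie:
                state, allele = "loss", under
            elif depth_ratio > 1.0 + depth_ratio_tie:
                state, allele = "gain", over
            else:
                state, allele, low_conf = "loss", "undetermined", True
            segments.append(
                CnvSegment(
                    sample_id=sample_id,
                    interval=GenomicInterval(
                        chrom,
                        int(run[0]["bin_start"]),
                        int(run[-1]["bin_start"]) + bin_size,
                    ),
                    state=state,
                    affected_allele=allele,
                    mean_baf=mean_baf,
                    mean_depth_ratio=depth_ratio,
                    n_snps=int(sum(b["n_snps"] for b in run)),
                    low_confidence=low_conf,
                )
            )

        prev_start = None
        for _, b in chrom_bins.iterrows():
            delta = b["baf"] - 0.5
            sign = 0
            if np.isfinite(delta) and abs(delta) > baf_delta_threshold:
                sign = 1 if delta > 0 else -1
            gap_bins = (
                (b["bin_start"] - prev_start) // bin_size - 1 if prev_start is not None else 0
            )
            if sign != 0 and sign == run_sign and run and gap_bins <= bridge_uninformative:
                run.append(b)
            else:
                flush(run, run_sign)
                run = [b] if sign != 0 else []
                run_sign = sign
            prev_start = b["bin_start"]
        flush(run, run_sign)
    return segments


def call_sample_segments(
    sample: SampleRecord,
    counts: pd.DataFrame,
    purity: float,
    bin_size: int = 4000,
    min_snps: int = 3,
    **kwargs,
) -> list[CnvSegment]:
    """Bin and segment one sample, refusing homozygous backgrounds.

    FVB x FVB samples carry no strain-informative heterozygous SNPs, so
    allele-specific calling is not attempted on them.
    """
    if sample.strain_cross != "F1":
        raise ValueError(
            f"sample {sample.sample_id} is on a homozygous background; "
            "allele-specific CNV calling requires an F1 hybrid"
        )
    bins = bin_allele_counts(counts, bin_size=bin_size, min_snps=min_snps)
    return call_segments(bins, purity, sample_id=sample.sample_id, **kwargs)


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def met_specific_segments(
    lm_segments: list[CnvSegment],
    pt_segments: list[CnvSegment],
    reciprocal_overlap: float = 0.5,
) -> list[CnvSegment]:
    """LM segments with no matching PT segment (same state and allele).

    A PT segment matches when state and affected allele agree and mutual
    overlap is at least ``reciprocal_overlap`` of both lengths; matched LM
    segments are shared truncal events and removed.
    """
    out = []
    for lm in lm_segments:
        if lm.state == "neutral":
            continue
        shared = any(
            pt.state == lm.state
            and pt.affected_allele == lm.affected_allele
            and _reciprocal_overlap(lm.interval, pt.interval) >= reciprocal_overlap
            for pt in pt_segments
        )
        if not shared:
            out.append(lm)
    return out


def recurrent_regions(
    met_segments: list[CnvSegment],
    sample_to_animal: dict[str, str],
    min_freq: int = 2,
) -> list[RecurrentRegion]:
    """Maximal intervals covered by same-state segments of >= min_freq animals.

    Loss and gain are analyzed separately.  An animal is counted once per
    region however many of its lesions contribute.  Sweep-line over segment
    endpoints: within each elementary interval the supporting animal set is
    constant; adjacent elementary intervals with identical supporter sets
    merge into one reported region.
    """
    out: list[RecurrentRegion] = []
    by_state_chrom: dict[tuple[str, str], list[CnvSegment]] = defaultdict(list)
    for seg in met_segments:
        if seg.state == "neutral":
            continue
        by_state_chrom[(seg.state, seg.interval.chrom)].append(seg)
    for (state, chrom) in sorted(by_state_chrom):
        segs = by_state_chrom[(state, chrom)]
        points = sorted({s.interval.start for s in segs} | {s.interval.end for s in segs})
        pieces: list[tuple[int, int, frozenset[str], set[str]]] = []
        for lo, hi in zip(points[:-1], points[1:]):
            covering = [s for s in segs if s.interval.start <= lo and s.interval.end >= hi]
            animals = frozenset(sample_to_animal[s.sample_id] for s in covering)
            samples = {s.sample_id for s in covering}
            if len(animals) >= min_freq:
                pieces.append((lo, hi, animals, samples))
        merged: list[list] = []
        for lo, hi, animals, samples in pieces:
            if merged and merged[-1][1] == lo and merged[-1][2] == animals:
                merged[-1][1] = hi
                merged[-1][3] |= samples
            else:
                merged.append([lo, hi, animals, set(samples)])
        for lo, hi, animals, samples in merged:
            out.append(
                RecurrentRegion(
                    interval=GenomicInterval(chrom, lo, hi),
                    state=state,
                    overlap_length=hi - lo,
                    freq=len(animals),
                    supporters=sorted(samples),
                )
            )
    return out


def region_gene_assignment(
    regions: list[RecurrentRegion],
    genes: list[GeneModel],
    flank: int = 0,
) -> list[tuple[RecurrentRegion, list[str]]]:
    """Genes whose span, extended by ``flank`` bp, intersects each region."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.span.chrom][max(0, g.span.start - flank) : g.span.end + flank] = g.gene_symbol
    out = []
    for region in regions:
        hits = trees[region.interval.chrom][region.interval.start : region.interval.end]
        out.append((region, sorted({h.data for h in hits})))
    return out
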