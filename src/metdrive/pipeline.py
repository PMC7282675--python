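"""Top-level pipeline: configuration and stage orchestration.

Stages run in method order — SNV screen, allele-specific CNV screen,
fusion/SV screen, clonality — each a pure function of its input files,
writing per-stage TSVs plus a cohort summary (TSV counts and a
machine-readable JSON).  All thresholds live in :class:`PipelineConfig`
with a provenance tag saying whether the value is stated by the source
study or is a repository default; the serialized config and its hash are
embedded in every output so reruns are attributable and, for fixed
inputs, byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .clonality import build_fingerprints, call_clonality, cluster
from .cnv import call_sample_segments, met_specific_segments, recurrent_regions
from .core import Cohort, load_sample_sheet
from .fusion import curate
from .snv import (
    CALLER_IDS,
    annotate_consensus,
    classify_recurrence,
    filter_calls,
    intersect_callers,
    met_enrichment_filter,
    mutual_exclusivity_report,
)

logger = logging.getLogger("metdrive")

PAPER_STATED = "paper_stated"
REPO_DEFAULT = "repo_default"


@dataclass
class PipelineConfig:
    """Every tunable threshold, with value provenance.

    provenance maps field name -> paper_stated | repo_default.
    """

    min_qual: float = 30.0
    vaf_low: float = 0.3
    vaf_high: float = 0.5
    pt_max_alt_reads: int = 1
    intersect_mode: str = "site"
    bin_size: int = 4000
    min_snps_per_bin: int = 3
    baf_delta_threshold: float = 0.1
    min_consecutive_bins: int = 5
    depth_ratio_tie: float = 0.05
    bridge_uninformative: int = 2
    reciprocal_overlap: float = 0.5
    min_region_freq: int = 2
    region_gene_flank: int = 0
    min_reads: int = 3
    min_partner_distance: int = 10_000
    gene_flank: int = 10_000
    match_tolerance: int = 100
    low_fraction_threshold: float = 0.01
    min_samples: int = 2
    linkage: str = "complete"
    weights: tuple[float, float] = (0.5, 0.5)
    provenance: dict = field(
        default_factory=lambda: {
            "min_qual": PAPER_STATED,
            "vaf_low": PAPER_STATED,
            "vaf_high": PAPER_STATED,
            "pt_max_alt_reads": REPO_DEFAULT,
            "intersect_mode": REPO_DEFAULT,
            "bin_size": PAPER_STATED,
            "min_snps_per_bin": REPO_DEFAULT,
            "baf_delta_threshold": REPO_DEFAULT,
            "min_consecutive_bins": REPO_DEFAULT,
            "depth_ratio_tie": REPO_DEFAULT,
            "bridge_uninformative": REPO_DEFAULT,
            "reciprocal_overlap": REPO_DEFAULT,
            "min_region_freq": PAPER_STATED,
            "region_gene_flank": REPO_DEFAULT,
            "min_reads": PAPER_STATED,
            "min_partner_distance": PAPER_STATED,
            "gene_flank": PAPER_STATED,
            "match_tolerance": REPO_DEFAULT,
            "low_fraction_threshold": PAPER_STATED,
            "min_samples": PAPER_STATED,
            "linkage": REPO_DEFAULT,
            "weights": REPO_DEFAULT,
        }
    )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "weights" in data:
            data["weights"] = tuple(data["weights"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = list(self.weights)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage} failed: {detail}")
        self.stage = stage


def _load_calls(run_dir: Path, cohort: Cohort) -> dict:
    calls = {}
    for r in cohort:
        for caller in CALLER_IDS:
            path = run_dir / "calls" / f"{r.sample_id}.{caller}.vcf"
            if not path.exists():
                raise StageError("snv-screen", f"missing call set {path} for sample {r.sample_id}")
            calls[(r.sample_id, caller)] = mio.read_vcf(path, caller_id=caller)
    return calls


def snv_screen_stage(run_dir: Path, cohort: Cohort, config: PipelineConfig):
    calls = _load_calls(run_dir, cohort)
    poly = mio.read_polymorphism_sites(run_dir / "polymorphisms.tsv")
    genes = mio.read_gene_annotation(run_dir / "genes.tsv")
    n_in = sum(len(v) for v in calls.values())
    filtered = {
        k: filter_calls(v, config.min_qual, poly) for k, v in sorted(calls.items())
    }
    n_filt = sum(len(v) for v in filtered.values())
    logger.info("snv-screen filter_calls: %d in, %d out, %d removed", n_in, n_filt, n_in - n_filt)
    lm_ids = {r.sample_id for r in cohort.by_tissue("LM")}
    lm_calls = [c for v in filtered.values() for c in v if c.sample_id in lm_ids]
    pt_calls_raw = [c for v in filtered.values() for c in v if c.sample_id not in lm_ids]
    consensus_lm = intersect_callers(lm_calls, mode=config.intersect_mode, genes=genes)
    consensus_pt = intersect_callers(pt_calls_raw, mode=config.intersect_mode, genes=genes)
    annotate_consensus(consensus_lm, genes)
    annotate_consensus(consensus_pt, genes)
    met, warnings = met_enrichment_filter(
        consensus_lm,
        pt_calls_raw,
        cohort,
        config.vaf_low,
        config.vaf_high,
        config.pt_max_alt_reads,
    )
    reports = classify_recurrence(met, cohort)
    recurrent = {
        r.gene
        for r in reports
        if r.recurrence_class in ("same_codon_recurrent", "diff_codon_recurrent")
    }
    me_table, any_cooc = mutual_exclusivity_report(met, recurrent)
    return {
        "consensus_lm": consensus_lm,
        "consensus_pt": consensus_pt,
        "met_enriched": met,
        "recurrence": reports,
        "recurrent_genes": sorted(recurrent),
        "mutual_exclusivity": me_table,
        "any_cooccurrence": any_cooc,
        "warnings": warnings,
    }


def cnv_screen_stage(run_dir: Path, cohort: Cohort, config: PipelineConfig, purity: dict):
    segments = {}
    for r in cohort:
        if r.strain_cross != "F1":
            logger.info("cnv-screen: skipping homozygous-background sample %s", r.sample_id)
            continue
        counts = mio.read_allele_counts(run_dir / "allele_counts" / f"{r.sample_id}.tsv")
        segments[r.sample_id] = call_sample_segments(
            r,
            counts,
            purity.get(r.sample_id, 1.0),
            bin_size=config.bin_size,
            min_snps=config.min_snps_per_bin,
            baf_delta_threshold=config.baf_delta_threshold,
            min_consecutive_bins=config.min_consecutive_bins,
            depth_ratio_tie=config.depth_ratio_tie,
            bridge_uninformative=config.bridge_uninformative,
        )
    met_specific = {}
    for r in cohort.by_tissue("LM"):
        if r.sample_id not in segments:
            continue
        pt_segs = [
            s
            for pt in cohort.pt_samples_of_animal(r.animal_id)
            for s in segments.get(pt.sample_id, [])
        ]
        met_specific[r.sample_id] = met_specific_segments(
            segments[r.sample_id], pt_segs, config.reciprocal_overlap
        )
    all_met = [s for segs in met_specific.values() for s in segs]
    regions = recurrent_regions(all_met, cohort.sample_to_animal, config.min_region_freq)
    return {"segments": segments, "met_specific": met_specific, "regions": regions}


def fusion_screen_stage(run_dir: Path, cohort: Cohort, config: PipelineConfig):
    genes = mio.read_gene_annotation(run_dir / "genes.tsv")
    repeats = mio.read_bed(run_dir / "repeats.bed")
    family_map = mio.read_family_map(run_dir / "family_map.tsv")
    rna = mio.read_fusion_rna(run_dir / "fusions" / "rna_candidates.tsv")
    wgs = mio.read_sv_wgs(run_dir / "fusions" / "wgs_candidates.tsv")
    lm_ids = {r.sample_id for r in cohort.by_tissue("LM")}
    reports = []
    # RNA and WGS candidates are curated separately, never merged
    for candidates in (rna, wgs):
        lm = [c for c in candidates if c.sample_id in lm_ids]
        pt = [c for c in candidates if c.sample_id not in lm_ids]
        reports.extend(
            curate(
                lm,
                pt,
                genes,
                repeats,
                family_map,
                cohort.sample_to_animal,
                config.min_reads,
                config.min_partner_distance,
                config.gene_flank,
                config.match_tolerance,
                config.low_fraction_threshold,
            )
        )
    return {"reports": reports, "survivors": [r for r in reports if r.passes_all]}


def clonality_stage(cohort: Cohort, snv_result: dict, cnv_result: dict, config: PipelineConfig):
    """Fingerprint metastasis-specific alterations across LM samples only."""
    lm_ids = [r.sample_id for r in cohort.by_tissue("LM")]
    segs = {s: cnv_result["met_specific"].get(s, []) for s in lm_ids}
    snvs = {s: [] for s in lm_ids}
    for m in snv_result["met_enriched"]:
        if m.sample_id in snvs:
            snvs[m.sample_id].append(m.site)
    matrix = build_fingerprints(segs, snvs, config.bin_size, config.min_samples)
    if len(matrix.samples) < 2:
        return {"matrix": matrix, "cluster": None, "calls": []}
    result = cluster(matrix, linkage=config.linkage, weights=config.weights)
    calls = call_clonality(result, cohort)
    return {"matrix": matrix, "cluster": result, "calls": calls}


def _met_snv_table(met) -> pd.DataFrame:
    rows = []
    for m in met:
        rows.append(
            {
                "Chr": m.site.chrom,
                "Position": m.site.pos,
                "type": "SNV",
                "alt.fraction": round(m.vaf_lm, 4),
                "sample_id": m.sample_id,
                "Transcript": "",
                "Gene": m.consensus.gene or "",
                "Codon": m.consensus.codon if m.consensus.codon is not None else "",
                "Nuc sub": f"{m.site.ref}>{m.site.alt}",
                "AA sub": m.consensus.aa_change or "",
                "cell_fraction": round(m.cell_fraction, 4),
                "pt_alt_reads": m.pt_alt_reads,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Chr", "Position", "type", "alt.fraction", "sample_id", "Transcript",
            "Gene", "Codon", "Nuc sub", "AA sub", "cell_fraction", "pt_alt_reads",
        ],
    )


def run_pipeline(
    run_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute all stages against a run directory; write reports + summary.

    ``run_dir`` follows the simulated-cohort layout (sample_sheet.tsv,
    calls/, allele_counts/, fusions/, side files).  Per-sample purity is
    read from truth.json when present, else assumed 1.
    """
    config = config or PipelineConfig()
    run_dir = Path(run_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = load_sample_sheet(run_dir / "sample_sheet.tsv")
    h = config.config_hash
    config.to_yaml(out / "pipeline_config.yaml")

    purity = {}
    truth_path = run_dir / "truth.json"
    if truth_path.exists():
        purity = json.loads(truth_path.read_text()).get("purity", {})

    if len(cohort) == 0:
        summary = {"n_samples": 0}
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
        return {"summary": summary}

    try:
        snv_result = snv_screen_stage(run_dir, cohort, config)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("snv-screen", str(exc)) from exc
    try:
        cnv_result = cnv_screen_stage(run_dir, cohort, config, purity)
    except Exception as exc:
        raise StageError("cnv-screen", str(exc)) from exc
    try:
        fusion_result = fusion_screen_stage(run_dir, cohort, config)
    except Exception as exc:
        raise StageError("fusion-screen", str(exc)) from exc
    try:
        clon_result = clonality_stage(cohort, snv_result, cnv_result, config)
    except Exception as exc:
        raise StageError("clonality", str(exc)) from exc

    mio.write_output_tsv(_met_snv_table(snv_result["met_enriched"]), out / "met_enriched_snvs.tsv", h)
    rec_rows = [
        {
            "gene": r.gene,
            "class": r.recurrence_class,
            "n_animals": len(r.animals),
            "events": ";".join(f"{e[0]}:{e[1]}:{e[3]}" for e in r.events),
        }
        for r in snv_result["recurrence"]
    ]
    mio.write_output_tsv(
        pd.DataFrame(rec_rows, columns=["gene", "class", "n_animals", "events"]),
        out / "snv_recurrence.tsv",
        h,
    )
    mio.write_output_tsv(snv_result["mutual_exclusivity"], out / "mutual_exclusivity.tsv", h)

    region_rows = [
        {
            "chr": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "state": r.state,
            "overlap.region": r.overlap_length,
            "freq": r.freq,
            "supporters": ";".join(r.supporters),
        }
        for r in cnv_result["regions"]
    ]
    mio.write_output_tsv(
        pd.DataFrame(
            region_rows,
            columns=["chr", "start", "end", "state", "overlap.region", "freq", "supporters"],
        ),
        out / "recurrent_regions.tsv",
        h,
    )
    seg_rows = [
        {
            "sample_id": s.sample_id,
            "chr": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "state": s.state,
            "allele": s.affected_allele,
            "mean_baf": round(s.mean_baf, 4),
            "depth_ratio": round(s.mean_depth_ratio, 4),
            "n_snps": s.n_snps,
            "met_specific": sid in cnv_result["met_specific"]
            and s in cnv_result["met_specific"][sid],
        }
        for sid, segs in sorted(cnv_result["segments"].items())
        for s in segs
    ]
    mio.write_output_tsv(
        pd.DataFrame(
            seg_rows,
            columns=[
                "sample_id", "chr", "start", "end", "state", "allele",
                "mean_baf", "depth_ratio", "n_snps", "met_specific",
            ],
        ),
        out / "cnv_segments.tsv",
        h,
    )

    fusion_rows = []
    for rep in fusion_result["reports"]:
        c = rep.candidate
        fusion_rows.append(
            {
                "uid": c.uid,
                "sample_id": c.sample_id,
                "source": c.source,
                "gene1": c.gene1,
                "gene2": c.gene2,
                "type": c.sv_type,
                "num_Reads": c.read_count,
                "met_specific": rep.met_specific,
                "repeat_class": rep.repeat_class,
                "family_class": rep.family_class,
                "recurrence": rep.recurrence,
                "read_fraction": "" if rep.read_fraction is None else round(rep.read_fraction, 5),
                "low_fraction": rep.low_fraction,
                "filters_failed": ";".join(k for k, v in rep.filters.items() if not v),
                "final": rep.passes_all,
            }
        )
    mio.write_output_tsv(
        pd.DataFrame(
            fusion_rows,
            columns=[
                "uid", "sample_id", "source", "gene1", "gene2", "type", "num_Reads",
                "met_specific", "repeat_class", "family_class", "recurrence",
                "read_fraction", "low_fraction", "filters_failed", "final",
            ],
        ),
        out / "fusion_audit.tsv",
        h,
    )
    link_rows = [
        {
            "chrom1": rep.candidate.breakpoint1.chrom,
            "pos1": rep.candidate.breakpoint1.pos,
            "chrom2": rep.candidate.breakpoint2.chrom,
            "pos2": rep.candidate.breakpoint2.pos,
            "class": rep.repeat_class,
        }
        for rep in fusion_result["survivors"]
    ]
    mio.write_output_tsv(
        pd.DataFrame(link_rows, columns=["chrom1", "pos1", "chrom2", "pos2", "class"]),
        out / "fusion_links.tsv",
        h,
    )

    clon_rows = [
        {"animal_id": c.animal_id, "verdict": c.verdict, "evidence": json.dumps(c.evidence, sort_keys=True)}
        for c in clon_result["calls"]
    ]
    mio.write_output_tsv(
        pd.DataFrame(clon_rows, columns=["animal_id", "verdict", "evidence"]),
        out / "clonality.tsv",
        h,
    )

    summary = {
        "config_hash": h,
        "n_samples": len(cohort),
        "n_animals": len(cohort.animals()),
        "consensus_snvs_pt": len(snv_result["consensus_pt"]),
        "consensus_snvs_lm": len(snv_result["consensus_lm"]),
        "met_enriched_snvs": len(snv_result["met_enriched"]),
        "recurrent_genes": snv_result["recurrent_genes"],
        "any_cooccurrence": snv_result["any_cooccurrence"],
        "recurrence_classes": {
            r.gene: r.recurrence_class for r in snv_result["recurrence"]
        },
        "recurrent_regions": len(cnv_result["regions"]),
        "fusion_candidates": len(fusion_result["reports"]),
        "fusion_survivors": len(fusion_result["survivors"]),
        "clonality": {c.animal_id: c.verdict for c in clon_result["calls"]},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return {
        "summary": summary,
        "snv": snv_result,
        "cnv": cnv_result,
        "fusion": fusion_result,
        "clonality": clon_result,
    }
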