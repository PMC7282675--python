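"""Genomic fingerprint clustering and mono/polyclonal seeding calls.

Each sample is encoded as a vector of 4000-bp copy-number bins coded
-1/0/+1 (loss/neutral/gain) plus per-site SNV presence coded 0/1;
features altered in fewer than two samples are dropped.  Samples are
clustered hierarchically (Jaccard distance on the SNV block, Manhattan on
the CNV block, equal-weight combination after scaling each block to
[0,1]; complete linkage).  An animal's metastases are called monoclonal
when they form a clade containing no other animal's samples, i.e. a
single founding subclone explains all of its lesions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .cnv import CnvSegment
from .core import Cohort, GenomicSite


@dataclass
class FingerprintMatrix:
    samples: list[str]
    features: list[tuple[str, str]]  # (kind: cnv_bin | snv_site, locus)
    values: np.ndarray  # samples x features
    bin_size: int = 4000

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("matrix shape does not match samples x features")
        for j, (kind, _) in enumerate(self.features):
            col = set(np.unique(self.values[:, j]).tolist())
            allowed = {-1, 0, 1} if kind == "cnv_bin" else {0, 1}
            if not col <= allowed:
                raise ValueError(f"feature {j} ({kind}) has codes outside {sorted(allowed)}")

    @property
    def cnv_block(self) -> np.ndarray:
        idx = [j for j, (k, _) in enumerate(self.features) if k == "cnv_bin"]
        return self.values[:, idx]

    @property
    def snv_block(self) -> np.ndarray:
        idx = [j for j, (k, _) in enumerate(self.features) if k == "snv_site"]
        return self.values[:, idx]


@dataclass
class ClonalityCall:
    animal_id: str
    verdict: str  # monoclonal_seeding | polyclonal_seeding | indeterminate
    evidence: dict = field(default_factory=dict)


@dataclass
class ClusterResult:
    samples: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    distances: np.ndarray  # condensed
    cophenetic: np.ndarray  # condensed
    n_features: int = -1


def bin_code(segments: list[CnvSegment], chrom: str, bin_start: int, bin_size: int) -> int:
    """Majority base-coverage code of one bin: -1 loss, +1 gain, 0 neutral/tie."""
    loss = gain = 0
    for seg in segments:
        if seg.interval.chrom != chrom:
            continue
        ov = max(0, min(seg.interval.end, bin_start + bin_size) - max(seg.interval.start, bin_start))
        if seg.state == "loss":
            loss += ov
        elif seg.state == "gain":
            gain += ov
    neutral = bin_size - min(bin_size, loss + gain)
    best = max(loss, gain, neutral)
    if best == neutral or (loss == gain and best == loss):
        return 0
    return -1 if loss > gain else 1


def build_fingerprints(
    segments_by_sample: dict[str, list[CnvSegment]],
    snvs_by_sample: dict[str, list[GenomicSite]],
    bin_size: int = 4000,
    min_samples: int = 2,
) -> FingerprintMatrix:
    """Build the per-sample CNV-bin / SNV-site feature matrix.

    CNV bins tile the union extent of all segments; a bin's code is the
    majority state by base coverage within the bin, ties coded 0.  A
    feature is retained only when non-reference in >= min_samples samples.
    """
    samples = sorted(set(segments_by_sample) | set(snvs_by_sample))
    extent: dict[str, int] = defaultdict(int)
    for segs in segments_by_sample.values():
        for seg in segs:
            extent[seg.interval.chrom] = max(extent[seg.interval.chrom], seg.interval.end)
    cnv_features: list[tuple[str, str]] = []
    cnv_cols: list[np.ndarray] = []
    for chrom in sorted(extent):
        for start in range(0, extent[chrom], bin_size):
            col = np.array(
                [
                    bin_code(segments_by_sample.get(s, []), chrom, start, bin_size)
                    for s in samples
                ]
            )
            if np.count_nonzero(col) >= min_samples:
                cnv_features.append(("cnv_bin", f"{chrom}:{start}-{start + bin_size}"))
                cnv_cols.append(col)
    site_keys = sorted(
        {s.key for sites in snvs_by_sample.values() for s in sites}
    )
    snv_features: list[tuple[str, str]] = []
    snv_cols: list[np.ndarray] = []
    present = {
        sid: {s.key for s in snvs_by_sample.get(sid, [])} for sid in samples
    }
    for key in site_keys:
        col = np.array([1 if key in present[s] else 0 for s in samples])
        if int(col.sum()) >= min_samples:
            snv_features.append(("snv_site", f"{key[0]}:{key[1]}{key[2]}>{key[3]}"))
            snv_cols.append(col)
    features = cnv_features + snv_features
    if features:
        values = np.column_stack(cnv_cols + snv_cols)
    else:
        values = np.zeros((len(samples), 0), dtype=int)
    return FingerprintMatrix(samples, features, values, bin_size)


def fingerprint_distances(matrix: FingerprintMatrix, weights=(0.5, 0.5)) -> np.ndarray:
    """Condensed pairwise distances: weighted Jaccard (SNV) + Manhattan (CNV).

    Each block is scaled to [0,1] (Manhattan by 2 x n_cnv_features) before
    the weighted sum; a block with no features contributes 0 and its
    weight is redistributed to the other block.
    """
    n = len(matrix.samples)
    cnv = matrix.cnv_block.astype(float)
    snv = matrix.snv_block.astype(float)
    w_cnv, w_snv = weights
    if cnv.shape[1] == 0:
        w_cnv, w_snv = 0.0, 1.0 if snv.shape[1] else 0.0
    elif snv.shape[1] == 0:
        w_cnv, w_snv = 1.0, 0.0
    total = (w_cnv + w_snv) or 1.0
    w_cnv, w_snv = w_cnv / total, w_snv / total
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            if w_cnv:
                d += w_cnv * np.abs(cnv[i] - cnv[j]).sum() / (2.0 * cnv.shape[1])
            if w_snv:
                union = np.logical_or(snv[i], snv[j]).sum()
                if union:
                    inter = np.logical_and(snv[i], snv[j]).sum()
                    d += w_snv * (1.0 - inter / union)
            out[k] = d
            k += 1
    return out


def cluster(
    matrix: FingerprintMatrix,
    linkage: str = "complete",
    weights=(0.5, 0.5),
) -> ClusterResult:
    """Agglomerative clustering of the fingerprint matrix.

    Deterministic for fixed input: distances are computed in sample-sheet
    order and ties resolve by that order.  Cophenetic distances exposed.
    """
    if len(matrix.samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    d = fingerprint_distances(matrix, weights)
    Z = sch.linkage(d, method=linkage)
    coph = sch.cophenet(Z)
    return ClusterResult(list(matrix.samples), Z, d, coph, len(matrix.features))


def _leaf_sets(Z: np.ndarray, n: int) -> list[set[int]]:
    """Leaf sets of every node (leaves then internal merges, scipy order)."""
    sets: list[set[int]] = [{i} for i in range(n)]
    for a, b, _, _ in Z:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets


def call_clonality(result: ClusterResult, cohort: Cohort) -> list[ClonalityCall]:
    """Mono/polyclonal seeding verdict per animal with >= 2 clustered LMs.

    Monoclonal when the smallest clade containing all of the animal's LM
    samples contains no other animal's samples (the animal's own PT may
    join the clade).  Animals with fewer than 2 LM samples in the matrix
    are indeterminate.
    """
    idx = {s: i for i, s in enumerate(result.samples)}
    s2a = cohort.sample_to_animal
    n = len(result.samples)
    node_sets = _leaf_sets(result.linkage, n)
    calls = []
    for animal in cohort.animals():
        lm = [
            r.sample_id
            for r in cohort
            if r.animal_id == animal and r.tissue == "LM" and r.sample_id in idx
        ]
        if len(lm) < 2 or result.n_features == 0:
            calls.append(
                ClonalityCall(
                    animal,
                    "indeterminate",
                    {"n_lm": len(lm), "n_features": result.n_features},
                )
            )
            continue
        target = {idx[s] for s in lm}
        # smallest node containing all the animal's LMs
        containing = [s for s in node_sets if target <= s]
        clade = min(containing, key=len)
        foreign = sorted(
            result.samples[i] for i in clade if s2a[result.samples[i]] != animal
        )
        verdict = "monoclonal_seeding" if not foreign else "polyclonal_seeding"
        calls.append(
            ClonalityCall(
                animal,
                verdict,
                {
                    "n_lm": len(lm),
                    "clade_size": len(clade),
                    "foreign_samples": foreign,
                },
            )
        )
    return calls
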