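# Methods

## The screens

### Consensus SNV screen

Calls from three callers per sample are filtered at Phred quality ≥ 30 and
against a known-polymorphism site list, then intersected. The default
intersection granularity is the site — a (sample, chrom, pos, ref, alt)
record must be present in all three call sets — which is stricter than
gene-level intersection; gene mode is retained (`intersect_mode: gene`)
and flags sites that are not themselves tri-supported. Pooled counts for
a consensus record come from the supporting caller with the highest depth
at the site (ties resolved by fixed caller-label order).

The metastasis-enrichment filter encodes two driver criteria:

1. **Absent from the primary tumor.** PT evidence for a site is the
   maximum alt-read count observed across the matched animal's PT samples
   and callers (animals with several pooled primaries contribute the union
   of their evidence); the default ceiling is 1 alt read. A read-level
   threshold rather than caller absence was chosen because a site can be
   absent from a caller's output while still having supporting reads.
2. **Present in the metastatic seeding cell.** For a heterozygous variant
   at a diploid locus, each carrying cell contributes one alt and one ref
   allele, so the carrier ("cell") fraction is `min(1, 2·VAF)`. The closed
   VAF window [0.3, 0.5] therefore keeps variants carried by at least 60 %
   of the lesion while allowing for stromal infiltration. The window is
   applied to raw VAF, not purity-corrected VAF. Both bounds are
   inclusive: 0.3 maps exactly to the 60 % carrier floor.

Recurrence is counted per animal, never per lesion: two metastases of one
animal sharing a codon are one independent observation. Genes partition
into same-codon recurrent (≥ 2 animals share a codon, regardless of the
substituted amino acid), different-codon recurrent (≥ 2 animals, distinct
codons) and singletons; unannotated sites go to an explicit
`non-coding/unassigned` bucket rather than being dropped. Codon indices
are always reported against one canonical transcript per gene, named in
the annotation table. Cross-platform validation marks an event
`validated` when the same site is called in the same sample on the other
platform, `not_transcribed` (unevaluable) when the gene is below the
expression flag, `absent` otherwise, and `no_data` when the sample lacks
a call set on that platform.

### Allele-specific CNV

For a one-copy event in a tumor-cell fraction *p* (purity), the expected
B-allele frequency of the tumor/normal mixture is

    loss of B:  (1 − p) / (2 − p)        gain of B:  (1 + p) / (2 + p)

with B the partner-strain allele, and the total-depth factor is
`(2 ∓ p)/2`. Segmentation is deliberately simple — threshold plus
run-merging over 4000-bp bins — rather than a reimplementation of a
model-based caller: the screen's conclusions rest on segment presence and
direction, not breakpoint precision. Defaults: BAF deviation threshold
0.1, minimum 5 consecutive shifted bins, minimum 3 informative SNPs per
bin, and up to 2 consecutive sparse (uninformative) bins bridged inside a
run, since such bins carry no evidence in either direction. The depth
ratio against the genome-median bin depth resolves loss (ratio < 0.95)
from gain (ratio > 1.05); inside the tie band the loss interpretation of
the BAF shift is kept but the affected allele is reported `undetermined`
and the segment flagged low-confidence — the allele is never guessed.
Homozygous-background (FVB × FVB) samples are refused: they carry no
strain-informative heterozygous SNPs, so allele-specific calling is not
meaningful there.

Metastasis-specific segments are LM segments with no PT segment of the
same state and allele at ≥ 0.5 reciprocal overlap (the subtraction rule
is a repository default; 0.5 reciprocal overlap is the common interval-
matching convention). Recurrent regions are maximal intervals covered by
same-state metastasis-specific segments from ≥ 2 distinct animals,
computed by a sweep-line over segment endpoints; adjacent elementary
intervals with the same supporting-animal set merge. Gene assignment is
plain interval intersection with an optional flank; no enrichment
statistic is computed.

### Fusion / SV curation

RNA and WGS candidates normalize into one schema (breakpoints stored in
canonical order) but are curated separately and never merged into joint
evidence; cross-source concordance is an observation, not a requirement.
Hard filters: read-through (RNA candidates joining adjacent same-strand
genes with no intervening gene and breakpoints inside both spans),
≥ 3 supporting reads, ≥ 10 kb between intrachromosomal partners
(interchromosomal events always pass), each breakpoint within 10 kb of an
annotated gene, and same-family partner exclusion. All distance
thresholds are closed (exactly 10 kb passes). Repeat classification
(both / one / neither breakpoint inside a repeat interval) is a flag, not
an exclusion, mechanizing what is otherwise manual curation as a
deterministic point-in-interval lookup. Family assignment uses an
explicit gene→family map; a fallback that strips trailing digits from
symbols exists but is off by default and labelled heuristic. Recurrence
is `multi_animal` (same unordered gene pair in ≥ 2 animals) or
`multi_partner` (a gene with ≥ 2 distinct partners); RNA candidates with
read fraction < 1 % of the partner-gene total are flagged low-fraction.
Every input candidate appears in the audit report exactly once with its
full filter vector.

### Clonality

Fingerprints are built from metastasis-specific alterations of the LM
samples: 4000-bp CNV bins coded −1/0/+1 by majority base coverage within
the bin (ties → 0) and SNV sites coded 0/1, keeping features altered in
≥ 2 samples. Distances combine Jaccard on the SNV block and Manhattan on
the CNV block (scaled by twice the CNV feature count), equal weights,
with a block's weight redistributed when it has no features; linkage is
complete (conservative clade compactness), computed with scipy and
checked in tests against a naive O(n³) agglomeration. An animal with ≥ 2
clustered metastases is `monoclonal_seeding` when the smallest clade
containing all of them contains no other animal's samples, otherwise
`polyclonal_seeding`; animals with fewer metastases or an empty feature
matrix are `indeterminate`. Principal-component analysis is not
implemented: no downstream result depends on it.

## The synthetic cohort generator

The generator emulates the call-level data the screens consume; it does
not simulate reads. Study conditions (defaults):

| parameter | default | rationale |
|---|---|---|
| animals × lesions | 6 × (1 PT + 4 LM) | enough animals for every recurrence class; ≥ 2 lesions per subclone so subclone features survive the ≥ 2-sample fingerprint filter |
| partner strains | C57BL/6J, C57BL/10J, CAST/EiJ, MOLF/EiJ | the four outcross partners |
| mean depth | 40× | published average exome coverage |
| purity | U(0.6, 0.95) | not reported for any sample; a realistic resection-purity window whose truncal heterozygous VAF (p/2) realizes the 0.3–0.5 driver window exactly |
| driver VAF | 0.3–0.5 | truncal heterozygous in the lesion (carrier fraction 1), VAF = purity/2 |
| informative SNPs | 2.5 / kb | highly polymorphic crosses (CAST, MOLF vs FVB); ≈ 10 SNPs per 4000-bp bin keeps bins informative |
| segments | 60–160 kb | tens of bins, comfortably above the 5-bin floor |
| caller FP/FN | 0.02 | per-caller miss probability per variant; FPs drawn per caller from a 200-site decoy pool, so the 3-caller intersection removes them with high probability |
| fusion mix | ¼ each | read-through, repeat-breakpoint, gene-family, true event |
| polyclonal animals | 40 % | the clonality sub-study's 2-of-5 split |

Depth per site is Poisson(mean depth) (shot noise around the average
coverage); alt counts are Binomial(depth, VAF); allele counts at
informative SNPs are Binomial with the mixture BAF and a Poisson depth
scaled by the copy-number factor. `count_model="expected"` replaces both
draws by their rounded expectations — the generator's deterministic
limit. Noise-free end-to-end recovery tests use this mode: with finite
depth even a zero-error caller produces sampling jitter that moves a
boundary VAF across the 0.3 threshold, so "exact recovery" is only
defined in the expectation limit.

Planted structure: drivers recur by design (one gene mutated in the same
codon in two animals; one in the same codon with different substitutions;
one in different codons); each subclone carries 12 private clonal marker
SNVs (met-specific, VAF in the driver window) and private loss segments;
truncal SNVs/segments are shared with the PT and must be subtracted;
germline polymorphisms appear in every sample and in the polymorphism
list; subclonal passengers sit below the VAF window. Two cohort-level
recurrent loss regions are each carried by two monoclonal animals, and
each polyclonal animal carries one region per subclone — so its lesions
genuinely split across cohort clades, which is what makes polyclonal
seeding detectable by clade purity. Losses remove the partner allele
except in MOLF/EiJ crosses, which lose FVB and may also gain (the
direction pattern seen in these crosses). The gene layout interleaves
paralog-family members and separates fusion partners so that each
artifact class is decidable by construction: read-through pairs are the
only adjacent same-strand pairs used, repeat-class breakpoints fall in
intronic repeat intervals, and true-event partners are distant,
single-copy and family-free.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: alignment and mapping artifacts,
caller-specific error models and their correlation (false positives here
are independent across callers by design), indels and multi-nucleotide
events, GC/mappability depth waves, subclonal copy-number mixtures,
whole-arm events, and contamination of the primary tumor by the
metastatic clone (default 0).

## Numerical and testing choices

All randomness flows from a single seed; analysis stages are seed-free
and byte-deterministic (fixed float formatting, sorted iteration), so a
rerun with the same config and inputs is bit-identical — outputs embed a
hash of the serialized configuration. Oracle-equivalence suites run 100
random instances per operation at small sizes (≤ 50 coordinate units for
interval sweeps, 5–7 samples for clustering); the clustering oracle skips
matrices with tied pairwise distances, where the merge order is a
convention, not a property. The clonality verdict property uses 100
seeded replicate cohorts (5 animals each) with subclone fingerprints
separated by ≥ 10 features and requires ≥ 95 % verdict agreement with the
plant. BAF-convergence checks compare per-SNP error to the binomial
prediction at three purities × three depths.

## Known limitations

- Segmentation has no explicit breakpoint model; boundaries are accurate
  to ± 1 bin at the default densities and depths, which suffices for
  recurrence intersection but not for base-pair breakpoint work.
- Loss/gain disambiguation needs a usable depth ratio; on depth-flat data
  every call degrades to the BAF-only loss interpretation with an
  undetermined allele.
- The mutual-exclusivity report is descriptive (a co-occurrence flag),
  not a statistical test of exclusivity.
- The clonality call is cladistic and depends on the cohort context:
  an animal whose lesions are distinct from each other but even more
  distinct from every other animal's will still form a clade and be
  called monoclonal.
- Gene annotation carries embedded exon sequences; there is no FASTA or
  liftover support, and only single-nucleotide substitutions are modeled.
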