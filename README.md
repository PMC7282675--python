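# metdrive

Metastasis-driver discovery from matched primary-tumor (PT) / lung-metastasis
(LM) pairs in F1-hybrid mouse mammary tumor models (MMTV-PyMT / MMTV-Her2
crosses). The package implements the downstream screens that sit on top of
standard variant callers:

- **Consensus SNV screen** — per-sample call sets from three callers
  (mpileup / Mutect2 / Strelka dialects) are quality-filtered (Phred ≥ 30),
  cleared of known polymorphisms, intersected across callers, and reduced to
  candidate metastasis drivers by two criteria: the variant is absent from
  the matched primary tumor (≤ 1 alt read across the animal's PTs) and it
  is present in the metastatic seeding cell. For a heterozygous variant at
  a diploid locus the carrier fraction is `min(1, 2·VAF)`, so the VAF window
  [0.3, 0.5] keeps variants carried by ≥ 60 % of the lesion. Survivors are
  classified by cross-animal recurrence (same codon / different codon /
  singleton) and checked for mutual exclusivity of recurrent genes.
- **Allele-specific CNV screen** — in an F1 hybrid every strain-informative
  heterozygous SNP phases reads to a parental allele. With tumor purity *p*,
  a one-copy loss of allele B shifts the B-allele frequency to
  `BAF = (1 − p)/(2 − p)` (gain: `(1 + p)/(2 + p)`). Allele counts are
  binned into 4000-bp tiles, runs of shifted bins become segments, the
  depth ratio resolves loss vs gain, PT-shared segments are subtracted, and
  metastasis-specific segments from ≥ 2 animals are intersected into
  recurrent regions (reported with overlap length and animal frequency).
- **Fusion/SV curation** — RNA-fusion (deFuse-style) and WGS-SV
  (BreakDancer-style) candidate tables pass a filter battery: metastasis
  specificity, read-through exclusion (adjacent same-strand genes),
  ≥ 3 supporting reads, ≥ 10 kb between intrachromosomal partners,
  breakpoints within 10 kb of a gene, repeat-breakpoint classification,
  and gene-family (paralog) exclusion, with a full per-candidate audit
  trail and recurrence/read-fraction reporting.
- **Clonality fingerprints** — per-lesion matrices of 4000-bp CNV bins
  coded −1/0/+1 plus SNV presence coded 0/1 (features altered in ≥ 2
  samples), clustered hierarchically (Jaccard on the SNV block, Manhattan
  on the CNV block, complete linkage). An animal's metastases are called
  monoclonal when they form a clade containing no other animal's samples.
- **Synthetic cohorts** — a generator that plants driver SNVs, parental
  allele-specific segments, fusion artifacts of three classes and subclone
  structure, emits caller-style VCFs, allele-count tracks and candidate
  tables, and serializes the ground truth for end-to-end validation.

## Worked example

```bash
metdrive simulate --seed 1 --out demo
metdrive run --samples demo --out demo_out
```

prints the cohort summary:

```json
{
 "any_cooccurrence": false,
 "clonality": {
  "A001": "monoclonal_seeding",
  "A002": "monoclonal_seeding",
  "A003": "monoclonal_seeding",
  "A004": "monoclonal_seeding",
  "A005": "polyclonal_seeding",
  "A006": "polyclonal_seeding"
 },
 "config_hash": "0e142b57b154",
 "consensus_snvs_lm": 310,
 "consensus_snvs_pt": 19,
 "fusion_candidates": 192,
 "fusion_survivors": 51,
 "met_enriched_snvs": 169,
 "n_animals": 6,
 "n_samples": 30,
 "recurrence_classes": {
  "drvA": "same_codon_recurrent",
  "drvB": "same_codon_recurrent",
  "drvC": "diff_codon_recurrent",
  "non-coding/unassigned": "singleton"
 },
 "recurrent_genes": ["drvA", "drvB", "drvC"],
 "recurrent_regions": 2
}
```

Reading: 310 LM consensus SNVs survive the three-caller intersection, 169
pass both driver criteria (PT absence + seeding-cell VAF). The planted
recurrent genes are recovered in their classes — `drvA` mutated in the
same codon in two animals, `drvB` in the same codon with different
substitutions, `drvC` in different codons — and no lesion carries two
recurrent genes at once (`any_cooccurrence: false`). Both planted
recurrent loss regions are found, and the two animals whose metastases
were seeded by two different primary-tumor subclones are called
polyclonal. `demo_out/` also holds the per-stage TSVs (met-enriched SNV
table, segment and recurrent-region tables, fusion audit and link tables,
clonality calls), each stamped with the config hash.

Stage-level entry points (`metdrive snv-screen|cnv-screen|fusion-screen|clonality`)
report the corresponding slice of the summary; the library functions in
`metdrive.snv`, `metdrive.cnv`, `metdrive.fusion` and `metdrive.clonality`
expose every operation individually.

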