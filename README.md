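# nutrimir

A two-condition small RNA-seq analysis pipeline for plants, built around the
kind of experiment that compares *Arabidopsis* seedlings under nutrient-replete
and nutrient-starved conditions: which microRNAs respond, which novel miRNAs
hide in the unannotated read space, and which transcripts do they slice?

The package takes two adapter-ligated small-RNA libraries and a reference
(genome, structural-RNA annotation, mature-miRNA set, transcriptome, degradome
tags) through:

1. **preprocess** — 3' adapter trimming (full match anywhere, or a ≥8-nt
   adapter prefix flush with the read end), length filtering, and collapsing
   into unique tags with per-library counts;
2. **mapper** — perfect-match placement of every tag on both genome strands
   (0 mismatches; multi-mapping tags counted once per tag);
3. **annotate** — rRNA/tRNA/snRNA/snoRNA classification by strand-aware
   interval overlap with precedence rRNA > tRNA > snRNA > snoRNA, plus
   composition and between-library overlap summaries;
4. **quant** — member-resolved quantification of known miRNAs (full-length
   identity; sequence-identical members merged, `miR169d-g` style), RPM
   normalization, log2 fold change of condition B over A
   (`log2(count_B/count_A)`, +1 to both counts when either is zero), and
   response classes: suppressed (NSS) if the ratio falls more than
   threshold-fold, induced (NSI) if it rises more than threshold-fold
   (default 3 for known, 2 for novel miRNAs);
5. **discover** — novel-miRNA candidates from unannotated tag clusters:
   precursor windows are excised, folded by weighted base-pair maximization
   (G:C=3, A:U=2, G:U=1, min loop 3), and kept only when the mature sits in
   one arm of a coherent stem-loop with ≤4 unpaired bases and no bulge run
   longer than 2; the miRNA* implied by 2-nt 3' overhangs is searched in the
   data and reported;
6. **targets** — ungapped antiparallel complementarity scan (mismatch 1,
   G:U wobble 0.5, threshold 3.0) over the transcriptome, with degradome
   5'-end tags graded at the position opposite miRNA nucleotide 10
   (categories 0–4, CleaveLand-style);
7. **synthio** — a fully seeded synthetic-data generator (genome with planted
   hairpins, structural and decoy loci, NB-distributed two-condition reads,
   degradome peaks) so the whole pipeline is testable without external data.

## Worked example

```bash
nutrimir simulate --out sim --seed 2 --depth 50000
nutrimir run --config config.yaml --out out
```

with `config.yaml`:

```yaml
genome: sim/genome.fa
annotations: sim/annotations.gff3
reads_a: sim/reads_A.fastq
reads_b: sim/reads_B.fastq
mature: sim/mature_known.fa
transcriptome: sim/transcripts.fa
degradome: sim/degradome.tsv
```

`out/novel_candidates.tsv` then contains one row per discovered hairpin
(columns abbreviated here):

```
id      sequence                  length  count_A  count_B  star_supported  log2fc  response
mirN02  CGGTGTCGAAGTAGAAACAGA     21      186      1200     False           2.7     NSI
mirN03  TGTCGTCGTAGGATAGCGCAT     21      214      1100     True            2.4     NSI
mirN05  AGCCTATTCTCGGCGAAACAG     21      259      239      True            -0.1    unchanged
```

Reading the `mirN03` row: a 21-nt tag seen 214 times in condition A but 1100
times in condition B (log2(1100/214) = 2.4, beyond the 2-fold novel
threshold, hence starvation-induced if A is the replete and B the starved
library), whose precursor passed all hairpin criteria and whose star sequence
was itself found in the reads — the strongest class of novel-miRNA evidence.
`out/target_report.tsv` lists complementary sites for each candidate with the
degradome category at the predicted cleavage position:

```
mirna   transcript  start1  end1  penalty  cleavage_pos  evidence_count  category
mirN03  AT04G130    233     253   0.0      244           30              0
```

a perfectly complementary site at transcript positions 233–253 with a 30-read
degradome pile-up at position 244 (= 233 + 21 − 10, opposite miRNA nucleotide
10) that is the unique maximum on that transcript — category 0, the strongest
cleavage evidence. `out/class_summary.tsv` and `out/overlap_summary.tsv`
reproduce the usual library-composition and common/specific-tag tables.

Every stage is also available standalone (`nutrimir preprocess`, `map`,
`classify`, `quant`, `discover`, `targets`) on the previous stage's TSVs, and
as plain library functions.

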