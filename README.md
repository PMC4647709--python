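# misasm

Mis-assembly detection for draft genome assemblies that combines a
reference genome with paired-end read evidence — and, crucially, tells
**assembly errors** apart from **correct assemblies that merely differ
from the reference through structural variation (SV)**.

Purely reference-based evaluators call every scaffold/reference
difference an error, so genuine SVs between the sequenced organism and
the reference become false positives. Purely read-based evaluators
score coverage and insert-size consistency but produce many false calls
on uneven real data. `misasm` does both: the reference *locates*
candidate differences, and the reads *validate* them.

## Who this is for

Anyone evaluating or polishing a draft assembly (bacterial to
small-eukaryote scale) who has (a) the scaffolds, (b) a reference or
close-strain genome, and (c) the paired-end reads the assembly was
built from.

## Method

1. **Locate differences.** Scaffold-to-reference alignments (BLAST
   outfmt 6, PAF, or the built-in k-mer aligner for synthetic data) are
   reduced to one non-redundant chain of segments per scaffold: start
   from the best-scoring segment and extend greedily in both directions,
   preferring the candidate with the smallest scaffold overlap/gap
   (≤ 1 kbp by default). Junctions between chained segments are
   classified by the scaffold gap `g_s` and oriented reference gap
   `g_r`:
   - different reference, different strand, or |`g_r`| > 10 kbp → **misjoin**;
   - `g_s − g_r` > 5 bp → **insertion** of that size; `g_r − g_s` > 5 bp → **deletion**;
   - unaligned scaffold ends / whole scaffolds → **insertion**.

2. **Compute breakpoint regions.** Each difference gets a scaffold
   interval [M_L, M_R): the overlap of the flanking segments for a
   misjoin (trimmed outward past pileup-mismatched tails), the inner
   segment endpoints for indels, the unaligned end for end insertions.

3. **Validate with read evidence.** Per region the pipeline computes:
   disagreements (pileup majority fraction < 0.8 at depth ≥ 5),
   high/low/zero coverage (50-bp windows vs 1.5×/0.5× of the scaffold
   mean; single-cell mode uses mean ± 1.5 sd of window coverages),
   multi-align ratio, discordant ratio (pairs that are not inward-FR or
   whose fragment deviates from the insert mean μ by > 3σ; max over
   500-bp sub-regions), and the mean fragment size of pairs spanning
   the region. Decision rules:
   - **misjoin**: abnormal coverage or > 1 disagreement, *or*
     multi-align ratio > 0.1;
   - **insertion**: |(span fragment − μ) − inserted size| < 2σ *and* at
     least two of {disagreements, low coverage, discordant ratio > 0.1};
     fallback for un-bridgeable insertions: > 1 disagreement per kbp;
     scaffold-end insertions: any disagreement or zero-coverage base;
   - **deletion**: mirror image with |(μ − span fragment) − deleted size| < 2σ;
   - anything unvalidated with even coverage, no disagreements and
     discordant ratio < 0.1 → **correct assembly (SV)**; otherwise a
     **warning**. Differences over N-gap runs are reported as gaps,
     never errors.

4. **Correct and report.** Validated misjoins split their scaffold at
   [M_L, M_R) (the mis-collapsed repeat is removed from both pieces);
   erroneous ends are trimmed; N50 and per-type counts are reported
   before/after, with precision = TP/(TP+FP) and TPR = TP/(TP+FN)
   against a truth table when one exists.

The package also ships a first-class synthetic-scenario generator
(genome, mis-assembled scaffolds, SV-mutated reference, Gaussian-insert
paired reads, truth tables) plus naive long-sequence and short-read
aligners, so the entire pipeline runs hermetically at desk scale.

## Worked example

```bash
python examples/detect_and_correct.py
```

prints (seed 7, 200-kbp genome, four injected errors):

```
scaffold    kind            region          verdict           correction
scf_mis0    misjoin         [19499,20000)   ERROR_MISJOIN     SPLIT[19499,20000)
scf_w1      insertion_mid   [14285,14585)   ERROR_INSERTION   REPORT_ONLY
scf_w2      insertion_end   [28571,28771)   ERROR_INSERTION   TRIM_END(right@28571)
scf_w3      deletion        [14125,14285)   ERROR_DELETION    REPORT_ONLY

errors vs truth: TP=4 FP=0 FN=0 precision=1.00 TPR=1.00
scaffolds 7 -> 8 (the misjoin was split), N50 28571 -> 28571 bp
```

All four injected errors are validated by their read evidence: the
misjoin by the multi-aligned reads over its 500-bp repeat junction
(region [19499,20000)), the insertions by zero/low coverage plus
oversized spanning fragments, the collapsed-repeat deletion by doubled
coverage and pileup disagreements. The misjoin split adds one scaffold
and barely moves N50. `examples/sv_versus_error.py` shows the converse:
eight differences caused by SVs in the reference are all classified
`CORRECT_SV` and nothing is broken.

Command-line equivalents:

```bash
misasm simulate --genome-len 1000000 --seed 1 --out scenario/
misasm run --assembly scenario/scaffolds.fasta --reference scenario/reference.fasta \
    --alignments scenario/alignments.blast6.tsv --reads1 scenario/reads_1.fastq \
    --reads2 scenario/reads_2.fastq --insert-mean 368 --insert-sd 61 \
    --truth scenario/truth.tsv --out results/
```

`misasm run` writes a per-difference TSV report, the corrected FASTA, a
summary table and five bedGraph tracks (coverage, disagreements,
zero-coverage, multi-align ratio and discordant ratio per 500 bp).

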