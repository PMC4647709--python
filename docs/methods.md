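# Methods

This note records the model behind `misasm`, the parameters that
matter, what the synthetic scenarios do and do not emulate, and the
design choices made where the design was genuinely open.

## Model and assumptions

The pipeline treats mis-assembly detection as a two-stage decision
problem. Stage one is purely comparative: scaffold-to-reference
alignment breaks locate *candidate* differences (misjoins, insertions,
deletions, unaligned ends). Stage two is evidential: paired-end reads
aligned to the scaffolds either confirm a candidate as an assembly
error or show that the scaffold is locally well-supported, in which
case the difference is attributed to structural variation between the
sequenced genome and the reference. The key assumptions are:

- the reference is close enough that well-assembled scaffold regions
  align contiguously (precision degrades with reference divergence, as
  poorly aligned regions attract spurious candidates);
- the library insert-size distribution is unimodal and summarized
  adequately by a mean μ and standard deviation σ (Gaussian-like); all
  fragment tests are expressed in units of σ;
- reads are plentiful enough (tens-fold coverage) that per-region
  features — disagreement counts, 50-bp window coverages, discordant
  ratios — are informative. Regions with almost no reads are reported
  as warnings, never as correct assemblies: absence of reads is not
  evidence of correctness.

## Parameters

| key | default | meaning |
|---|---|---|
| `max_adjacency` | 1000 bp | max overlap/gap between chained segments |
| `misjoin_distance` | 10 kbp | reference jumps beyond this are misjoins ("more than several kbp") |
| `indel_min` | 5 bp | smaller gap discrepancies are alignment jitter |
| `end_min` | 10 bp | shorter unaligned ends ignored |
| `gap_run_min` | 10 | N-run length that marks an intra-scaffold gap |
| `majority_frac` | 0.8 | disagreement: majority fraction strictly below |
| `min_depth` | 5 | depth floor for disagreement calls |
| `window_cov` / `window_disc` | 50 / 500 bp | coverage and ratio windows |
| `anomaly_windows` | 2 | windows needed to flag high/low coverage |
| `cov_high_fold` / `cov_low_fold` | 1.5 / 0.5 | fold thresholds vs scaffold mean |
| `sc_sd_mult` | 1.5 | single-cell mode: mean ± 1.5 sd of window coverages |
| `sd_mult_discordant` | 3 | pair discordant beyond μ ± 3σ |
| `multi_ratio_thresh` / `disc_ratio_thresh` | 0.1 | ratio thresholds |
| `sd_mult_indel` | 2 | fragment-size closeness for indel validation |
| `disag_per_kbp` | 1 | fallback disagreement rate for large indels |
| `trim_cap` | 200 bp | cap on misjoin margin trimming per side |
| `min_span_pairs` | 3 | fragments needed for a spanning mean |
| `min_region_reads` | 5 | below this (with no spanning pairs): low evidence |
| `min_out_len` | 200 bp | floor for emitted corrected fragments |
| `match_slop` | 100 bp | truth-matching tolerance |

All threshold comparisons are strict exactly as stated (< 0.8, > 0.1,
< 2σ, > 3σ, < 0.1, > 1/kbp); the boundary tests in the suite pin this.

Choices worth explaining:

- **`min_depth` = 5.** The disagreement definition at depth 1–2 would
  fire on isolated sequencing errors; five reads is the smallest depth
  at which a sub-0.8 majority is meaningful.
- **`anomaly_windows` = 2** reads "more than one 50-bp sub-region"
  literally. Because breakpoint regions can be shorter than two
  windows, windows are collected from the region extended by one read
  length per side. Both the count and the extension are configurable.
- **Pair membership.** A pair's fragment interval is [leftmost 5′ end,
  rightmost 5′ end); a pair is "in" a region iff that interval overlaps
  it. Fragment size is the span between the two 5′ ends.
- **`min_span_pairs` = 3**: a mean over fewer fragments is too unstable
  to subject to a ±2σ test.
- **`trim_cap` = 200 bp** bounds misjoin margin trimming so a fully
  mismatched pileup cannot consume a flank.
- **Misjoin split semantics.** A split removes [M_L, M_R) from both
  pieces: the region is the mis-collapsed repeat whose two true copies
  each live on one side, so both derived pieces end flush at their
  margin. Middle indel errors are reported but not edited — rewriting
  bases inside a scaffold without reassembly would fabricate sequence.
- **Unaligned scaffolds** are validated through the end-insertion rule
  applied genome-wide and, when validated, reported rather than
  deleted; removing a whole scaffold record is more destructive than
  breaking at misjoins, which is the only sequence-level correction
  with clear support.
- **Reference-gap sign.** Only |g_r| > `misjoin_distance` (or a
  reference/strand change) makes a misjoin. A moderately negative g_r
  (segments overlapping on the reference) is deliberately routed
  through the indel arithmetic instead: tandem expansion in a scaffold
  legitimately produces overlapping reference intervals and is an
  insertion signature, not a misjoin.

## Synthetic scenarios

The generator is a pure function of (spec, seed). It partitions the
genome into equal windows, one scaffold per window, and gives each
engineered feature its own window so features cannot interact:

- **misjoins** are built the way they arise: the genome carries an
  exact two-copy 500-bp interspersed repeat (both copies also live in
  correctly assembled scaffolds), and the misjoined scaffold glues the
  sequence upstream of copy 1 to the sequence downstream of copy 2
  through the shared repeat. Reads from either copy then genuinely
  multi-align at the junction — the multi-align ratio is produced by
  the data, not asserted;
- **deletion errors** are collapsed tandem repeats: the genome carries
  two copies diverged by ~2 % (at least two substitutions), the
  scaffold one. Reads from both copies stack on the collapsed copy,
  giving elevated coverage and systematic pileup disagreements at the
  divergent sites — the classic collapse signature;
- **middle/end insertions** are novel sequence (expanded/untrimmed
  ends), giving zero-coverage interiors and oversized spanning
  fragments;
- **SVs** (duplication, relocation, insertion, deletion) are edits to
  the *reference*, so they create differences on correctly assembled
  scaffolds. The six-modification preset (duplication 1 kbp,
  relocation, 70/30-bp insertions, 70/30-bp deletions) yields exactly
  eight expected difference loci: one from the duplication, three from
  the relocation, one each from the indels.

Default error sizes (middle insertions 250–600 bp, end insertions
150–500 bp, deletions 130–240 bp) reflect repeat-collapse/expansion
scale and keep every error's validating evidence inside the operating
range of the rules above: deletions below ~100 bp cannot lift two
50-bp coverage windows past 1.5× and, with ≤1 divergent site, may leave
only one supporting feature — such errors are reported as warnings
rather than validated, which is the honest behaviour of the rule set.

The benchmark scenario is deliberately scaled down: a 1-Mbp genome
(relocation scaled to 20 kbp accordingly), 27 errors, 50× reads with
μ = 368 bp / σ = 61 bp and 0.5 % substitution error. At this size the
whole pipeline, including read alignment, runs in well under a minute,
and the test suite stays within an ordinary CI budget.

**What the simulation does not emulate.** Real base-quality profiles
and indel sequencing errors; chimeric fragments; GC-coverage bias; MDA
amplification bias (single-cell mode is exercised by its thresholds,
not by realistic unevenness); reference divergence beyond the
engineered SVs; gapped scaffolds with N runs (the gap-demotion path is
tested with constructed inputs instead). Passing tests therefore show
the decision rules and plumbing are correct under the stated model,
not that the thresholds are optimal for any particular real dataset.

## Built-in aligners

Both aligners exist so the pipeline is hermetic on synthetic data; they
are not general-purpose and external alignments (blast6/PAF, SAM/BAM)
are first-class inputs.

- **Long-sequence aligner:** unique 31-mer anchors chained per
  diagonal/strand, then X-drop extension (match +1, mismatch −3, drop
  12). Extension lets segments run through two-copy and slightly
  diverged repeats the way a real long-range aligner does — which is
  what makes misjoined segments overlap across their shared repeat and
  collapsed repeats appear as overlapping flanks. On synthetic data the
  implied size of every engineered indel is recovered exactly, because
  it derives from anchor diagonals, not from endpoint precision.
- **Read aligner:** seeds at `max_mismatch`+1 offsets (pigeonhole:
  every placement with ≤ 3 mismatches is found), full-length first;
  reads with no full-length placement fall back to the longest
  soft-clipped prefix/suffix of ≥ 30 bases, as short-read aligners clip
  across breakpoints. Equal-best placements pick one primary uniformly
  at random (seeded) so correct two-copy repeat regions keep coverage,
  and the rest mark the read multi-aligned.

## Numerical and degenerate-input conventions

- Zero-width junction regions (e.g., a clean deletion junction) are
  widened to 1 bp so evidence queries are well-defined.
- Ratios over empty read/pair sets are 0 with an explicit low-evidence
  flag downstream.
- Library estimation discards fragments outside [1, 5 × median] before
  taking mean/sd and refuses to estimate from under 1000 FR pairs.
- Chain-selection ties break deterministically: higher score, longer
  scaffold interval, smaller start; during extension, smaller
  overlap/gap first, then higher score.
- Coverage statistics exclude N-run bases from the scaffold mean and
  windows that are mostly N from anomaly counts, so assembly gaps
  cannot masquerade as coverage anomalies.

## Known limitations

- Short tandem-repeat indels below the read length can be genuinely
  indistinguishable from structural variation by these features; the
  rules then produce warnings or SV calls, trading recall for
  precision.
- The fragment-size closeness test cannot distinguish indel sizes
  smaller than 2σ from zero; such calls rest on the two-of-three
  feature clause alone.
- Spanning-fragment means are length-biased (pairs with larger inserts
  are more likely to bridge a region), which slightly shrinks the
  apparent size deficit of large deletions; the ±2σ tolerance absorbs
  this at the supported error sizes.
- Corrections never re-join or gap-fill; they only split and trim.
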