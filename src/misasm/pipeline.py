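"""End-to-end orchestration: chain alignments, classify differences,
gather read evidence, validate, correct, and summarise."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chain import Difference, SegmentChain, classify_differences, select_nonredundant
from .config import Config, DEFAULT
from .correct import (AssemblyStats, EvaluationResult, TruthRecord,
                      apply_corrections, assembly_stats, evaluate_against_truth)
from .evidence import LibraryModel, Pair, ScaffoldEvidence, estimate_library, pair_up
from .io_formats import AlignSegment, ReadAlignment, SequenceRecord
from .validate import Verdict, validate_difference


@dataclass
class PipelineResult:
    verdicts: list[Verdict]
    corrected: list[SequenceRecord]
    stats_before: AssemblyStats
    stats_after: AssemblyStats
    library: LibraryModel
    correction_log: list[str]
    evidence: dict[str, ScaffoldEvidence] = field(default_factory=dict)
    chains: dict[str, SegmentChain] = field(default_factory=dict)
    evaluation: Optional[EvaluationResult] = None
    sv_evaluation: Optional[EvaluationResult] = None

    @property
    def error_verdicts(self) -> list[Verdict]:
        return [v for v in self.verdicts if v.label.is_error]


def run_pipeline(
    scaffolds: Sequence[SequenceRecord],
    segments: Sequence[AlignSegment],
    read_alignments: Sequence[ReadAlignment],
    library: Optional[LibraryModel] = None,
    cfg: Config = DEFAULT,
    truth: Optional[Sequence[TruthRecord]] = None,
    keep_evidence: bool = False,
) -> PipelineResult:
    """Run the full mis-assembly analysis.

    ``segments`` are scaffold-to-reference alignments (any producer);
    ``read_alignments`` are paired-end read placements on the scaffolds.
    If ``library`` is None the insert-size model is estimated from the
    FR pairs.  When a truth table is given, error and SV evaluations are
    attached to the result.
    """
    scaffolds = list(scaffolds)
    by_scaffold_segs: dict[str, list[AlignSegment]] = {}
    for seg in segments:
        by_scaffold_segs.setdefault(seg.scaffold_id, []).append(seg)

    chains: dict[str, SegmentChain] = {}
    differences: dict[str, list[Difference]] = {}
    for scaf in scaffolds:
        chain = select_nonredundant(by_scaffold_segs.get(scaf.id, []), len(scaf),
                                    cfg.max_adjacency)
        if not chain.scaffold_id:
            chain = SegmentChain(scaf.id, len(scaf), ())
        chains[scaf.id] = chain
        diffs = classify_differences(chain, cfg.misjoin_distance,
                                     cfg.indel_min, cfg.end_min)
        if diffs:
            differences[scaf.id] = diffs

    reads_by_scaffold: dict[str, list[ReadAlignment]] = {}
    for r in read_alignments:
        reads_by_scaffold.setdefault(r.scaffold_id, []).append(r)
    pairs_by_scaffold, fr_fragments = pair_up(read_alignments)

    if library is None:
        library = estimate_library(fr_fragments, cfg.min_lib_pairs)

    verdicts: list[Verdict] = []
    evidence: dict[str, ScaffoldEvidence] = {}
    for scaf in scaffolds:
        diffs = differences.get(scaf.id)
        if not diffs:
            continue
        ev = ScaffoldEvidence(
            scaf,
            reads_by_scaffold.get(scaf.id, []),
            pairs_by_scaffold.get(scaf.id, []),
            library, cfg,
        )
        if keep_evidence:
            evidence[scaf.id] = ev
        for diff in diffs:
            verdicts.append(validate_difference(diff, chains[scaf.id], ev, cfg))

    corrected, log = apply_corrections(scaffolds, verdicts, cfg.min_out_len)
    result = PipelineResult(
        verdicts=verdicts,
        corrected=corrected,
        stats_before=assembly_stats(scaffolds),
        stats_after=assembly_stats(corrected),
        library=library,
        correction_log=log,
        evidence=evidence,
        chains=chains,
    )
    if truth is not None:
        result.evaluation = evaluate_against_truth(verdicts, truth,
                                                   cfg.match_slop, cls="error")
        result.sv_evaluation = evaluate_against_truth(verdicts, truth,
                                                      cfg.match_slop, cls="sv")
    return result
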