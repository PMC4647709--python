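"""Assembly correction, continuity statistics and truth evaluation.

Validated misjoins break their scaffold at the breakpoint region, with
the region itself (the mis-collapsed repeat tails around both margins)
removed from both resulting pieces; validated end insertions trim the
erroneous end off.  Middle indel errors are reported but not edited --
editing bases inside a scaffold without reassembly would fabricate
sequence.  Fragments shorter than ``min_out_len`` are dropped.

The evaluation counts a verdict as matching a truth record when the
scaffold and error class (misjoin / insertion / deletion) agree and the
breakpoint region overlaps the true locus within ``match_slop`` bp;
precision = TP/(TP+FP), TPR = TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import Config, DEFAULT
from .io_formats import SequenceRecord
from .validate import CorrectionKind, Label, Verdict


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_len: int
    n50: int


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one engineered difference.

    ``cls`` is 'error' for injected assembly errors and 'sv' for
    differences a correct assembly shows against an SV-mutated
    reference; ``kind`` is the expected difference class
    (misjoin/insertion/deletion).
    """

    scaffold_id: str
    kind: str
    left: int
    right: int
    size: int
    cls: str  # "error" | "sv"


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L sum to at least half
    the total length."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    return ordered[-1]  # unreachable


def assembly_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    lengths = [len(r) for r in records]
    return AssemblyStats(len(records), sum(lengths), n50(lengths) if lengths else 0)


def apply_corrections(scaffolds: Sequence[SequenceRecord],
                      verdicts: Sequence[Verdict],
                      min_out_len: int = DEFAULT.min_out_len,
                      ) -> tuple[list[SequenceRecord], list[str]]:
    """Apply SPLIT and TRIM_END corrections; returns (records, log).

    Splits are applied right-to-left so earlier coordinates stay valid;
    a trim overlapping a split interval is skipped (SPLIT takes
    precedence) and logged.  Fragments below ``min_out_len`` are
    dropped with a log entry.  Unaffected scaffolds keep their ids;
    split/trimmed pieces get ``.1``, ``.2`` ... suffixes.
    """
    by_scaffold: dict[str, list[Verdict]] = {}
    for v in verdicts:
        if v.correction.kind is not CorrectionKind.REPORT_ONLY and v.label.is_error:
            by_scaffold.setdefault(v.difference.scaffold_id, []).append(v)

    out: list[SequenceRecord] = []
    log: list[str] = []
    for scaf in scaffolds:
        todo = by_scaffold.get(scaf.id)
        if not todo:
            out.append(scaf)
            continue
        L = len(scaf)
        splits = sorted(
            ((v.correction.left, v.correction.right) for v in todo
             if v.correction.kind is CorrectionKind.SPLIT),
            key=lambda iv: iv[0],
        )
        lo, hi = 0, L  # remaining extent after end trims
        for v in todo:
            c = v.correction
            if c.kind is not CorrectionKind.TRIM_END:
                continue
            cut = c.left if c.side == "left" else c.right
            if any(s <= cut <= e for s, e in splits):
                log.append(f"{scaf.id}: TRIM_END at {cut} overlaps a SPLIT interval; skipped")
                continue
            if c.side == "left":
                lo = max(lo, c.left)
            else:
                hi = min(hi, c.right)
        # build kept intervals: [lo, hi) minus every split interval
        kept: list[tuple[int, int]] = []
        cursor = lo
        for s, e in splits:
            s, e = max(s, lo), min(e, hi)
            if s > cursor:
                kept.append((cursor, s))
            cursor = max(cursor, e)
        if hi > cursor:
            kept.append((cursor, hi))
        if kept == [(0, L)]:
            out.append(scaf)
            continue
        piece_no = 0
        for s, e in kept:
            if e - s < min_out_len:
                log.append(f"{scaf.id}: fragment [{s},{e}) shorter than {min_out_len} bp dropped")
                continue
            piece_no += 1
            out.append(SequenceRecord(f"{scaf.id}.{piece_no}", scaf.sequence[s:e]))
        if piece_no == 0:
            log.append(f"{scaf.id}: all fragments dropped")
    return out, log


# ---------------------------------------------------------------------------
# evaluation against a truth table
# ---------------------------------------------------------------------------

_LABEL_CLASS = {
    Label.ERROR_MISJOIN: "misjoin",
    Label.ERROR_INSERTION: "insertion",
    Label.ERROR_DELETION: "deletion",
}


def _verdict_class(v: Verdict) -> Optional[str]:
    if v.label in _LABEL_CLASS:
        return _LABEL_CLASS[v.label]
    if v.label is Label.CORRECT_SV:
        return v.difference.kind.error_class
    return None


def evaluate_against_truth(verdicts: Sequence[Verdict],
                           truth: Sequence[TruthRecord],
                           match_slop: int = DEFAULT.match_slop,
                           cls: str = "error") -> EvaluationResult:
    """Match verdicts of one class ('error' or 'sv') against truth.

    Error verdicts are compared with truth class 'error'; CORRECT_SV
    verdicts with truth class 'sv'.  A match needs the same scaffold,
    the same error class and breakpoint-region overlap within
    ``match_slop``.  Matching is greedy over truth records sorted by
    position, one verdict per truth record, and is independent of
    verdict input order.
    """
    if cls == "error":
        cands = [v for v in verdicts if v.label.is_error]
    elif cls == "sv":
        cands = [v for v in verdicts if v.label is Label.CORRECT_SV]
    else:
        raise ValueError(f"unknown truth class {cls!r}")
    truths = sorted((t for t in truth if t.cls == cls),
                    key=lambda t: (t.scaffold_id, t.left, t.right))
    cands = sorted(cands, key=lambda v: (v.difference.scaffold_id,
                                         v.region.M_L, v.region.M_R))
    used = [False] * len(cands)
    tp = 0
    for t in truths:
        for i, v in enumerate(cands):
            if used[i]:
                continue
            if v.difference.scaffold_id != t.scaffold_id:
                continue
            if _verdict_class(v) != t.kind:
                continue
            if v.region.M_L - match_slop < t.right + 1 and v.region.M_R + match_slop > t.left - 1:
                used[i] = True
                tp += 1
                break
    fp = used.count(False)
    fn = len(truths) - tp
    return EvaluationResult(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize(verdicts: Sequence[Verdict],
              stats_before: Optional[AssemblyStats] = None,
              stats_after: Optional[AssemblyStats] = None) -> pd.DataFrame:
    """Counts by label and kind plus N50 before/after, as a tidy table."""
    rows: list[dict] = []
    for label in Label:
        n = sum(1 for v in verdicts if v.label is label)
        rows.append({"metric": f"n_{label.value}", "value": n})
    kind_counts: dict[str, int] = {}
    for v in verdicts:
        if v.label.is_error:
            key = f"n_error_{v.difference.kind.error_class}"
            kind_counts[key] = kind_counts.get(key, 0) + 1
    for key in ("n_error_misjoin", "n_error_insertion", "n_error_deletion"):
        rows.append({"metric": key, "value": kind_counts.get(key, 0)})
    if stats_before is not None:
        rows += [
            {"metric": "n_scaffolds_before", "value": stats_before.n_scaffolds},
            {"metric": "total_len_before", "value": stats_before.total_len},
            {"metric": "n50_before", "value": stats_before.n50},
        ]
    if stats_after is not None:
        rows += [
            {"metric": "n_scaffolds_after", "value": stats_after.n_scaffolds},
            {"metric": "total_len_after", "value": stats_after.total_len},
            {"metric": "n50_after", "value": stats_after.n50},
        ]
    return pd.DataFrame(rows, columns=["metric", "value"])
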