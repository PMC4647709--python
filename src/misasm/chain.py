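"""Non-redundant alignment chaining and putative-difference calling.

A scaffold usually attracts many overlapping reference alignments; only
a best chain of segments that together cover the scaffold is informative
about its structure.  The junctions between chained segments are then
classified into putative mis-assemblies: misjoins (distant regions,
opposite strands or different replicons joined together), middle
insertions/deletions (scaffold and reference gap sizes disagree) and
unaligned scaffold ends or whole scaffolds (treated as insertions).
All of these remain *putative* until read evidence validates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .config import Config, DEFAULT
from .io_formats import AlignSegment


class DiffKind(str, Enum):
    MISJOIN = "misjoin"
    INSERTION_MID = "insertion_mid"
    INSERTION_END = "insertion_end"
    DELETION = "deletion"
    UNALIGNED_SCAFFOLD = "unaligned_scaffold"

    @property
    def error_class(self) -> str:
        """Collapse to the three truth classes: misjoin/insertion/deletion."""
        if self is DiffKind.MISJOIN:
            return "misjoin"
        if self is DiffKind.DELETION:
            return "deletion"
        return "insertion"


@dataclass(frozen=True)
class SegmentChain:
    scaffold_id: str
    scaffold_len: int
    segments: tuple[AlignSegment, ...]

    def __post_init__(self):
        starts = [s.s_start for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("chain segments must be sorted by s_start")


@dataclass(frozen=True)
class Difference:
    """A putative mis-assembly located on a scaffold.

    ``s_left``/``s_right`` bound the difference on the scaffold;
    ``est_size`` is the inserted/deleted length implied by the alignment
    gap arithmetic (0 for misjoins).  ``end_side`` marks which scaffold
    end an INSERTION_END sits on.
    """

    kind: DiffKind
    scaffold_id: str
    s_left: int
    s_right: int
    est_size: int = 0
    left_seg: Optional[AlignSegment] = None
    right_seg: Optional[AlignSegment] = None
    end_side: Optional[str] = None  # "left" | "right" for INSERTION_END

    def __post_init__(self):
        if self.s_left > self.s_right:
            raise ValueError("difference must have s_left <= s_right")
        if self.est_size < 0:
            raise ValueError("est_size must be >= 0")
        if self.kind is DiffKind.MISJOIN and (self.left_seg is None or self.right_seg is None):
            raise ValueError("misjoin requires both flanking segments")


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _seg_sort_key(seg: AlignSegment):
    # preference order: higher score, longer scaffold interval, smaller s_start
    return (-seg.score, -seg.s_len, seg.s_start)


def _remove_contained(segments: Sequence[AlignSegment]) -> list[AlignSegment]:
    """Drop segments whose scaffold interval lies inside another's.

    Contained segments can never be chosen by the extension rule but
    complicate the overlap/gap arithmetic, so they go first.  Exact
    duplicates are collapsed too.
    """
    uniq = list(dict.fromkeys(segments))
    uniq.sort(key=lambda s: (s.s_start, -s.s_end, _seg_sort_key(s)))
    kept: list[AlignSegment] = []
    max_end = -1
    for seg in uniq:
        if seg.s_end <= max_end:
            continue  # contained in an earlier (wider or equal) interval
        kept.append(seg)
        max_end = seg.s_end
    return kept


def select_nonredundant(
    segments: Sequence[AlignSegment], scaffold_len: int,
    max_adjacency: int = DEFAULT.max_adjacency,
) -> SegmentChain:
    """Reduce raw alignments to one ordered chain covering the scaffold.

    A uniquely aligned scaffold keeps its single segment unchanged.
    Otherwise chaining starts from the best-scoring segment and extends
    greedily toward the 3' end, at each step taking the candidate whose
    scaffold-interval overlap or gap with the current chain end is
    smallest, restricted to candidates within ``max_adjacency``; if no
    candidate is that close, the globally closest extending segment is
    admitted.  The 5' side is extended symmetrically.  Ties: smaller
    overlap/gap first, then higher score.
    """
    if not segments:
        return SegmentChain(scaffold_id="", scaffold_len=scaffold_len, segments=())
    scaffold_id = segments[0].scaffold_id
    if any(s.scaffold_id != scaffold_id for s in segments):
        raise ValueError("all segments must belong to one scaffold")
    if len(segments) == 1:
        return SegmentChain(scaffold_id, scaffold_len, (segments[0],))

    work = _remove_contained(segments)
    start = min(work, key=_seg_sort_key)
    chosen = [start]
    pool = [s for s in work if s is not start]

    # extend toward the scaffold 3' end
    cur_end = start.s_end
    while True:
        cands = [s for s in pool if s.s_end > cur_end]
        if not cands:
            break
        def adj(s: AlignSegment) -> int:
            return abs(s.s_start - cur_end)
        within = [s for s in cands if adj(s) <= max_adjacency]
        pick_from = within if within else cands
        pick = min(pick_from, key=lambda s: (adj(s), -s.score, s.s_start))
        chosen.append(pick)
        pool.remove(pick)
        cur_end = pick.s_end

    # extend toward the 5' end
    cur_start = start.s_start
    while True:
        cands = [s for s in pool if s.s_start < cur_start]
        if not cands:
            break
        def adj5(s: AlignSegment) -> int:
            return abs(cur_start - s.s_end)
        within = [s for s in cands if adj5(s) <= max_adjacency]
        pick_from = within if within else cands
        pick = min(pick_from, key=lambda s: (adj5(s), -s.score, s.s_start))
        chosen.append(pick)
        pool.remove(pick)
        cur_start = pick.s_start

    chosen.sort(key=lambda s: (s.s_start, s.s_end))
    return SegmentChain(scaffold_id, scaffold_len, tuple(chosen))


# ---------------------------------------------------------------------------
# difference classification
# ---------------------------------------------------------------------------

def reference_gap(left: AlignSegment, right: AlignSegment) -> Optional[int]:
    """Oriented reference gap between two same-reference, same-strand
    segments adjacent on the scaffold (None if ref/strand differ).

    Positive: reference sequence lies between them (deletion signature);
    negative: their reference intervals overlap (insertion/expansion
    signature).
    """
    if left.ref_id != right.ref_id or left.strand != right.strand:
        return None
    if left.strand == "+":
        return right.r_start - left.r_end
    return left.r_start - right.r_end


def classify_differences(
    chain: SegmentChain,
    misjoin_distance: int = DEFAULT.misjoin_distance,
    indel_min: int = DEFAULT.indel_min,
    end_min: int = DEFAULT.end_min,
) -> list[Difference]:
    """Classify chain junctions and unaligned spans into putative errors.

    Junction rules for adjacent segments (scaffold gap g_s, oriented
    reference gap g_r): different reference, different strand or
    |g_r| > misjoin_distance -> MISJOIN; otherwise g_s - g_r > indel_min
    -> INSERTION_MID of that size, g_r - g_s > indel_min -> DELETION.
    Unaligned scaffold ends longer than end_min are INSERTION_END; a
    scaffold with no alignments at all is UNALIGNED_SCAFFOLD (treated as
    insertion downstream).
    """
    diffs: list[Difference] = []
    segs = chain.segments
    if not segs:
        if chain.scaffold_len > 0 and chain.scaffold_id:
            diffs.append(Difference(
                DiffKind.UNALIGNED_SCAFFOLD, chain.scaffold_id,
                0, chain.scaffold_len, est_size=chain.scaffold_len,
            ))
        return diffs

    sid = chain.scaffold_id
    if segs[0].s_start > end_min:
        diffs.append(Difference(
            DiffKind.INSERTION_END, sid, 0, segs[0].s_start,
            est_size=segs[0].s_start, right_seg=segs[0], end_side="left",
        ))

    for left, right in zip(segs, segs[1:]):
        g_s = right.s_start - left.s_end
        g_r = reference_gap(left, right)
        lo, hi = min(left.s_end, right.s_start), max(left.s_end, right.s_start)
        if g_r is None or abs(g_r) > misjoin_distance:
            diffs.append(Difference(
                DiffKind.MISJOIN, sid, lo, hi,
                est_size=0, left_seg=left, right_seg=right,
            ))
            continue
        delta = g_s - g_r
        if delta > indel_min:
            diffs.append(Difference(
                DiffKind.INSERTION_MID, sid, lo, hi,
                est_size=delta, left_seg=left, right_seg=right,
            ))
        elif -delta > indel_min:
            diffs.append(Difference(
                DiffKind.DELETION, sid, lo, hi,
                est_size=-delta, left_seg=left, right_seg=right,
            ))
        # else: alignment jitter, no difference

    if chain.scaffold_len - segs[-1].s_end > end_min:
        diffs.append(Difference(
            DiffKind.INSERTION_END, sid, segs[-1].s_end, chain.scaffold_len,
            est_size=chain.scaffold_len - segs[-1].s_end,
            left_seg=segs[-1], end_side="right",
        ))
    return diffs
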