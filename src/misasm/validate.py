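"""Breakpoint regions and per-type validation of putative mis-assemblies.

Each putative difference gets a *breakpoint region* [M_L, M_R) on its
scaffold, the interval over which read evidence is evaluated:

* misjoin: the overlap (or junction) of the two flanking segments,
  with each margin trimmed outward past contiguous tail columns whose
  pileup majority base disagrees with the scaffold base (alignment
  tools leave mismatched tails around the repeat margins);
* middle insertion/deletion: the inner endpoints of the flanking
  segments, read directly off the alignments;
* end insertion: the unaligned scaffold end; unaligned scaffold: the
  whole scaffold.

Validation applies the per-type decision rules, all thresholds strict
as specified:

* misjoin is an error iff it has abnormal coverage (high/low/zero) or
  more than 1 disagreement, OR its multi-align ratio exceeds 0.1;
* a middle insertion is an error iff the spanning-pair fragment excess
  over the library mean is within 2 sigma of the inserted size AND at
  least two of {disagreements, low coverage, discordant ratio > 0.1}
  hold; without a usable fragment test (inserted sequence longer than
  the fragments can bridge) the fallback is more than one disagreement
  per kbp; an end insertion is an error iff the end has disagreements
  or zero-coverage bases;
* a deletion is the mirror image (library mean minus fragment size
  close to the deleted size; abnormal coverage counts high/low/zero);
* anything not validated is a correct assembly reflecting structural
  variation between target and reference iff its region shows even
  coverage, no disagreements and discordant ratio below 0.1 --
  otherwise it is reported as a warning.

Differences overlapping N-gap runs are reported as gaps, never errors:
those regions simply lack read coverage and are normal in scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .chain import DiffKind, Difference, SegmentChain
from .config import Config, DEFAULT
from .evidence import EvidenceBundle, LibraryModel, ScaffoldEvidence


class Label(str, Enum):
    ERROR_MISJOIN = "ERROR_MISJOIN"
    ERROR_INSERTION = "ERROR_INSERTION"
    ERROR_DELETION = "ERROR_DELETION"
    CORRECT_SV = "CORRECT_SV"
    WARNING = "WARNING"
    GAP_REPORT = "GAP_REPORT"

    @property
    def is_error(self) -> bool:
        return self.name.startswith("ERROR_")


class CorrectionKind(str, Enum):
    SPLIT = "SPLIT"
    TRIM_END = "TRIM_END"
    REPORT_ONLY = "REPORT_ONLY"


@dataclass(frozen=True)
class Correction:
    kind: CorrectionKind
    # SPLIT: remove [left, right) and split; TRIM_END: drop bases beyond
    # position (side 'right') or before it (side 'left')
    left: Optional[int] = None
    right: Optional[int] = None
    side: Optional[str] = None

    def __str__(self) -> str:
        if self.kind is CorrectionKind.SPLIT:
            return f"SPLIT[{self.left},{self.right})"
        if self.kind is CorrectionKind.TRIM_END:
            return f"TRIM_END({self.side}@{self.left if self.side == 'left' else self.right})"
        return "REPORT_ONLY"


REPORT_ONLY = Correction(CorrectionKind.REPORT_ONLY)


@dataclass(frozen=True)
class BreakpointRegion:
    scaffold_id: str
    M_L: int
    M_R: int
    origin_kind: DiffKind

    def __post_init__(self):
        if self.M_L > self.M_R:
            raise ValueError("breakpoint region must have M_L <= M_R")

    @property
    def interval(self) -> tuple[int, int]:
        return self.M_L, self.M_R

    def __len__(self) -> int:
        return self.M_R - self.M_L


@dataclass(frozen=True)
class Verdict:
    difference: Difference
    region: BreakpointRegion
    label: Label
    evidence: Optional[EvidenceBundle]
    correction: Correction
    note: str = ""

    def __post_init__(self):
        if self.label is Label.ERROR_MISJOIN and self.correction.kind is not CorrectionKind.SPLIT:
            raise ValueError("misjoin errors must carry a SPLIT correction")
        if self.label in (Label.CORRECT_SV, Label.WARNING, Label.GAP_REPORT) \
                and self.correction.kind is not CorrectionKind.REPORT_ONLY:
            raise ValueError(f"{self.label} must be report-only")

    def report_row(self) -> dict:
        ev = self.evidence
        return {
            "scaffold": self.difference.scaffold_id,
            "kind": self.difference.kind.value,
            "s_left": self.difference.s_left,
            "s_right": self.difference.s_right,
            "M_L": self.region.M_L,
            "M_R": self.region.M_R,
            "label": self.label.value,
            "correction": str(self.correction),
            "est_size": self.difference.est_size,
            "n_disagreements": ev.n_disagreements if ev else None,
            "disagreements_per_kbp": round(ev.disagreements_per_kbp, 3) if ev else None,
            "has_high_cov": ev.has_high_cov if ev else None,
            "has_low_cov": ev.has_low_cov if ev else None,
            "has_zero_cov": ev.has_zero_cov if ev else None,
            "multi_align_ratio": round(ev.multi_align_ratio, 4) if ev else None,
            "discordant_ratio": round(ev.discordant_ratio, 4) if ev else None,
            "span_frag_mean": round(ev.span_frag_mean, 1) if ev and ev.span_frag_mean is not None else None,
            "span_pair_count": ev.span_pair_count if ev else None,
            "low_evidence": "low evidence" in self.note,
        }


# ---------------------------------------------------------------------------
# breakpoint regions
# ---------------------------------------------------------------------------

def _trim_mismatched_tails(ev: ScaffoldEvidence, m_l: int, m_r: int,
                           cap: int) -> tuple[int, int]:
    """Extend margins outward past contiguous columns whose pileup
    majority base disagrees with the scaffold base (capped per side)."""
    codes = ev.scaffold_codes
    j, moved = m_l - 1, 0
    while j >= 0 and moved < cap:
        maj = ev.majority_base_code(j)
        if maj == 4 or maj == codes[j]:
            break
        j -= 1
        moved += 1
    new_l = j + 1
    L = len(codes)
    j, moved = m_r, 0
    while j < L and moved < cap:
        maj = ev.majority_base_code(j)
        if maj == 4 or maj == codes[j]:
            break
        j += 1
        moved += 1
    new_r = j
    return new_l, new_r


def compute_breakpoint_region(diff: Difference, chain: SegmentChain,
                              ev: Optional[ScaffoldEvidence] = None,
                              cfg: Config = DEFAULT) -> BreakpointRegion:
    """Breakpoint region [M_L, M_R) for a difference (see module doc).

    Pileup-based margin trimming for misjoins happens only when
    evidence is supplied.  Regions are clipped to the scaffold and
    widened to at least 1 bp so evidence queries are well-defined.
    """
    L = chain.scaffold_len
    if diff.kind is DiffKind.UNALIGNED_SCAFFOLD:
        m_l, m_r = 0, L
    elif diff.kind is DiffKind.INSERTION_END:
        m_l, m_r = diff.s_left, diff.s_right
    else:
        m_l, m_r = diff.s_left, diff.s_right
        if diff.kind is DiffKind.MISJOIN and ev is not None:
            m_l, m_r = _trim_mismatched_tails(ev, m_l, m_r, cfg.trim_cap)
    m_l = max(0, min(m_l, L - 1))
    m_r = max(m_l + 1, min(m_r, L))
    return BreakpointRegion(diff.scaffold_id, m_l, m_r, diff.kind)


# ---------------------------------------------------------------------------
# validation rules
# ---------------------------------------------------------------------------

def _at_least_two(*conditions: bool) -> bool:
    return sum(bool(c) for c in conditions) >= 2


def validate_misjoin(diff: Difference, region: BreakpointRegion,
                     ev: EvidenceBundle, cfg: Config = DEFAULT) -> Verdict:
    cond_cov = ev.has_high_cov or ev.has_low_cov or ev.has_zero_cov or ev.n_disagreements > 1
    cond_multi = ev.multi_align_ratio > cfg.multi_ratio_thresh
    if cond_cov or cond_multi:
        return Verdict(diff, region, Label.ERROR_MISJOIN, ev,
                       Correction(CorrectionKind.SPLIT, region.M_L, region.M_R))
    return classify_sv(diff, region, ev, cfg)


def _end_correction(diff: Difference, region: BreakpointRegion) -> Correction:
    if diff.end_side == "left":
        return Correction(CorrectionKind.TRIM_END, left=region.M_R, side="left")
    return Correction(CorrectionKind.TRIM_END, right=region.M_L, side="right")


def validate_insertion(diff: Difference, region: BreakpointRegion,
                       ev: EvidenceBundle, lib: LibraryModel,
                       cfg: Config = DEFAULT) -> Verdict:
    if diff.kind in (DiffKind.INSERTION_END, DiffKind.UNALIGNED_SCAFFOLD):
        if ev.n_disagreements >= 1 or ev.has_zero_cov:
            correction = (_end_correction(diff, region)
                          if diff.kind is DiffKind.INSERTION_END else REPORT_ONLY)
            return Verdict(diff, region, Label.ERROR_INSERTION, ev, correction)
        return classify_sv(diff, region, ev, cfg)

    # middle insertion
    if ev.span_frag_mean is not None:
        frag_excess = ev.span_frag_mean - lib.mu
        if abs(frag_excess - diff.est_size) < cfg.sd_mult_indel * lib.sigma:
            if _at_least_two(
                ev.n_disagreements >= 1,
                ev.has_low_cov,
                ev.discordant_ratio > cfg.disc_ratio_thresh,
            ):
                return Verdict(diff, region, Label.ERROR_INSERTION, ev, REPORT_ONLY)
            return classify_sv(diff, region, ev, cfg)
    # no usable fragment-size match (inserted sequence typically longer
    # than what fragments can bridge): fall back to the disagreement rate
    if ev.disagreements_per_kbp > cfg.disag_per_kbp:
        return Verdict(diff, region, Label.ERROR_INSERTION, ev, REPORT_ONLY)
    return classify_sv(diff, region, ev, cfg)


def validate_deletion(diff: Difference, region: BreakpointRegion,
                      ev: EvidenceBundle, lib: LibraryModel,
                      cfg: Config = DEFAULT) -> Verdict:
    if ev.span_frag_mean is not None:
        frag_deficit = lib.mu - ev.span_frag_mean
        if abs(frag_deficit - diff.est_size) < cfg.sd_mult_indel * lib.sigma:
            if _at_least_two(
                ev.n_disagreements >= 1,
                ev.has_high_cov or ev.has_low_cov or ev.has_zero_cov,
                ev.discordant_ratio > cfg.disc_ratio_thresh,
            ):
                return Verdict(diff, region, Label.ERROR_DELETION, ev, REPORT_ONLY)
            return classify_sv(diff, region, ev, cfg)
    if ev.disagreements_per_kbp > cfg.disag_per_kbp:
        return Verdict(diff, region, Label.ERROR_DELETION, ev, REPORT_ONLY)
    return classify_sv(diff, region, ev, cfg)


def classify_sv(diff: Difference, region: BreakpointRegion,
                ev: EvidenceBundle, cfg: Config = DEFAULT) -> Verdict:
    """Unvalidated differences: structural variation or warning.

    A region with too few reads to judge is a warning, not a correct
    assembly -- absence of reads is not evidence of correctness.
    """
    if ev.span_pair_count < cfg.min_span_pairs and ev.n_reads < cfg.min_region_reads:
        return Verdict(diff, region, Label.WARNING, ev, REPORT_ONLY,
                       note="low evidence: too few reads to judge")
    if (not ev.has_high_cov and not ev.has_low_cov and not ev.has_zero_cov
            and ev.n_disagreements == 0
            and ev.discordant_ratio < cfg.disc_ratio_thresh):
        return Verdict(diff, region, Label.CORRECT_SV, ev, REPORT_ONLY)
    return Verdict(diff, region, Label.WARNING, ev, REPORT_ONLY)


def _overlaps_gap_run(diff: Difference, region: BreakpointRegion,
                      n_mask: np.ndarray) -> bool:
    lo = min(diff.s_left, region.M_L)
    hi = max(diff.s_right, region.M_R)
    return bool(n_mask[lo:hi].any())


def validate_difference(diff: Difference, chain: SegmentChain,
                        ev: ScaffoldEvidence, cfg: Config = DEFAULT) -> Verdict:
    """Compute the breakpoint region, gather evidence and apply the
    per-type rule; the single entry point the pipeline uses."""
    region = compute_breakpoint_region(diff, chain, ev, cfg)
    if _overlaps_gap_run(diff, region, ev.n_mask):
        return Verdict(diff, region, Label.GAP_REPORT, None, REPORT_ONLY,
                       note="difference overlaps an assembly gap (N run)")
    bundle = ev.bundle(region.interval)
    if diff.kind is DiffKind.MISJOIN:
        return validate_misjoin(diff, region, bundle, cfg)
    if diff.kind is DiffKind.DELETION:
        return validate_deletion(diff, region, bundle, ev.lib, cfg)
    return validate_insertion(diff, region, bundle, ev.lib, cfg)
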