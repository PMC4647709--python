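"""Paired-end read evidence features.

Everything the validation rules consume is computed here from read
alignments on one scaffold: the base-count pileup, disagreement calls,
windowed coverage anomalies (standard and single-cell thresholds), the
multi-align ratio, discordant-pair classification and ratios, and the
fragment sizes of pairs spanning a breakpoint region.

A *disagreement* is a scaffold position whose pileup majority-base
fraction is strictly below ``majority_frac`` at depth >= ``min_depth``.
A pair is *discordant* when it is not inward-facing (FR) or its
fragment size deviates from the library mean by more than
``sd_mult_discordant`` standard deviations.  The fragment size is the
span between the two 5' ends of the pair as placed on the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import dna
from .config import Config, DEFAULT
from .io_formats import ReadAlignment, SequenceRecord


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupColumn:
    counts: dict  # {"A": int, "C": int, "G": int, "T": int}
    depth: int
    multi_count: int


@dataclass(frozen=True)
class LibraryModel:
    """Insert-size model of the sequencing library (mean/sd in bp)."""

    mu: float
    sigma: float
    source: str = "given"  # "given" | "estimated"

    def __post_init__(self):
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("library mu and sigma must be positive")


@dataclass(frozen=True)
class EvidenceBundle:
    """All per-region features the validation rules look at."""

    n_disagreements: int
    disagreements_per_kbp: float
    has_high_cov: bool
    has_low_cov: bool
    has_zero_cov: bool
    multi_align_ratio: float
    discordant_ratio: float
    span_frag_mean: Optional[float]
    span_pair_count: int
    n_reads: int
    end_paired_support: bool = False

    def __post_init__(self):
        for r in (self.multi_align_ratio, self.discordant_ratio):
            if not (0.0 <= r <= 1.0):
                raise ValueError("ratios must lie in [0, 1]")
        if self.n_disagreements < 0 or self.disagreements_per_kbp < 0:
            raise ValueError("rates must be >= 0")


class Pileup:
    """Columnwise A/C/G/T counts plus multi-aligned-read coverage."""

    def __init__(self, length: int):
        self.counts = np.zeros((length, 4), dtype=np.int32)
        self.multi = np.zeros(length, dtype=np.int32)
        self.n_rejected = 0  # reads whose interval fell outside the scaffold

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, i: int) -> PileupColumn:
        c = self.counts[i]
        return PileupColumn(
            counts={"A": int(c[0]), "C": int(c[1]), "G": int(c[2]), "T": int(c[3])},
            depth=int(c.sum()), multi_count=int(self.multi[i]),
        )


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def build_pileup(reads: Iterable[ReadAlignment], scaffold: SequenceRecord) -> Pileup:
    """One column per scaffold base; N read bases ignored; reads whose
    interval leaves the scaffold are rejected (counted, not raised)."""
    L = len(scaffold)
    pile = Pileup(L)
    pos_chunks: list[np.ndarray] = []
    code_chunks: list[np.ndarray] = []
    multi_chunks: list[np.ndarray] = []
    pending = 0

    def flush():
        nonlocal pending
        if not pos_chunks:
            return
        pos = np.concatenate(pos_chunks)
        codes = np.concatenate(code_chunks)
        keep = codes < 4
        np.add.at(pile.counts, (pos[keep], codes[keep]), 1)
        if multi_chunks:
            np.add.at(pile.multi, np.concatenate(multi_chunks), 1)
        pos_chunks.clear(); code_chunks.clear(); multi_chunks.clear()
        pending = 0

    for read in reads:
        if read.scaffold_id != scaffold.id:
            continue
        if read.pos < 0 or read.end > L:
            pile.n_rejected += 1
            continue
        if read.seq is None:
            continue
        codes = dna.encode(read.seq[: read.end - read.pos])
        pos = np.arange(read.pos, read.pos + codes.size)
        pos_chunks.append(pos)
        code_chunks.append(codes)
        if read.is_multi:
            multi_chunks.append(pos)
        pending += codes.size
        if pending >= 2_000_000:
            flush()
    flush()
    return pile


def call_disagreements(
    pileup: Pileup,
    majority_frac: float = DEFAULT.majority_frac,
    min_depth: int = DEFAULT.min_depth,
) -> np.ndarray:
    """Positions where depth >= min_depth and the majority-base fraction
    is strictly below majority_frac."""
    depth = pileup.depth
    majority = pileup.counts.max(axis=1)
    mask = (depth >= min_depth) & (majority < majority_frac * depth)
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# coverage anomalies
# ---------------------------------------------------------------------------

def _window_means(depth: np.ndarray, window: int) -> np.ndarray:
    L = depth.size
    n_win = (L + window - 1) // window
    padded = np.zeros(n_win * window, dtype=np.float64)
    padded[:L] = depth
    sums = padded.reshape(n_win, window).sum(axis=1)
    sizes = np.full(n_win, window, dtype=np.float64)
    if L % window:
        sizes[-1] = L % window
    return sums / sizes


def coverage_flags(
    pileup: Pileup,
    region: tuple[int, int],
    scaffold_seq: Optional[str] = None,
    mode: str = "standard",
    window: int = DEFAULT.window_cov,
    anomaly_windows: int = DEFAULT.anomaly_windows,
    flank: int = 0,
    high_fold: float = DEFAULT.cov_high_fold,
    low_fold: float = DEFAULT.cov_low_fold,
    sc_sd_mult: float = DEFAULT.sc_sd_mult,
    gap_run_min: int = DEFAULT.gap_run_min,
) -> tuple[bool, bool, bool]:
    """(has_high_cov, has_low_cov, has_zero_cov) for a scaffold region.

    The scaffold is partitioned into consecutive ``window``-bp windows.
    Standard mode flags high/low when at least ``anomaly_windows``
    windows intersecting the region (extended by ``flank`` on each side,
    typically one read length, because breakpoint regions can be shorter
    than two windows) exceed high_fold x the scaffold mean coverage or
    fall below low_fold x it.  Single-cell mode replaces the fold
    thresholds with the window-mean +/- sc_sd_mult x window-sd of that
    scaffold.  has_zero_cov is true iff any base of the unextended
    region has depth 0.  N-gap windows are excluded from anomaly counts
    and N-run bases from the scaffold mean.
    """
    start, end = region
    L = len(pileup)
    if not (0 <= start < end <= L):
        raise ValueError(f"region [{start},{end}) outside scaffold of length {L}")
    if mode not in ("standard", "single_cell"):
        raise ValueError(f"unknown coverage mode {mode!r}")

    depth = pileup.depth.astype(np.float64)
    n_mask = (dna.n_run_mask(scaffold_seq, gap_run_min)
              if scaffold_seq is not None else np.zeros(L, dtype=bool))

    wmeans = _window_means(depth, window)
    if mode == "single_cell":
        usable = _window_means((~n_mask).astype(np.float64), window) > 0.5
        base = wmeans[usable] if usable.any() else wmeans
        mean, sd = float(base.mean()), float(base.std())
        hi_thr = mean + sc_sd_mult * sd
        lo_thr = mean - sc_sd_mult * sd
    else:
        valid = depth[~n_mask]
        scaf_mean = float(valid.mean()) if valid.size else 0.0
        hi_thr = high_fold * scaf_mean
        lo_thr = low_fold * scaf_mean

    w_lo = max(0, (start - flank)) // window
    w_hi = (min(L, end + flank) - 1) // window + 1
    sel = np.arange(w_lo, w_hi)
    # drop windows that are mostly assembly gap (N runs)
    n_frac = _window_means(n_mask.astype(np.float64), window)[sel]
    sel = sel[n_frac <= 0.5]
    w = wmeans[sel]

    has_high = int((w > hi_thr).sum()) >= anomaly_windows
    has_low = int((w < lo_thr).sum()) >= anomaly_windows
    region_depth = depth[start:end]
    region_n = n_mask[start:end]
    has_zero = bool(((region_depth == 0) & ~region_n).any())
    return has_high, has_low, has_zero


# ---------------------------------------------------------------------------
# read sets and pair sets (array-backed, one per scaffold)
# ---------------------------------------------------------------------------

class ReadSet:
    """Interval + multi-flag arrays for all reads on one scaffold."""

    def __init__(self, reads: Sequence[ReadAlignment]):
        self.starts = np.array([r.pos for r in reads], dtype=np.int64)
        self.ends = np.array([r.end for r in reads], dtype=np.int64)
        self.is_multi = np.array([r.is_multi for r in reads], dtype=bool)
        self.median_len = int(np.median(self.ends - self.starts)) if reads else 0

    def __len__(self) -> int:
        return self.starts.size

    def overlapping(self, start: int, end: int) -> np.ndarray:
        return (self.starts < end) & (self.ends > start)


def multi_align_ratio(reads: ReadSet, region: tuple[int, int]) -> tuple[float, int]:
    """(fraction of region-overlapping reads flagged multi, read count);
    ratio 0 with count 0 when the region holds no reads."""
    mask = reads.overlapping(*region)
    n = int(mask.sum())
    if n == 0:
        return 0.0, 0
    return float(reads.is_multi[mask].sum()) / n, n


@dataclass(frozen=True)
class Pair:
    """A resolved read pair on one scaffold (mates given left-to-right)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    left_strand: str
    right_strand: str
    inter_scaffold: bool = False

    @property
    def fragment(self) -> int:
        """Span between the two 5' ends (left mate start to right mate end)."""
        return self.right_end - self.left_start

    @property
    def fr_oriented(self) -> bool:
        return self.left_strand == "+" and self.right_strand == "-"


def classify_pair(pair: Pair, lib: LibraryModel,
                  sd_mult: float = DEFAULT.sd_mult_discordant) -> str:
    """'concordant' or 'discordant'.

    Discordant: mates on different scaffolds, orientation not inward FR,
    or |fragment - mu| strictly greater than sd_mult * sigma.
    """
    if pair.inter_scaffold:
        return "discordant"
    if not pair.fr_oriented:
        return "discordant"
    if abs(pair.fragment - lib.mu) > sd_mult * lib.sigma:
        return "discordant"
    return "concordant"


class PairSet:
    """Array-backed pair features for one scaffold.

    A pair's fragment interval is [leftmost 5' end, rightmost 5' end);
    a pair is "in" a region iff that interval overlaps it.
    """

    def __init__(self, pairs: Sequence[Pair], lib: LibraryModel,
                 sd_mult: float = DEFAULT.sd_mult_discordant):
        self.f_start = np.array([p.left_start for p in pairs], dtype=np.int64)
        self.f_end = np.array([p.right_end for p in pairs], dtype=np.int64)
        self.l_end = np.array([p.left_end for p in pairs], dtype=np.int64)
        self.r_start = np.array([p.right_start for p in pairs], dtype=np.int64)
        self.fr = np.array([p.fr_oriented for p in pairs], dtype=bool)
        self.inter = np.array([p.inter_scaffold for p in pairs], dtype=bool)
        frag = (self.f_end - self.f_start).astype(np.float64)
        self.fragment = frag
        self.discordant = (self.inter | ~self.fr
                           | (np.abs(frag - lib.mu) > sd_mult * lib.sigma))

    def __len__(self) -> int:
        return self.f_start.size

    def overlapping(self, start: int, end: int) -> np.ndarray:
        return (self.f_start < end) & (self.f_end > start)


def discordant_ratio(pairs: PairSet, region: tuple[int, int],
                     window: int = DEFAULT.window_disc) -> float:
    """Discordant / all pairs in the region; for regions longer than
    ``window`` bp, the maximum ratio over consecutive window-sized
    sub-regions.  0 when no pairs are present."""
    start, end = region
    if end - start <= window:
        mask = pairs.overlapping(start, end)
        n = int(mask.sum())
        return float(pairs.discordant[mask].sum()) / n if n else 0.0
    best = 0.0
    for s in range(start, end, window):
        e = min(s + window, end)
        mask = pairs.overlapping(s, e)
        n = int(mask.sum())
        if n:
            best = max(best, float(pairs.discordant[mask].sum()) / n)
    return best


def spanning_fragments(pairs: PairSet, region: tuple[int, int],
                       min_span_pairs: int = DEFAULT.min_span_pairs,
                       ) -> tuple[Optional[float], int]:
    """Mean fragment size of FR pairs bridging the region (one mate
    entirely left of M_L, the other entirely right of M_R).

    Returns (mean, count); mean is None below ``min_span_pairs`` because
    an average of fewer fragments is too unstable to test against.
    """
    m_l, m_r = region
    mask = pairs.fr & ~pairs.inter & (pairs.l_end <= m_l) & (pairs.r_start >= m_r)
    count = int(mask.sum())
    if count < min_span_pairs:
        return None, count
    return float(pairs.fragment[mask].mean()), count


def estimate_library(fragments: Sequence[float] | np.ndarray,
                     min_pairs: int = DEFAULT.min_lib_pairs,
                     given: Optional[tuple[float, float]] = None) -> LibraryModel:
    """Robust insert-size mean/sd from FR-pair fragment sizes.

    Fragments outside [1, 5 x median] are discarded before taking the
    mean and sd.  If (mu, sigma) are supplied they are returned verbatim
    with source='given'.
    """
    if given is not None:
        return LibraryModel(mu=float(given[0]), sigma=float(given[1]), source="given")
    frags = np.asarray(fragments, dtype=np.float64)
    if frags.size < min_pairs:
        raise ValueError(
            f"only {frags.size} FR pairs available (< {min_pairs}); "
            "supply the library insert mean/sd explicitly"
        )
    med = np.median(frags)
    keep = frags[(frags >= 1) & (frags <= 5 * med)]
    return LibraryModel(mu=float(keep.mean()), sigma=float(keep.std(ddof=1)),
                        source="estimated")


# ---------------------------------------------------------------------------
# per-scaffold evidence assembly
# ---------------------------------------------------------------------------

def pair_up(reads: Sequence[ReadAlignment]) -> tuple[dict[str, list[Pair]], list[float]]:
    """Group primary alignments into per-scaffold Pair lists.

    Returns (pairs by scaffold of the leftmost mate, FR fragment sizes
    for library estimation).  Mates on different scaffolds yield an
    inter-scaffold Pair registered on both scaffolds, with the local
    read standing in for the fragment interval.
    """
    by_read: dict[str, dict[int, ReadAlignment]] = {}
    for r in reads:
        by_read.setdefault(r.read_id, {})[r.mate_index] = r
    pairs: dict[str, list[Pair]] = {}
    fr_fragments: list[float] = []
    for mates in by_read.values():
        if len(mates) != 2:
            continue
        a, b = mates[1], mates[2]
        if a.scaffold_id == b.scaffold_id:
            left, right = (a, b) if a.pos <= b.pos else (b, a)
            pair = Pair(left.pos, left.end, right.pos, right.end,
                        left.strand, right.strand)
            pairs.setdefault(a.scaffold_id, []).append(pair)
            if pair.fr_oriented:
                fr_fragments.append(float(pair.fragment))
        else:
            for local in (a, b):
                pairs.setdefault(local.scaffold_id, []).append(Pair(
                    local.pos, local.end, local.pos, local.end,
                    local.strand, local.strand, inter_scaffold=True,
                ))
    return pairs, fr_fragments


@dataclass(frozen=True)
class EvidenceTracks:
    """Per-scaffold browser tracks mirroring the five evidence panels."""

    depth: np.ndarray
    disagreement_mask: np.ndarray
    zero_mask: np.ndarray
    multi_ratio_500: np.ndarray
    discordant_ratio_500: np.ndarray
    scaffold_len: int


class ScaffoldEvidence:
    """All read evidence for one scaffold, ready for region queries."""

    def __init__(self, scaffold: SequenceRecord, reads: Sequence[ReadAlignment],
                 pairs: Sequence[Pair], lib: LibraryModel, cfg: Config = DEFAULT):
        self.scaffold = scaffold
        self.cfg = cfg
        self.lib = lib
        self.pileup = build_pileup(reads, scaffold)
        self.reads = ReadSet(reads)
        self.pairs = PairSet(pairs, lib, cfg.sd_mult_discordant)
        self.disagreement_positions = call_disagreements(
            self.pileup, cfg.majority_frac, cfg.min_depth)
        self.scaffold_codes = dna.encode(scaffold.sequence)
        self.n_mask = dna.n_run_mask(scaffold.sequence, cfg.gap_run_min)

    def bundle(self, region: tuple[int, int]) -> EvidenceBundle:
        cfg = self.cfg
        start, end = region
        length = max(1, end - start)
        dis = self.disagreement_positions
        n_dis = int(((dis >= start) & (dis < end)).sum())
        high, low, zero = coverage_flags(
            self.pileup, region, scaffold_seq=self.scaffold.sequence,
            mode="single_cell" if cfg.single_cell else "standard",
            window=cfg.window_cov, anomaly_windows=cfg.anomaly_windows,
            flank=self.reads.median_len,
            high_fold=cfg.cov_high_fold, low_fold=cfg.cov_low_fold,
            sc_sd_mult=cfg.sc_sd_mult, gap_run_min=cfg.gap_run_min,
        )
        m_ratio, n_reads = multi_align_ratio(self.reads, region)
        d_ratio = discordant_ratio(self.pairs, region, cfg.window_disc)
        span_mean, span_count = spanning_fragments(self.pairs, region,
                                                   cfg.min_span_pairs)
        end_support = bool((self.pairs.fr & self.pairs.overlapping(start, end)).any())
        return EvidenceBundle(
            n_disagreements=n_dis,
            disagreements_per_kbp=n_dis / (length / 1000.0),
            has_high_cov=high, has_low_cov=low, has_zero_cov=zero,
            multi_align_ratio=m_ratio, discordant_ratio=d_ratio,
            span_frag_mean=span_mean, span_pair_count=span_count,
            n_reads=n_reads, end_paired_support=end_support,
        )

    def majority_base_code(self, i: int) -> int:
        """Pileup majority base at column i (4 when depth is zero)."""
        c = self.pileup.counts[i]
        if c.sum() == 0:
            return 4
        return int(c.argmax())

    def tracks(self) -> EvidenceTracks:
        L = len(self.scaffold)
        depth = self.pileup.depth
        dis_mask = np.zeros(L, dtype=bool)
        dis_mask[self.disagreement_positions] = True
        zero_mask = (depth == 0) & ~self.n_mask
        n_bins = (L + 499) // 500
        multi_r = np.zeros(n_bins)
        disc_r = np.zeros(n_bins)
        for b in range(n_bins):
            s, e = b * 500, min((b + 1) * 500, L)
            multi_r[b], _ = multi_align_ratio(self.reads, (s, e))
            disc_r[b] = discordant_ratio(self.pairs, (s, e))
        return EvidenceTracks(depth, dis_mask, zero_mask, multi_r, disc_r, L)
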