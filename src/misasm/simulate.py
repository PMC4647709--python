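"""Synthetic scenarios: genome, mis-assembled scaffolds, SV-mutated
reference, paired-end reads, truth tables, and naive aligners.

The generator builds fully specified desk-scale analogues of the
evaluation setting the method targets: a random bacterial-scale genome;
scaffolds carrying injected assembly errors (repeat-mediated misjoins,
middle/end insertions, deletions); a reference derived from the same
genome by structural-variation edits (duplication, relocation,
insertions, deletions), so that differences on *correctly* assembled
scaffolds reflect SVs, not errors; and paired-end reads drawn from the
true genome with Gaussian insert sizes and a uniform substitution error
rate.  Reads always come from the true genome, so scaffold errors
manifest as coverage anomalies, disagreements and discordant pairs.

Misjoins are engineered the way they arise in practice: the genome
carries two copies of a repeat, and the misjoined scaffold glues the
sequence upstream of copy 1 to the sequence downstream of copy 2
through the shared repeat, so multi-aligned reads genuinely accumulate
at the junction.

Everything is a pure function of (spec, seed).  The two naive aligners
(exact k-mer anchoring with collinear chaining for scaffolds; seeded
mismatch-bounded placement for reads) keep the whole pipeline hermetic
at desk scale; synthetic sequences share exact k-mers outside the
engineered difference loci, which is all they rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import dna
from .config import DEFAULT
from .correct import TruthRecord
from .io_formats import AlignSegment, ReadAlignment, SequenceRecord


# ---------------------------------------------------------------------------
# scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    """One injected assembly error.

    kinds: 'misjoin' (uses repeat_len), 'insertion_mid', 'insertion_end',
    'deletion' (use size).
    """

    kind: str
    size: int = 0
    repeat_len: int = 500

    def __post_init__(self):
        if self.kind not in ("misjoin", "insertion_mid", "insertion_end", "deletion"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.kind != "misjoin" and self.size < 1:
            raise ValueError("indel errors need size >= 1")


@dataclass(frozen=True)
class SvSpec:
    """One structural variation introduced into the reference."""

    kind: str
    size: int

    def __post_init__(self):
        if self.kind not in ("duplication", "relocation", "insertion", "deletion"):
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("SV size must be >= 1")


@dataclass(frozen=True)
class ScenarioSpec:
    genome_len: int = 1_000_000
    gc_frac: float = 0.5
    errors: tuple[ErrorSpec, ...] = ()
    svs: tuple[SvSpec, ...] = ()
    depth: float = 50.0
    read_len: int = 100
    insert_mu: float = 368.0
    insert_sd: float = 61.0
    base_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.genome_len < 1:
            raise ValueError("genome_len must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def six_sv_preset(relocation_size: int = 20_000) -> tuple[SvSpec, ...]:
    """The six-modification SV design: one duplication (1 kbp), one large
    relocation, two insertions (70/30 bp) and two deletions (70/30 bp)."""
    return (
        SvSpec("duplication", 1000),
        SvSpec("relocation", relocation_size),
        SvSpec("insertion", 70),
        SvSpec("insertion", 30),
        SvSpec("deletion", 70),
        SvSpec("deletion", 30),
    )


def ecoli_like_errors() -> tuple[ErrorSpec, ...]:
    """27 injected errors (3 misjoins, 20 insertions, 4 deletions).

    Sizes reflect how these errors arise: expanded repeats (middle
    insertions of a few hundred bp), unsupported scaffold ends (one to
    a few read lengths) and collapsed repeat units (deletions of tens
    to a couple hundred bp, small enough that read pairs still bridge
    the missing sequence and carry a fragment-size signal)."""
    mids = [250, 300, 350, 400, 450, 500, 550, 600, 275, 325, 375, 425]
    ends = [150, 200, 250, 300, 350, 400, 450, 500]
    dels = [130, 160, 200, 240]
    return tuple(
        [ErrorSpec("misjoin", repeat_len=500)] * 3
        + [ErrorSpec("insertion_mid", s) for s in mids]
        + [ErrorSpec("insertion_end", s) for s in ends]
        + [ErrorSpec("deletion", s) for s in dels]
    )


def ecoli_like_scenario(seed: int = 0, genome_len: int = 1_000_000,
                        errors: Optional[tuple[ErrorSpec, ...]] = None,
                        svs: Optional[tuple[SvSpec, ...]] = None) -> ScenarioSpec:
    """Scaled-down analogue of a 50x bacterial resequencing experiment."""
    return ScenarioSpec(
        genome_len=genome_len, gc_frac=0.5,
        errors=ecoli_like_errors() if errors is None else errors,
        svs=six_sv_preset() if svs is None else svs,
        depth=50.0, read_len=100, insert_mu=368.0, insert_sd=61.0,
        base_error_rate=0.005, seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic window layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Layout:
    """Deterministic partition of the genome into equal windows, one per
    scaffold, with misjoins consuming a (front, back) window pair."""

    win: int
    n_windows: int
    misjoin_pairs: tuple[tuple[int, int], ...]
    other_windows: tuple[int, ...]   # parallel to the non-misjoin errors
    sv_windows: tuple[tuple[int, ...], ...]  # parallel to svs; relocation has 2
    spare_windows: tuple[int, ...]

    def span(self, w: int) -> tuple[int, int]:
        return w * self.win, (w + 1) * self.win


def _layout(spec: ScenarioSpec) -> _Layout:
    misjoins = [e for e in spec.errors if e.kind == "misjoin"]
    others = [e for e in spec.errors if e.kind != "misjoin"]
    sv_need = [2 if sv.kind == "relocation" else 1 for sv in spec.svs]
    n_spare = 2
    W = 2 * len(misjoins) + len(others) + sum(sv_need) + n_spare
    W = max(W, 1)
    win = spec.genome_len // W
    # capacity checks so every feature fits inside its window with margins
    for e in misjoins:
        if int(0.4 * win) < e.repeat_len + 1000:
            raise ValueError("genome too small for the requested misjoin repeats")
    for e in others:
        if e.size * 2 + 2000 > win:
            raise ValueError(f"genome too small for a {e.size}-bp {e.kind}")
    for sv in spec.svs:
        need = sv.size + 2000 if sv.kind != "relocation" else sv.size + 2000
        if need > win:
            raise ValueError(f"genome too small for a {sv.size}-bp {sv.kind}")

    pairs = tuple((i, W - 1 - i) for i in range(len(misjoins)))
    cursor = len(misjoins)
    other_windows = tuple(range(cursor, cursor + len(others)))
    cursor += len(others)
    sv_windows = []
    for need in sv_need:
        sv_windows.append(tuple(range(cursor, cursor + need)))
        cursor += need
    spare = tuple(range(cursor, W - len(misjoins)))
    return _Layout(win, W, pairs, other_windows, tuple(sv_windows), spare)


def _repeat_loci(spec: ScenarioSpec, lay: _Layout) -> list[tuple[int, int, int]]:
    """(copy1_start, copy2_start, repeat_len) per misjoin, in genome coords."""
    misjoins = [e for e in spec.errors if e.kind == "misjoin"]
    loci = []
    for (wa, wb), e in zip(lay.misjoin_pairs, misjoins):
        a_s, _ = lay.span(wa)
        b_s, _ = lay.span(wb)
        h_a = int(0.7 * lay.win)
        h_b = int(0.4 * lay.win)
        loci.append((a_s + h_a - e.repeat_len, b_s + h_b - e.repeat_len, e.repeat_len))
    return loci


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rng(spec: ScenarioSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _random_codes(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _deletion_loci(spec: ScenarioSpec, lay: _Layout) -> list[tuple[int, int]]:
    """(second_copy_start, size) of the tandem repeat behind each
    deletion error, in genome coordinates."""
    others = [e for e in spec.errors if e.kind != "misjoin"]
    loci = []
    for w, e in zip(lay.other_windows, others):
        if e.kind == "deletion":
            w_s, _ = lay.span(w)
            loci.append((w_s + lay.win // 2, e.size))
    return loci


def generate_genome(spec: ScenarioSpec) -> SequenceRecord:
    """The true target genome: i.i.d. bases at the stated GC fraction,
    plus the repeat structure the injected errors rely on.  Misjoins
    need an exact two-copy interspersed repeat (the join template);
    deletion errors need a slightly diverged tandem duplication, since
    they arise by collapsing such repeats -- the divergence between
    copies (about 2%) is what later shows up as pileup disagreements
    when reads from both copies stack on the collapsed scaffold copy.
    Deterministic per seed."""
    rng = _rng(spec, 0)
    codes = _random_codes(spec.genome_len, spec.gc_frac, rng)
    lay = _layout(spec)
    for c1, c2, r in _repeat_loci(spec, lay):
        codes[c2:c2 + r] = codes[c1:c1 + r]
    for p, z in _deletion_loci(spec, lay):
        copy = codes[p - z:p].copy()
        n_div = max(2, z // 50)
        sites = rng.choice(z, size=n_div, replace=False)
        copy[sites] = (copy[sites] + rng.integers(1, 4, size=n_div)) % 4
        codes[p:p + z] = copy
    return SequenceRecord("genome", dna.decode(codes))


def inject_assembly_errors(genome: SequenceRecord, spec: ScenarioSpec,
                           ) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Cut the genome into window scaffolds and inject the spec's errors.

    Misjoins glue the sequence ending at repeat copy 1 to the sequence
    following repeat copy 2 (the classic collapsed-repeat join); the
    window half preceding copy 2 becomes a separate correct scaffold so
    the repeat stays two-copy in the assembly and multi-aligned reads
    occur at the junction.  Each other error sits at the centre (or
    end) of its own window scaffold.  SV and spare windows come out as
    error-free scaffolds.  The truth table carries exact scaffold
    coordinates of every injected error.
    """
    lay = _layout(spec)
    rng = _rng(spec, 1)
    seq = genome.sequence
    misjoins = [e for e in spec.errors if e.kind == "misjoin"]
    others = [e for e in spec.errors if e.kind != "misjoin"]
    scaffolds: list[SequenceRecord] = []
    truth: list[TruthRecord] = []

    for i, ((wa, wb), (c1, c2, r)) in enumerate(
            zip(lay.misjoin_pairs, _repeat_loci(spec, lay))):
        a_s, _ = lay.span(wa)
        b_s, b_e = lay.span(wb)
        part_a = seq[a_s:c1 + r]          # ends with repeat copy 1
        part_b = seq[c2 + r:b_e]          # continuation after copy 2
        name = f"scf_mis{i}"
        scaffolds.append(SequenceRecord(name, part_a + part_b))
        truth.append(TruthRecord(name, "misjoin",
                                 len(part_a) - r, len(part_a), r, "error"))
        # correct partner scaffold ending with repeat copy 2
        scaffolds.append(SequenceRecord(f"scf_w{wb}", seq[b_s:c2 + r]))

    for w, e in zip(lay.other_windows, others):
        w_s, w_e = lay.span(w)
        base = seq[w_s:w_e]
        name = f"scf_w{w}"
        if e.kind == "insertion_mid":
            p = len(base) // 2
            ins = dna.decode(_random_codes(e.size, spec.gc_frac, rng))
            scaffolds.append(SequenceRecord(name, base[:p] + ins + base[p:]))
            truth.append(TruthRecord(name, "insertion", p, p + e.size, e.size, "error"))
        elif e.kind == "insertion_end":
            ins = dna.decode(_random_codes(e.size, spec.gc_frac, rng))
            if w % 2 == 0:  # alternate 3' and 5' ends
                scaffolds.append(SequenceRecord(name, base + ins))
                truth.append(TruthRecord(name, "insertion",
                                         len(base), len(base) + e.size, e.size, "error"))
            else:
                scaffolds.append(SequenceRecord(name, ins + base))
                truth.append(TruthRecord(name, "insertion", 0, e.size, e.size, "error"))
        else:  # deletion
            p = len(base) // 2
            scaffolds.append(SequenceRecord(name, base[:p] + base[p + e.size:]))
            truth.append(TruthRecord(name, "deletion", p, p, e.size, "error"))

    for w in [w for ws in lay.sv_windows for w in ws] + list(lay.spare_windows):
        w_s, w_e = lay.span(w)
        scaffolds.append(SequenceRecord(f"scf_w{w}", seq[w_s:w_e]))
    return scaffolds, truth


def inject_svs(genome: SequenceRecord, spec: ScenarioSpec,
               misjoin_distance: int = DEFAULT.misjoin_distance,
               ) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Derive the reference by applying the spec's SV edits to the genome.

    The truth table enumerates the *expected difference loci on the
    scaffolds*: a duplication in the reference shows up as one
    deletion-type difference; a relocation produces three junction
    differences (two at the source locus, one at the target); an
    insertion/deletion in the reference appears as a deletion/insertion
    -type difference of the same size.  Truth kinds account for
    ``misjoin_distance``: reference jumps beyond it classify as
    misjoins.
    """
    lay = _layout(spec)
    rng = _rng(spec, 2)
    codes = dna.encode(genome.sequence)
    edits: list[tuple[int, str, object]] = []  # (genome pos, op, payload)
    truth: list[TruthRecord] = []

    for sv, ws in zip(spec.svs, lay.sv_windows):
        if sv.kind == "duplication":
            w_s, _ = lay.span(ws[0])
            p = w_s + lay.win // 2
            edits.append((p, "ins", codes[p - sv.size:p].copy()))
            name = f"scf_w{ws[0]}"
            truth.append(TruthRecord(
                name, "misjoin" if sv.size > misjoin_distance else "deletion",
                p - sv.size - w_s, p - w_s, sv.size, "sv"))
        elif sv.kind == "insertion":
            w_s, _ = lay.span(ws[0])
            p = w_s + lay.win // 2
            edits.append((p, "ins", _random_codes(sv.size, spec.gc_frac, rng)))
            name = f"scf_w{ws[0]}"
            truth.append(TruthRecord(
                name, "misjoin" if sv.size > misjoin_distance else "deletion",
                p - w_s, p - w_s, sv.size, "sv"))
        elif sv.kind == "deletion":
            w_s, _ = lay.span(ws[0])
            p = w_s + lay.win // 2 - sv.size // 2
            edits.append((p, "del", sv.size))
            name = f"scf_w{ws[0]}"
            truth.append(TruthRecord(
                name, "misjoin" if sv.size > misjoin_distance else "insertion",
                p - w_s, p - w_s + sv.size, sv.size, "sv"))
        else:  # relocation: move a segment from window X to window Y
            wx, wy = ws
            x_s, x_e = lay.span(wx)
            margin = max(1000, (lay.win - sv.size) // 2)
            x0 = x_s + min(margin, lay.win - sv.size - 1000)
            y_s, _ = lay.span(wy)
            y = y_s + lay.win // 2
            seg = codes[x0:x0 + sv.size].copy()
            edits.append((x0, "del", sv.size))
            edits.append((y, "ins", seg))
            x_name, y_name = f"scf_w{wx}", f"scf_w{wy}"
            jump = abs(y - x0)
            x_kind = "misjoin" if jump > misjoin_distance else "deletion"
            truth.append(TruthRecord(x_name, x_kind,
                                     x0 - x_s, x0 - x_s, sv.size, "sv"))
            truth.append(TruthRecord(x_name, x_kind,
                                     x0 + sv.size - x_s, x0 + sv.size - x_s, sv.size, "sv"))
            truth.append(TruthRecord(
                y_name, "misjoin" if sv.size > misjoin_distance else "deletion",
                y - y_s, y - y_s, sv.size, "sv"))

    positions = [p for p, _, _ in edits]
    if len(set(positions)) != len(positions):
        raise ValueError("SV edit positions overlap")
    pieces = codes
    for p, op, payload in sorted(edits, key=lambda e: -e[0]):
        if op == "ins":
            pieces = np.concatenate([pieces[:p], payload, pieces[p:]])
        else:
            pieces = np.concatenate([pieces[:p], pieces[p + payload:]])
    return SequenceRecord("ref", dna.decode(pieces)), truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedReads:
    """Paired reads as uint8 code arrays plus their true placements."""

    reads1: np.ndarray   # (n, read_len)
    reads2: np.ndarray
    starts: np.ndarray   # fragment start on the genome
    fragments: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.reads1.shape[0]

    def sequences(self) -> tuple[list[str], list[str]]:
        r1 = [dna.decode(row) for row in self.reads1]
        r2 = [dna.decode(row) for row in self.reads2]
        return r1, r2


def simulate_reads(genome: SequenceRecord, spec: ScenarioSpec) -> SimulatedReads:
    """FR paired reads with Gaussian insert sizes from the true genome.

    Pair count = round(depth * genome / (2 * read_len)); fragment sizes
    are rounded normals floored at read_len; starts are uniform;
    substitution errors are symmetric at base_error_rate.  Mate 1 is the
    forward (left) read, mate 2 the reverse-complemented right read.
    """
    rng = _rng(spec, 3)
    G, L = len(genome), spec.read_len
    if G < L:
        raise ValueError("genome shorter than the read length")
    n = int(round(spec.depth * G / (2 * L)))
    if n < 1:
        raise ValueError("requested depth yields zero read pairs")
    codes = dna.encode(genome.sequence)
    frags = np.clip(np.rint(rng.normal(spec.insert_mu, spec.insert_sd, n)),
                    L, G).astype(np.int64)
    starts = rng.integers(0, G - frags + 1)
    offsets = np.arange(L)
    r1 = codes[starts[:, None] + offsets]
    r2_fwd = codes[(starts + frags - L)[:, None] + offsets]
    r2 = (3 - r2_fwd)[:, ::-1].copy()  # reverse complement
    if spec.base_error_rate > 0:
        for arr in (r1, r2):
            hits = rng.random(arr.shape) < spec.base_error_rate
            shift = rng.integers(1, 4, size=int(hits.sum()), dtype=np.uint8)
            arr[hits] = (arr[hits] + shift) % 4
    return SimulatedReads(r1.astype(np.uint8), r2.astype(np.uint8), starts, frags)


# ---------------------------------------------------------------------------
# naive long-sequence aligner (k-mer anchors, collinear chaining)
# ---------------------------------------------------------------------------

_AMBIG = (-1, -1)


def _reference_index(references: Sequence[SequenceRecord], k: int) -> dict:
    index: dict[bytes, tuple[int, int]] = {}
    for ri, ref in enumerate(references):
        b = ref.sequence.encode()
        for i in range(len(b) - k + 1):
            km = b[i:i + k]
            if b"N" in km:
                continue
            if km in index:
                index[km] = _AMBIG
            else:
                index[km] = (ri, i)
    return index


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _xdrop_walk(pairs_iter, match: int = 1, mismatch: int = 3,
                xdrop: int = 12) -> int:
    """Number of steps to the best-scoring prefix of a base-pair walk,
    stopping once the score falls ``xdrop`` below its maximum (the
    classic gapless X-drop extension)."""
    score = best = best_i = 0
    for i, (a, b) in enumerate(pairs_iter, start=1):
        score += match if a == b else -mismatch
        if score > best:
            best, best_i = score, i
        if score <= best - xdrop:
            break
    return best_i


def _extend_segment(seg: AlignSegment, scaf: str, ref: str) -> AlignSegment:
    """X-drop extension of a segment in both directions, the way a
    long-sequence aligner extends through repeats (including slightly
    diverged copies) that unique-k-mer anchoring cannot enter."""
    s_start, s_end, r_start, r_end = seg.s_start, seg.s_end, seg.r_start, seg.r_end
    if seg.strand == "+":
        n = _xdrop_walk(zip(scaf[s_end:], ref[r_end:]))
        s_end += n
        r_end += n
        n = _xdrop_walk(zip(scaf[s_start - 1::-1] if s_start else "",
                            ref[r_start - 1::-1] if r_start else ""))
        s_start -= n
        r_start -= n
    else:
        n = _xdrop_walk((a, _COMP[b]) for a, b in
                        zip(scaf[s_end:], ref[r_start - 1::-1] if r_start else ""))
        s_end += n
        r_start -= n
        n = _xdrop_walk((a, _COMP[b]) for a, b in
                        zip(scaf[s_start - 1::-1] if s_start else "", ref[r_end:]))
        s_start -= n
        r_end += n
    if (s_start, s_end, r_start, r_end) == (seg.s_start, seg.s_end, seg.r_start, seg.r_end):
        return seg
    from dataclasses import replace
    return replace(seg, s_start=s_start, s_end=s_end, r_start=r_start,
                   r_end=r_end, score=float(s_end - s_start))


def naive_align_long(scaffolds: Sequence[SequenceRecord],
                     references: Sequence[SequenceRecord],
                     k: int = 31,
                     max_anchor_gap: int = 10_000) -> list[AlignSegment]:
    """Exact-k-mer anchor chaining of scaffolds onto references.

    Unique k-mer matches (forward and reverse-complement) become
    anchors; maximal runs of anchors on one diagonal, one strand and one
    reference, with anchor gaps at most ``max_anchor_gap``, merge into
    segments scored by their scaffold length.  Repeated k-mers are
    ambiguous and contribute no anchors, so alignments break at every
    engineered difference; segments are then extended by exact matching
    so that, like a real long-sequence aligner, they run through
    two-copy repeats instead of stopping at their borders (misjoined
    segments therefore overlap across their shared repeat).
    """
    index = _reference_index(references, k)
    segments: list[AlignSegment] = []
    for scaf in scaffolds:
        s = scaf.sequence.encode()
        Ls = len(s)
        if Ls < k:
            continue
        rc = dna.revcomp(scaf.sequence).encode()
        anchors: list[tuple[int, int, int, str]] = []
        for i in range(Ls - k + 1):
            hit = index.get(s[i:i + k])
            if hit is None:
                hit = index.get(rc[Ls - k - i:Ls - i])
                if hit is not None and hit is not _AMBIG:
                    anchors.append((i, hit[0], hit[1], "-"))
                continue
            if hit is not _AMBIG:
                anchors.append((i, hit[0], hit[1], "+"))

        def close_run(run: list[tuple[int, int, int, str]]):
            i0, ri, r0, strand = run[0]
            i1, _, r1, _ = run[-1]
            if strand == "+":
                r_start, r_end = r0, r1 + k
            else:
                r_start, r_end = r1, r0 + k
            segments.append(AlignSegment(
                scaffold_id=scaf.id, ref_id=references[ri].id,
                s_start=i0, s_end=i1 + k, r_start=r_start, r_end=r_end,
                strand=strand, score=float(i1 + k - i0),
            ))

        run: list[tuple[int, int, int, str]] = []
        for a in anchors:
            if run:
                pi, pri, pr, ps = run[-1]
                same_diag = (a[2] - a[0] == pr - pi) if a[3] == "+" else (a[2] + a[0] == pr + pi)
                if (a[1] == pri and a[3] == ps and same_diag
                        and a[0] - pi <= max_anchor_gap):
                    run.append(a)
                    continue
                close_run(run)
            run = [a]
        if run:
            close_run(run)
    extended = []
    for seg in segments:
        scaf = next(s for s in scaffolds if s.id == seg.scaffold_id)
        ref = next(r for r in references if r.id == seg.ref_id)
        extended.append(_extend_segment(seg, scaf.sequence, ref.sequence))
    return extended


# ---------------------------------------------------------------------------
# naive short-read aligner (seeded, mismatch-bounded)
# ---------------------------------------------------------------------------

class _ScaffoldIndex:
    """Concatenated scaffold codes with a seed k-mer index."""

    SEP = 5  # separator code: matches nothing

    def __init__(self, scaffolds: Sequence[SequenceRecord], read_len: int,
                 max_mismatch: int):
        self.scaffolds = scaffolds
        self.k = max(8, read_len // (max_mismatch + 1))
        self.offsets = list(range(0, read_len - self.k + 1,
                                  self.k))[: max_mismatch + 1]
        sep = np.full(8, self.SEP, dtype=np.uint8)
        chunks, spans = [], []
        pos = 0
        for s in scaffolds:
            codes = dna.encode(s.sequence)
            spans.append((pos, pos + len(codes)))
            chunks.append(codes)
            chunks.append(sep)
            pos += len(codes) + sep.size
        self.concat = np.concatenate(chunks) if chunks else np.empty(0, np.uint8)
        self.spans = spans
        self.span_starts = np.array([s for s, _ in spans], dtype=np.int64)
        cb = self.concat.tobytes()
        self.bytes = cb
        index: dict[bytes, list[int]] = {}
        k = self.k
        for i in range(len(cb) - k + 1):
            km = cb[i:i + k]
            if max(km) >= 4:
                continue
            index.setdefault(km, []).append(i)
        self.index = index

    def locate(self, p: int, length: int) -> Optional[tuple[int, int]]:
        """Concat position -> (scaffold index, local position), or None if
        the interval crosses a scaffold boundary."""
        si = int(np.searchsorted(self.span_starts, p, side="right")) - 1
        if si < 0:
            return None
        s, e = self.spans[si]
        if p + length <= e:
            return si, p - s
        return None


def naive_align_reads(sim: SimulatedReads,
                      scaffolds: Sequence[SequenceRecord],
                      max_mismatch: int = 3,
                      min_clip_len: int = 30,
                      seed: int = 0,
                      name_prefix: str = "pair") -> list[ReadAlignment]:
    """Place simulated pairs on scaffolds; equal-best multi-placements
    pick one primary uniformly at random (seeded, so correct regions
    keep coverage) and set is_multi; proper-pair mate fields are filled
    for pairs with both mates placed.

    Seeds at max_mismatch+1 read offsets guarantee (pigeonhole) that any
    full-length placement with at most max_mismatch mismatches is
    found.  Reads with no full-length placement (typically those
    crossing an indel junction) fall back to soft-clipped placement:
    the longest read prefix or suffix of at least ``min_clip_len``
    bases within the mismatch budget, as short-read aligners clip reads
    across breakpoints.
    """
    L = sim.reads1.shape[1]
    idx = _ScaffoldIndex(scaffolds, L, max_mismatch)
    rng = np.random.default_rng([seed, 17])
    concat = idx.concat
    index = idx.index
    offsets = idx.offsets
    k = idx.k

    def candidates(rb: bytes) -> set[int]:
        cand: set[int] = set()
        for off in offsets:
            for p in index.get(rb[off:off + k], ()):
                cand.add(p - off)
        return cand

    def place(codes_fwd: np.ndarray) -> list[tuple[int, str, int, int]]:
        """Equal-best placements as (concat_pos, strand, read_off, aligned_len)."""
        best_mm = max_mismatch + 1
        best: list[tuple[int, str]] = []
        strands = (("+", codes_fwd), ("-", dna.revcomp_codes(codes_fwd)))
        cand_cache: list[tuple[str, np.ndarray, set[int]]] = []
        for strand, codes in strands:
            cand = candidates(codes.tobytes())
            cand_cache.append((strand, codes, cand))
            for p in cand:
                if p < 0 or p + L > concat.size:
                    continue
                mm = int(np.count_nonzero(concat[p:p + L] != codes))
                if mm < best_mm:
                    best_mm = mm
                    best = [(p, strand)]
                elif mm == best_mm:
                    best.append((p, strand))
        if best_mm <= max_mismatch:
            return [(p, s, 0, L) for p, s in best]
        # soft-clipped fallback
        best_len = min_clip_len - 1
        clipped: list[tuple[int, str, int, int]] = []
        for strand, codes, cand in cand_cache:
            for p in cand:
                if p < 0 or p + L > concat.size:
                    continue
                mism = concat[p:p + L] != codes
                cum = np.cumsum(mism)
                n_pre = int(np.searchsorted(cum, max_mismatch, side="right"))
                cum_r = np.cumsum(mism[::-1])
                n_suf = int(np.searchsorted(cum_r, max_mismatch, side="right"))
                for q_off, n in ((0, n_pre), (L - n_suf, n_suf)):
                    if n > best_len:
                        best_len = n
                        clipped = [(p + q_off, strand, q_off, n)]
                    elif n == best_len:
                        entry = (p + q_off, strand, q_off, n)
                        if entry not in clipped:
                            clipped.append(entry)
        return clipped

    alignments: list[ReadAlignment] = []
    for i in range(sim.n_pairs):
        placements = {}
        for mate, codes in ((1, sim.reads1[i]), (2, sim.reads2[i])):
            hits = [h for h in place(codes)
                    if idx.locate(h[0], h[3]) is not None]
            if not hits:
                continue
            pick = hits[rng.integers(len(hits))] if len(hits) > 1 else hits[0]
            p_aln, strand, q_off, n = pick
            si, local = idx.locate(p_aln, n)
            oriented = codes if strand == "+" else dna.revcomp_codes(codes)
            seq = dna.decode(oriented[q_off:q_off + n])
            placements[mate] = (si, local, local + n, strand, len(hits) > 1, seq)
        for mate, (si, start, end, strand, multi, seq) in placements.items():
            other = placements.get(2 if mate == 1 else 1)
            alignments.append(ReadAlignment(
                read_id=f"{name_prefix}{i}",
                mate_index=mate,
                scaffold_id=scaffolds[si].id,
                pos=start, end=end, strand=strand,
                is_multi=multi, seq=seq,
                mate_scaffold=scaffolds[other[0]].id if other else None,
                mate_pos=other[1] if other else None,
                mate_strand=other[3] if other else None,
            ))
    return alignments


# ---------------------------------------------------------------------------
# whole-scenario convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    spec: ScenarioSpec
    genome: SequenceRecord
    scaffolds: list[SequenceRecord]
    reference: SequenceRecord
    truth: list[TruthRecord]


def build_scenario(spec: ScenarioSpec,
                   misjoin_distance: int = DEFAULT.misjoin_distance) -> Scenario:
    """Genome + error scaffolds + SV reference + combined truth table."""
    genome = generate_genome(spec)
    scaffolds, err_truth = inject_assembly_errors(genome, spec)
    reference, sv_truth = inject_svs(genome, spec, misjoin_distance)
    return Scenario(spec, genome, scaffolds, reference, err_truth + sv_truth)
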