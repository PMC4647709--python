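"""Standard-format I/O and the internal coordinate convention.

Everything inside the package uses 0-based half-open intervals on the
forward strand of the named sequence; conversion from the dialects that
do otherwise (BLAST outfmt 6 is 1-based inclusive with a possibly
reversed subject interval) happens here and only here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from . import dna


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (scaffold, contig or reference replicon)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignSegment:
    """One scaffold-to-reference alignment block.

    ``s_*`` are scaffold coordinates, ``r_*`` reference coordinates on
    the forward reference strand; ``strand`` records which reference
    strand the scaffold interval matches.
    """

    scaffold_id: str
    ref_id: str
    s_start: int
    s_end: int
    r_start: int
    r_end: int
    strand: str  # "+" or "-"
    score: float
    identity_pct: float = 100.0
    n_mismatch: int = 0
    n_gap: int = 0

    def __post_init__(self):
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad scaffold interval [{self.s_start},{self.s_end})")
        if not (0 <= self.r_start < self.r_end):
            raise ValueError(f"bad reference interval [{self.r_start},{self.r_end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def s_len(self) -> int:
        return self.s_end - self.s_start


@dataclass(frozen=True)
class ReadAlignment:
    """A single aligned read (one mate of a pair, or an unpaired read).

    ``seq`` holds the aligned bases in scaffold-forward orientation, one
    character per reference position of the alignment (insertions to the
    scaffold dropped, deletions padded with N), so pileup construction is
    a straight columnwise count.  Mate fields are populated only when the
    mate's placement is resolved.
    """

    read_id: str
    mate_index: int  # 1 or 2
    scaffold_id: str
    pos: int
    end: int
    strand: str
    is_multi: bool = False
    seq: Optional[str] = None
    mate_scaffold: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_strand: Optional[str] = None

    def __post_init__(self):
        if not self.pos < self.end:
            raise ValueError("read alignment must have pos < end")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; uppercase, U->T, anything else outside ACGTN -> N.

    Raises FormatError for an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, dna.normalize(str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> Path:
    path = Path(path)
    bio = (_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")
    return path


def write_fastq_pair(
    reads1: Sequence[str], reads2: Sequence[str], path1: str | Path, path2: str | Path,
    name_prefix: str = "pair",
) -> tuple[Path, Path]:
    """Write paired reads as two plain FASTQ files with constant quality."""
    path1, path2 = Path(path1), Path(path2)
    for path, reads, mate in ((path1, reads1, 1), (path2, reads2, 2)):
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@{name_prefix}{i}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path1, path2


def read_fastq_pair(path1: str | Path, path2: str | Path) -> tuple[list[str], list[str]]:
    r1 = [dna.normalize(str(r.seq)) for r in SeqIO.parse(str(path1), "fastq")]
    r2 = [dna.normalize(str(r.seq)) for r in SeqIO.parse(str(path2), "fastq")]
    if len(r1) != len(r2):
        raise FormatError("paired FASTQ files have different read counts")
    return r1, r2


# ---------------------------------------------------------------------------
# tabular scaffold-to-reference alignments (BLAST outfmt 6 / PAF)
# ---------------------------------------------------------------------------

def read_alignments_tabular(path: str | Path, dialect: str = "blast6") -> list[AlignSegment]:
    """Parse BLAST tabular (12-column outfmt 6) or PAF into AlignSegments.

    blast6 coordinates are 1-based inclusive and the subject interval is
    reversed for minus-strand hits; both are converted to the internal
    0-based half-open forward-strand convention.  PAF is already 0-based
    half-open with an explicit strand column.
    """
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    segments: list[AlignSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "blast6":
                    segments.append(_parse_blast6(cols))
                else:
                    segments.append(_parse_paf(cols))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: malformed {dialect} row at line {lineno}: {exc}") from exc
    return segments


def _parse_blast6(cols: Sequence[str]) -> AlignSegment:
    if len(cols) < 12:
        raise ValueError(f"expected 12 columns, got {len(cols)}")
    qid, sid = cols[0], cols[1]
    pident = float(cols[2])
    mismatch, gapopen = int(cols[4]), int(cols[5])
    qstart, qend, sstart, send = (int(c) for c in cols[6:10])
    bitscore = float(cols[11])
    if sstart <= send:
        strand, r_start, r_end = "+", sstart - 1, send
    else:
        strand, r_start, r_end = "-", send - 1, sstart
    return AlignSegment(
        scaffold_id=qid, ref_id=sid,
        s_start=qstart - 1, s_end=qend,
        r_start=r_start, r_end=r_end,
        strand=strand, score=bitscore,
        identity_pct=pident, n_mismatch=mismatch, n_gap=gapopen,
    )


def _parse_paf(cols: Sequence[str]) -> AlignSegment:
    if len(cols) < 12:
        raise ValueError(f"expected >= 12 columns, got {len(cols)}")
    qid = cols[0]
    qstart, qend = int(cols[2]), int(cols[3])
    strand = cols[4]
    sid = cols[5]
    tstart, tend = int(cols[7]), int(cols[8])
    nmatch, alnlen = int(cols[9]), int(cols[10])
    ident = 100.0 * nmatch / alnlen if alnlen else 0.0
    return AlignSegment(
        scaffold_id=qid, ref_id=sid,
        s_start=qstart, s_end=qend,
        r_start=tstart, r_end=tend,
        strand=strand, score=float(nmatch),
        identity_pct=ident, n_mismatch=alnlen - nmatch,
    )


def segment_to_blast6(seg: AlignSegment) -> str:
    """Render a segment as a 12-column blast6 row (inverse of the parser)."""
    if seg.strand == "+":
        sstart, send = seg.r_start + 1, seg.r_end
    else:
        sstart, send = seg.r_end, seg.r_start + 1
    aln_len = seg.s_len
    return "\t".join(str(v) for v in (
        seg.scaffold_id, seg.ref_id, seg.identity_pct, aln_len,
        seg.n_mismatch, seg.n_gap, seg.s_start + 1, seg.s_end,
        sstart, send, 0.0, seg.score,
    ))


def write_alignments_blast6(segments: Iterable[AlignSegment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(segment_to_blast6(seg) + "\n")
    return path


# ---------------------------------------------------------------------------
# SAM / BAM read alignments
# ---------------------------------------------------------------------------

def _aligned_seq(rec: pysam.AlignedSegment) -> Optional[str]:
    """Aligned bases per reference position (soft clips and insertions
    dropped, deletions padded with N)."""
    qseq = rec.query_sequence
    if qseq is None:
        return None
    out: list[str] = []
    qpos = 0
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            out.append(qseq[qpos:qpos + length])
            qpos += length
        elif op in (1, 4):  # I, S consume query only
            qpos += length
        elif op in (2, 3):  # D, N consume reference only
            out.append("N" * length)
        # H, P consume nothing
    return "".join(out)


def load_read_alignments(path: str | Path) -> Iterator[ReadAlignment]:
    """Load SAM/BAM read alignments.

    Unmapped and supplementary records are dropped; secondary records
    are folded into an ``is_multi`` flag on the primary alignment.  Mate
    fields are resolved from the pairing flags.  Desk-scale: the file is
    read fully to resolve multi-mapping before yielding.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise FormatError(f"{path}: SAM header has no sequence dictionary")
        multi: set[tuple[str, int]] = set()
        primaries: list[pysam.AlignedSegment] = []
        for rec in fh:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            mate_index = 2 if rec.is_read2 else 1
            if rec.is_secondary:
                multi.add((rec.query_name, mate_index))
            else:
                primaries.append(rec)
    for rec in primaries:
        mate_index = 2 if rec.is_read2 else 1
        has_mate = rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_name is not None
        nh = rec.get_tag("NH") if rec.has_tag("NH") else 1
        yield ReadAlignment(
            read_id=rec.query_name,
            mate_index=mate_index,
            scaffold_id=rec.reference_name,
            pos=rec.reference_start,
            end=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
            is_multi=(rec.query_name, mate_index) in multi or nh > 1,
            seq=_aligned_seq(rec),
            mate_scaffold=rec.next_reference_name if has_mate else None,
            mate_pos=rec.next_reference_start if has_mate else None,
            mate_strand=("-" if rec.mate_is_reverse else "+") if has_mate else None,
        )


def write_sam(alignments: Sequence[ReadAlignment], scaffolds: Sequence[SequenceRecord],
              path: str | Path) -> Path:
    """Write ReadAlignments as a plain-text SAM file (primary records only)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": s.id, "LN": len(s)} for s in scaffolds],
    }
    tid = {s.id: i for i, s in enumerate(scaffolds)}
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment()
            rec.query_name = aln.read_id
            rec.reference_id = tid[aln.scaffold_id]
            rec.reference_start = aln.pos
            rec.mapping_quality = 0 if aln.is_multi else 60
            length = aln.end - aln.pos
            rec.cigartuples = [(0, length)]
            rec.query_sequence = aln.seq if aln.seq is not None else "N" * length
            flag = 0
            if aln.strand == "-":
                flag |= 0x10
            if aln.mate_scaffold is not None:
                flag |= 0x1 | 0x2
                flag |= 0x40 if aln.mate_index == 1 else 0x80
                if aln.mate_strand == "-":
                    flag |= 0x20
                rec.next_reference_id = tid[aln.mate_scaffold]
                rec.next_reference_start = aln.mate_pos
            rec.flag = flag
            if aln.is_multi:
                rec.set_tag("NH", 2)
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _bedgraph_from_values(scaffold_id: str, values, fh, bin_size: int = 1,
                          total_len: int | None = None) -> None:
    """Run-length-merged bedGraph lines covering every base exactly once."""
    import numpy as np

    values = np.asarray(values)
    if values.size == 0:
        return
    if total_len is None:
        total_len = values.size * bin_size
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    for s, e in zip(starts, ends):
        v = values[s]
        v = int(v) if float(v).is_integer() else round(float(v), 4)
        fh.write(f"{scaffold_id}\t{s * bin_size}\t{min(e * bin_size, total_len)}\t{v}\n")


def write_outputs(verdicts, corrected_scaffolds, tracks, out_dir,
                  stats_before=None, stats_after=None) -> dict[str, Path]:
    """Write the TSV report, corrected FASTA, bedGraph tracks and summary.

    ``tracks`` maps scaffold id -> evidence track bundle (see
    :class:`misasm.evidence.ScaffoldEvidence.tracks`); pass an empty dict
    to skip track output.
    """
    import pandas as pd

    from .correct import summarize

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths: dict[str, Path] = {}

    rows = [v.report_row() for v in verdicts]
    report_cols = [
        "scaffold", "kind", "s_left", "s_right", "M_L", "M_R", "label",
        "correction", "est_size", "n_disagreements", "disagreements_per_kbp",
        "has_high_cov", "has_low_cov", "has_zero_cov", "multi_align_ratio",
        "discordant_ratio", "span_frag_mean", "span_pair_count", "low_evidence",
    ]
    report = pd.DataFrame(rows, columns=report_cols)
    paths["report"] = out_dir / "report.tsv"
    report.to_csv(paths["report"], sep="\t", index=False)

    paths["corrected_fasta"] = write_fasta(corrected_scaffolds, out_dir / "corrected.fasta")

    track_names = ("coverage", "disagreements", "zero_coverage",
                   "multi_align_ratio", "discordant_ratio")
    handles = {}
    for name in track_names:
        paths[name] = out_dir / f"{name}.bedGraph"
        handles[name] = open(paths[name], "w")
    try:
        for scaf_id, tr in tracks.items():
            _bedgraph_from_values(scaf_id, tr.depth, handles["coverage"])
            _bedgraph_from_values(scaf_id, tr.disagreement_mask.astype(int), handles["disagreements"])
            _bedgraph_from_values(scaf_id, tr.zero_mask.astype(int), handles["zero_coverage"])
            _bedgraph_from_values(scaf_id, tr.multi_ratio_500, handles["multi_align_ratio"],
                                  bin_size=500, total_len=tr.scaffold_len)
            _bedgraph_from_values(scaf_id, tr.discordant_ratio_500, handles["discordant_ratio"],
                                  bin_size=500, total_len=tr.scaffold_len)
    finally:
        for fh in handles.values():
            fh.close()

    summary = summarize(verdicts, stats_before, stats_after)
    paths["summary"] = out_dir / "summary.tsv"
    summary.to_csv(paths["summary"], sep="\t", index=False)
    return paths
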