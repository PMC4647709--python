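"""Breakpoint-region computation and validation-rule tests."""

import numpy as np
import pytest

from misasm.chain import DiffKind, Difference, SegmentChain
from misasm.config import DEFAULT
from misasm.evidence import EvidenceBundle, LibraryModel, ScaffoldEvidence
from misasm.io_formats import AlignSegment, SequenceRecord
from misasm.validate import (BreakpointRegion, CorrectionKind, Label,
                             classify_sv, compute_breakpoint_region,
                             validate_deletion, validate_difference,
                             validate_insertion, validate_misjoin)

from conftest import make_read, random_scaffold


def bundle(**kw) -> EvidenceBundle:
    base = dict(n_disagreements=0, disagreements_per_kbp=0.0,
                has_high_cov=False, has_low_cov=False, has_zero_cov=False,
                multi_align_ratio=0.0, discordant_ratio=0.0,
                span_frag_mean=None, span_pair_count=0, n_reads=100)
    base.update(kw)
    return EvidenceBundle(**base)


def region(m_l=1000, m_r=1200, kind=DiffKind.MISJOIN):
    return BreakpointRegion("s", m_l, m_r, kind)


def diff(kind=DiffKind.MISJOIN, s_left=1000, s_right=1200, est=0, **kw):
    segs = {}
    if kind is DiffKind.MISJOIN:
        segs = dict(
            left_seg=AlignSegment("s", "ref", 0, 1200, 0, 1200, "+", 10),
            right_seg=AlignSegment("s", "ref", 1000, 3000, 50_000, 52_000, "+", 10),
        )
    return Difference(kind, "s", s_left, s_right, est_size=est, **segs, **kw)


class TestBreakpointRegion:
    def evidence_for(self, scaf, reads):
        return ScaffoldEvidence(scaf, reads, [], LibraryModel(368, 61), DEFAULT)

    def chain_for(self, scaf):
        return SegmentChain(scaf.id, len(scaf), ())

    def test_misjoin_no_mismatched_tails(self):
        scaf = random_scaffold(3000)
        reads = [make_read("s", p, scaf.sequence[p:p + 100], read_id=f"r{p}")
                 for p in range(0, 2900, 10)]
        ev = self.evidence_for(scaf, reads)
        got = compute_breakpoint_region(diff(), self.chain_for(scaf), ev)
        assert (got.M_L, got.M_R) == (1000, 1200)

    def test_misjoin_trims_past_mismatched_tail(self):
        scaf = random_scaffold(3000)
        reads = []
        for p in range(0, 2900, 5):
            seq = scaf.sequence[p:p + 100]
            # reads disagree with the scaffold over [990, 1000)
            seq = "".join(
                ("A" if scaf.sequence[p + i] != "A" else "C")
                if 990 <= p + i < 1000 else b
                for i, b in enumerate(seq))
            reads.append(make_read("s", p, seq, read_id=f"r{p}"))
        ev = self.evidence_for(scaf, reads)
        got = compute_breakpoint_region(diff(), self.chain_for(scaf), ev)
        assert got.M_L == 990 and got.M_R == 1200

    def test_trim_capped(self):
        scaf = SequenceRecord("s", "A" * 3000)
        reads = [make_read("s", p, "G" * 100, read_id=f"r{p}")
                 for p in range(0, 2900, 5)]  # every column mismatches
        ev = self.evidence_for(scaf, reads)
        got = compute_breakpoint_region(diff(), self.chain_for(scaf), ev)
        assert got.M_L == 1000 - DEFAULT.trim_cap

    def test_insertion_margins_from_alignments(self):
        scaf = random_scaffold(3000)
        d = diff(DiffKind.INSERTION_MID, 500, 600, est=100)
        got = compute_breakpoint_region(d, self.chain_for(scaf), None)
        assert (got.M_L, got.M_R) == (500, 600)

    def test_deletion_point_region_widened_to_one_base(self):
        scaf = random_scaffold(3000)
        d = diff(DiffKind.DELETION, 700, 700, est=50)
        got = compute_breakpoint_region(d, self.chain_for(scaf), None)
        assert (got.M_L, got.M_R) == (700, 701)

    def test_unaligned_scaffold_is_whole_scaffold(self):
        scaf = random_scaffold(3000)
        d = Difference(DiffKind.UNALIGNED_SCAFFOLD, "s", 0, 3000, est_size=3000)
        got = compute_breakpoint_region(d, self.chain_for(scaf), None)
        assert (got.M_L, got.M_R) == (0, 3000)


class TestValidateMisjoin:
    def test_disagreements_validate(self):
        v = validate_misjoin(diff(), region(), bundle(n_disagreements=3))
        assert v.label is Label.ERROR_MISJOIN
        assert v.correction.kind is CorrectionKind.SPLIT

    def test_single_disagreement_insufficient(self):
        v = validate_misjoin(diff(), region(), bundle(n_disagreements=1))
        assert v.label is not Label.ERROR_MISJOIN

    def test_multi_ratio_validates(self):
        v = validate_misjoin(diff(), region(), bundle(multi_align_ratio=0.25))
        assert v.label is Label.ERROR_MISJOIN

    def test_multi_ratio_boundary_strict(self):
        v = validate_misjoin(diff(), region(), bundle(multi_align_ratio=0.1))
        assert v.label is Label.CORRECT_SV  # 0.1 is not > 0.1

    def test_clean_region_goes_to_sv(self):
        v = validate_misjoin(diff(), region(),
                             bundle(multi_align_ratio=0.05, n_disagreements=0))
        assert v.label is Label.CORRECT_SV

    @pytest.mark.parametrize("flag", ["has_high_cov", "has_low_cov", "has_zero_cov"])
    def test_coverage_flags_validate(self, flag):
        v = validate_misjoin(diff(), region(), bundle(**{flag: True}))
        assert v.label is Label.ERROR_MISJOIN


class TestValidateInsertion:
    def test_fragment_match_plus_two_conditions(self, lib):
        # fragment excess 470-368=102, inserted size 100: |102-100| < 2*61
        d = diff(DiffKind.INSERTION_MID, 1000, 1100, est=100)
        ev = bundle(span_frag_mean=470.0, span_pair_count=10,
                    n_disagreements=1, discordant_ratio=0.2)
        v = validate_insertion(d, region(1000, 1100, d.kind), ev, lib)
        assert v.label is Label.ERROR_INSERTION

    def test_fragment_match_single_condition_insufficient(self, lib):
        d = diff(DiffKind.INSERTION_MID, 1000, 1100, est=100)
        ev = bundle(span_frag_mean=470.0, span_pair_count=10, has_low_cov=True)
        v = validate_insertion(d, region(1000, 1100, d.kind), ev, lib)
        assert v.label is not Label.ERROR_INSERTION

    def test_large_insertion_falls_back_to_disagreement_rate(self, lib):
        d = diff(DiffKind.INSERTION_MID, 1000, 3000, est=2000)
        ev = bundle(disagreements_per_kbp=0.4, n_disagreements=1, n_reads=500)
        v = validate_insertion(d, region(1000, 3000, d.kind), ev, lib)
        assert v.label is not Label.ERROR_INSERTION  # 0.4 <= 1/kbp
        ev2 = bundle(disagreements_per_kbp=2.5, n_disagreements=5, n_reads=500)
        v2 = validate_insertion(d, region(1000, 3000, d.kind), ev2, lib)
        assert v2.label is Label.ERROR_INSERTION

    def test_end_insertion_zero_coverage_trims(self, lib):
        d = Difference(DiffKind.INSERTION_END, "s", 4800, 5000, est_size=200,
                       end_side="right")
        ev = bundle(has_zero_cov=True)
        v = validate_insertion(d, region(4800, 5000, d.kind), ev, lib)
        assert v.label is Label.ERROR_INSERTION
        assert v.correction.kind is CorrectionKind.TRIM_END
        assert v.correction.right == 4800

    def test_end_insertion_clean_goes_to_sv(self, lib):
        d = Difference(DiffKind.INSERTION_END, "s", 4800, 5000, est_size=200,
                       end_side="right")
        v = validate_insertion(d, region(4800, 5000, d.kind), bundle(), lib)
        assert v.label is Label.CORRECT_SV


class TestValidateDeletion:
    def test_fragment_match_plus_two_conditions(self, lib):
        # deficit 368-310 = 58, deleted size 55: |58-55| < 2*61
        d = diff(DiffKind.DELETION, 1000, 1001, est=55)
        ev = bundle(span_frag_mean=310.0, span_pair_count=8,
                    has_zero_cov=True, discordant_ratio=0.15)
        v = validate_deletion(d, region(1000, 1001, d.kind), ev, lib)
        assert v.label is Label.ERROR_DELETION

    def test_fragment_mismatch_and_null_evidence_is_sv(self, lib):
        d = diff(DiffKind.DELETION, 1000, 1001, est=70)
        ev = bundle(span_frag_mean=368.0, span_pair_count=8)
        v = validate_deletion(d, region(1000, 1001, d.kind), ev, lib)
        assert v.label is Label.CORRECT_SV

    def test_no_spanning_pairs_disagreement_rate(self, lib):
        d = diff(DiffKind.DELETION, 1000, 1300, est=300)
        ev = bundle(disagreements_per_kbp=3.0, n_disagreements=1, n_reads=200)
        v = validate_deletion(d, region(1000, 1300, d.kind), ev, lib)
        assert v.label is Label.ERROR_DELETION


class TestClassifySv:
    def test_clean_region_is_sv(self):
        v = classify_sv(diff(), region(), bundle(discordant_ratio=0.02))
        assert v.label is Label.CORRECT_SV
        assert v.correction.kind is CorrectionKind.REPORT_ONLY

    def test_low_coverage_blocks_sv(self):
        v = classify_sv(diff(), region(), bundle(has_low_cov=True))
        assert v.label is Label.WARNING

    def test_discordant_boundary_strict(self):
        v = classify_sv(diff(), region(), bundle(discordant_ratio=0.1))
        assert v.label is Label.WARNING  # needs < 0.1 strictly

    def test_low_evidence_is_warning_not_sv(self):
        v = classify_sv(diff(), region(), bundle(n_reads=2, span_pair_count=0))
        assert v.label is Label.WARNING and "low evidence" in v.note


class TestEndToEndRules:
    def test_gap_run_demotes_to_gap_report(self):
        seq = "ACGT" * 500 + "N" * 50 + "ACGT" * 500
        scaf = SequenceRecord("s", seq)
        ev = ScaffoldEvidence(scaf, [], [], LibraryModel(368, 61), DEFAULT)
        chain = SegmentChain("s", len(seq), ())
        d = Difference(DiffKind.INSERTION_MID, "s", 1990, 2060, est_size=70)
        v = validate_difference(d, chain, ev)
        assert v.label is Label.GAP_REPORT

    def test_every_difference_gets_one_verdict_label(self):
        labels = {Label.ERROR_MISJOIN, Label.ERROR_INSERTION,
                  Label.ERROR_DELETION, Label.CORRECT_SV, Label.WARNING,
                  Label.GAP_REPORT}
        assert {l for l in Label} == labels

    def test_monotonicity_error_never_flips_to_sv(self, lib):
        rng = np.random.default_rng(4)
        for _ in range(200):
            ev = bundle(
                n_disagreements=int(rng.integers(0, 4)),
                disagreements_per_kbp=float(rng.uniform(0, 3)),
                has_high_cov=bool(rng.integers(2)),
                has_low_cov=bool(rng.integers(2)),
                has_zero_cov=bool(rng.integers(2)),
                multi_align_ratio=float(rng.uniform(0, 0.3)),
                discordant_ratio=float(rng.uniform(0, 0.3)),
                span_frag_mean=float(rng.uniform(200, 600)),
                span_pair_count=int(rng.integers(3, 20)),
            )
            stronger = bundle(
                n_disagreements=ev.n_disagreements + 2,
                disagreements_per_kbp=ev.disagreements_per_kbp + 2,
                has_high_cov=ev.has_high_cov, has_low_cov=ev.has_low_cov,
                has_zero_cov=ev.has_zero_cov,
                multi_align_ratio=min(1.0, ev.multi_align_ratio + 0.2),
                discordant_ratio=min(1.0, ev.discordant_ratio + 0.2),
                span_frag_mean=ev.span_frag_mean,
                span_pair_count=ev.span_pair_count,
            )
            for kind, fn in ((DiffKind.MISJOIN, validate_misjoin),
                             (DiffKind.INSERTION_MID, validate_insertion),
                             (DiffKind.DELETION, validate_deletion)):
                d = diff(kind, 1000, 1100, est=100 if kind is not DiffKind.MISJOIN else 0)
                args = (d, region(1000, 1100, kind))
                if kind is DiffKind.MISJOIN:
                    v1, v2 = fn(*args, ev), fn(*args, stronger)
                else:
                    v1, v2 = fn(*args, ev, lib), fn(*args, stronger, lib)
                if v1.label.is_error:
                    assert v2.label is not Label.CORRECT_SV
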