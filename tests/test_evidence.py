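"""Read-evidence feature tests (pileup, disagreements, coverage windows,
pair classification, ratios, fragment statistics, library estimation)."""

import numpy as np
import pytest

from misasm.evidence import (LibraryModel, Pair, PairSet, Pileup, ReadSet,
                             build_pileup, call_disagreements, classify_pair,
                             coverage_flags, discordant_ratio,
                             estimate_library, multi_align_ratio,
                             spanning_fragments)
from misasm.io_formats import SequenceRecord

from conftest import make_read, random_scaffold


def pileup_from_counts(counts):
    """Build a Pileup directly from an (L, 4) count array."""
    p = Pileup(len(counts))
    p.counts[:] = np.asarray(counts, dtype=np.int32)
    return p


class TestPileup:
    def test_no_reads(self):
        pile = build_pileup([], random_scaffold(50))
        assert pile.depth.sum() == 0

    def test_identical_reads_counted(self):
        scaf = SequenceRecord("s", "A" * 30)
        reads = [make_read("s", 5, "A" * 10, read_id=f"r{i}") for i in range(10)]
        pile = build_pileup(reads, scaf)
        col = pile.column(7)
        assert col.counts == {"A": 10, "C": 0, "G": 0, "T": 0} and col.depth == 10

    def test_multi_read_counted_per_column(self):
        scaf = random_scaffold(30)
        pile = build_pileup([make_read("s", 5, scaf.sequence[5:10], is_multi=True)],
                            scaf)
        assert list(pile.multi[5:10]) == [1] * 5
        assert pile.multi.sum() == 5

    def test_read_outside_scaffold_rejected(self):
        scaf = random_scaffold(30)
        pile = build_pileup([make_read("s", 25, "ACGTACGT")], scaf)
        assert pile.n_rejected == 1 and pile.depth.sum() == 0

    def test_n_bases_ignored(self):
        scaf = random_scaffold(30)
        pile = build_pileup([make_read("s", 0, "ANCGT")], scaf)
        assert pile.depth[1] == 0 and pile.depth.sum() == 4

    def test_conservation(self):
        # sum of column depths == sum of aligned non-N bases over reads
        rng = np.random.default_rng(3)
        scaf = random_scaffold(500)
        reads = []
        total = 0
        for i in range(200):
            pos = int(rng.integers(0, 450))
            ln = int(rng.integers(10, 50))
            seq = "".join("ACGTN"[j] for j in rng.integers(0, 5, ln))
            reads.append(make_read("s", pos, seq, read_id=f"r{i}"))
            total += sum(1 for b in seq if b != "N")
        pile = build_pileup(reads, scaf)
        assert int(pile.depth.sum()) == total


class TestDisagreements:
    @pytest.mark.parametrize("a,c,expected", [
        (7, 3, True),    # 0.7 < 0.8
        (8, 2, False),   # 0.8 is not < 0.8 (strict)
        (10, 0, False),
        (3, 1, False),   # depth 4 < min_depth
    ])
    def test_majority_threshold(self, a, c, expected):
        pile = pileup_from_counts([[a, c, 0, 0]])
        got = call_disagreements(pile, majority_frac=0.8, min_depth=5)
        assert (0 in got) is expected

    def test_matches_per_column_recount(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 12, size=(300, 4))
        pile = pileup_from_counts(counts)
        got = set(call_disagreements(pile).tolist())
        expected = set()
        for i, row in enumerate(counts):
            depth = row.sum()
            if depth >= 5 and row.max() / depth < 0.8:
                expected.add(i)
        assert got == expected


class TestCoverageFlags:
    def uniform_pileup(self, length, depth):
        counts = np.zeros((length, 4), dtype=int)
        counts[:, 0] = depth
        return pileup_from_counts(counts)

    def test_uniform_coverage_no_flags(self):
        pile = self.uniform_pileup(1000, 50)
        assert coverage_flags(pile, (400, 600)) == (False, False, False)

    def test_two_high_windows_flag_high(self):
        pile = self.uniform_pileup(1000, 50)
        pile.counts[400:500, 0] = 80  # two 50-bp windows at 80 > 1.5*mean(~53)
        high, low, zero = coverage_flags(pile, (400, 500), anomaly_windows=2)
        assert high and not low and not zero

    def test_single_high_window_not_enough(self):
        pile = self.uniform_pileup(1000, 50)
        pile.counts[400:450, 0] = 200
        high, _, _ = coverage_flags(pile, (400, 450), anomaly_windows=2)
        assert not high

    def test_zero_coverage_base(self):
        pile = self.uniform_pileup(1000, 50)
        pile.counts[455] = 0
        _, _, zero = coverage_flags(pile, (450, 460))
        assert zero

    def test_zero_outside_region_not_flagged(self):
        pile = self.uniform_pileup(1000, 50)
        pile.counts[10] = 0
        assert coverage_flags(pile, (450, 460))[2] is False

    def test_single_cell_mode_tolerates_fold_changes(self):
        # smoothly varying coverage: fold thresholds would fire, sd-based do not
        length = 2000
        counts = np.zeros((length, 4), dtype=int)
        counts[:, 0] = np.linspace(20, 200, length).astype(int)
        pile = pileup_from_counts(counts)
        std = coverage_flags(pile, (0, 100), mode="standard")
        sc = coverage_flags(pile, (900, 1100), mode="single_cell")
        assert std[1] is True          # low under fold rule
        assert sc == (False, False, False)  # mid-range is unremarkable vs sd

    def test_region_validation(self):
        pile = self.uniform_pileup(100, 10)
        with pytest.raises(ValueError):
            coverage_flags(pile, (50, 50))

    def test_n_run_windows_excluded(self):
        scaf = SequenceRecord("s", "A" * 400 + "N" * 200 + "A" * 400)
        pile = self.uniform_pileup(1000, 50)
        pile.counts[400:600] = 0  # no coverage over the gap
        high, low, zero = coverage_flags(pile, (350, 650),
                                         scaffold_seq=scaf.sequence)
        assert not low and not zero


class TestRatiosAndPairs:
    def reads(self, n, n_multi, start=0, ln=100):
        return ReadSet([
            make_read("s", start + i, "A" * ln, read_id=f"r{i}",
                      is_multi=(i < n_multi))
            for i in range(n)
        ])

    def test_multi_align_ratio(self):
        assert multi_align_ratio(self.reads(10, 0), (0, 200)) == (0.0, 10)
        ratio, n = multi_align_ratio(self.reads(10, 3), (0, 200))
        assert ratio == pytest.approx(0.3) and n == 10

    def test_multi_align_ratio_empty_region(self):
        assert multi_align_ratio(self.reads(10, 5), (5000, 5100)) == (0.0, 0)

    def test_classify_pair_rules(self, lib):
        fr = Pair(1000, 1100, 1268, 1368, "+", "-")   # fragment = mu
        assert fr.fragment == 368
        assert classify_pair(fr, lib) == "concordant"
        far = Pair(1000, 1100, 1000 + 368 + 244 - 100, 1000 + 368 + 244, "+", "-")
        assert abs(far.fragment - lib.mu) == pytest.approx(4 * lib.sigma)
        assert classify_pair(far, lib) == "discordant"
        rf = Pair(1000, 1100, 1268, 1368, "-", "+")   # outward-facing
        assert classify_pair(rf, lib) == "discordant"
        inter = Pair(0, 100, 0, 100, "+", "-", inter_scaffold=True)
        assert classify_pair(inter, lib) == "discordant"

    def test_discordant_boundary_is_strict(self, lib):
        at3sd = Pair(0, 100, int(lib.mu + 3 * lib.sigma) - 100,
                     int(lib.mu + 3 * lib.sigma), "+", "-")
        assert abs(at3sd.fragment - lib.mu) == pytest.approx(3 * lib.sigma)
        assert classify_pair(at3sd, lib) == "concordant"  # > is strict

    def make_pairset(self, frags, lib, start=0):
        pairs = [Pair(start, start + 100, start + f - 100, start + f, "+", "-")
                 for f in frags]
        return PairSet(pairs, lib)

    def test_discordant_ratio_small_region(self, lib):
        ps = self.make_pairset([368] * 16 + [700] * 4, lib)
        assert discordant_ratio(ps, (50, 350)) == pytest.approx(0.2)

    def test_discordant_ratio_zero(self, lib):
        ps = self.make_pairset([368] * 20, lib)
        assert discordant_ratio(ps, (0, 400)) == 0.0
        assert discordant_ratio(PairSet([], lib), (0, 400)) == 0.0

    def test_discordant_ratio_max_over_subregions(self, lib):
        # 1200-bp region split into 500/500/200; sub-ratios 0.05, 0.30, 0.0
        def fr(start):
            return Pair(start, start + 100, start + 268, start + 368, "+", "-")

        def rf(start):  # outward-facing: discordant by orientation
            return Pair(start, start + 100, start + 268, start + 368, "-", "+")

        pairs = [fr(i) for i in range(0, 95, 5)] + [rf(100)]          # 1/20
        pairs += [fr(500 + i) for i in range(0, 70, 5)] + \
                 [rf(505 + i) for i in range(0, 30, 5)]               # 6/20
        ps = PairSet(pairs, lib)
        assert discordant_ratio(ps, (0, 500)) == pytest.approx(0.05)
        assert discordant_ratio(ps, (1000, 1200)) == 0.0
        assert discordant_ratio(ps, (0, 1200)) == pytest.approx(0.30)

    def test_ratio_bounds_and_monotonicity(self, lib):
        rng = np.random.default_rng(2)
        base = [368] * 30
        prev = 0.0
        for n_disc in range(0, 31, 5):
            frags = base[:30 - n_disc] + [900] * n_disc
            ps = self.make_pairset(frags, lib)
            r = discordant_ratio(ps, (0, 400))
            assert 0.0 <= r <= 1.0
            assert r >= prev
            prev = r


class TestSpanningFragments:
    def test_no_spanning_pairs(self, lib):
        ps = PairSet([], lib)
        assert spanning_fragments(ps, (100, 200)) == (None, 0)

    def test_mean_of_five(self, lib):
        frags = [400, 410, 390, 405, 395]
        pairs = [Pair(900 - 100, 900, 900 - 100 + f - 100, 900 - 100 + f, "+", "-")
                 for f in frags]
        ps = PairSet(pairs, lib)
        mean, count = spanning_fragments(ps, (950, 1000))
        assert count == 5 and mean == pytest.approx(400.0)

    def test_mate_inside_region_excluded(self, lib):
        inside = Pair(940, 1040, 1200, 1300, "+", "-")  # left mate enters region
        outside = Pair(840, 940, 1200, 1300, "+", "-")
        ps = PairSet([inside, outside] * 3, lib)
        mean, count = spanning_fragments(ps, (950, 1000))
        assert count == 3

    def test_below_floor_reports_absent(self, lib):
        pairs = [Pair(800, 900, 1100, 1200, "+", "-")] * 2
        mean, count = spanning_fragments(PairSet(pairs, lib), (950, 1000))
        assert mean is None and count == 2


class TestEstimateLibrary:
    def test_given_returned_verbatim(self):
        lib = estimate_library([], given=(368, 61))
        assert (lib.mu, lib.sigma, lib.source) == (368.0, 61.0, "given")

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="supply the library"):
            estimate_library([300.0] * 10)

    def test_parameter_recovery_within_two_percent(self):
        rng = np.random.default_rng(0)
        frags = rng.normal(368, 61, 10_000)
        frags = np.concatenate([frags, [5000.0, 9000.0]])  # chimeric outliers
        lib = estimate_library(frags)
        assert lib.source == "estimated"
        assert abs(lib.mu - 368) / 368 < 0.02
        assert abs(lib.sigma - 61) / 61 < 0.02
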