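"""The read-evidence features, one by one, on hand-built data.

Shows how the pileup, disagreement calls, coverage-anomaly windows,
pair classification and the discordant ratio behave on small inputs
whose expected values can be checked by eye.
"""

import numpy as np

from misasm.evidence import (LibraryModel, Pair, PairSet, Pileup,
                             call_disagreements, classify_pair,
                             coverage_flags, discordant_ratio)

lib = LibraryModel(mu=368, sigma=61)
print(f"library model: insert mean {lib.mu:.0f} bp, sd {lib.sigma:.0f} bp\n")

# --- disagreements: majority-base fraction strictly below 0.8 ---
pile = Pileup(4)
pile.counts[0] = [10, 0, 0, 0]   # unanimous
pile.counts[1] = [8, 2, 0, 0]    # majority exactly 0.8 -> no call
pile.counts[2] = [7, 3, 0, 0]    # majority 0.7 -> disagreement
pile.counts[3] = [2, 1, 0, 0]    # depth 3 < 5 -> too shallow to judge
calls = call_disagreements(pile)
print(f"disagreement positions: {calls.tolist()}  (expected [2]: only the "
      "7A/3C column fails the 0.8 majority test at adequate depth)")

# --- coverage anomalies: 50-bp windows vs 1.5x / 0.5x scaffold mean ---
cov = Pileup(1000)
cov.counts[:, 0] = 50
cov.counts[300:400, 0] = 90      # two windows at 90 > 1.5 * 50
high, low, zero = coverage_flags(cov, (300, 400))
print(f"coverage flags over the 90x stretch: high={high} low={low} zero={zero}")

# --- pair classification: orientation and the 3-sigma fragment rule ---
pairs = {
    "proper FR at mean": Pair(0, 100, 268, 368, "+", "-"),
    "FR at mean + 4 sd": Pair(0, 100, 512, 612, "+", "-"),
    "outward-facing RF": Pair(0, 100, 268, 368, "-", "+"),
}
for name, p in pairs.items():
    print(f"{name:<20} fragment={p.fragment:<4} -> {classify_pair(p, lib)}")

# --- discordant ratio in a region ---
good = [Pair(i, i + 100, i + 268, i + 368, "+", "-") for i in range(0, 160, 10)]
bad = [Pair(5 + i, 105 + i, 705 + i, 805 + i, "+", "-") for i in range(0, 40, 10)]
ratio = discordant_ratio(PairSet(good + bad, lib), (0, 500))
print(f"\ndiscordant ratio: {ratio:.2f}  (4 of 20 pairs exceed mu + 3 sd; "
      "a breakpoint region above 0.1 supports an error call)")
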