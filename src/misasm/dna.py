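"""Small DNA-sequence helpers shared across the package.

Sequences are plain Python strings over {A,C,G,T,N}; hot loops work on
uint8 code arrays (A=0, C=1, G=2, T=3, N/other=4) so that pileup and
alignment arithmetic stays vectorised.
"""

from __future__ import annotations

import numpy as np

# code 4 is "not a base": N in sequences, never counted in pileups
A, C, G, T, N = 0, 1, 2, 3, 4

_CODE_OF = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
    _CODE_OF[_b + 32] = _i  # lowercase

_BASE_OF = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 code array."""
    return _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE_OF[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, codes).astype(np.uint8)
    return out[::-1].copy()


def normalize(seq: str) -> str:
    """Uppercase, U->T, anything outside {A,C,G,T,N} -> N."""
    up = seq.upper().replace("U", "T")
    arr = np.frombuffer(up.encode("ascii", errors="replace"), dtype=np.uint8)
    return decode(_CODE_OF[arr])


def n_run_mask(seq: str, min_run: int = 10) -> np.ndarray:
    """Boolean mask of bases lying in runs of >= min_run consecutive N."""
    codes = encode(seq)
    is_n = codes == N
    mask = np.zeros(len(seq), dtype=bool)
    if not is_n.any():
        return mask
    # run-length scan over the N indicator
    padded = np.concatenate(([False], is_n, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            mask[start:stop] = True
    return mask
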