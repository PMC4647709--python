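import numpy as np
import pytest

from misasm.evidence import LibraryModel
from misasm.io_formats import ReadAlignment, SequenceRecord


@pytest.fixture
def lib() -> LibraryModel:
    return LibraryModel(mu=368.0, sigma=61.0)


def make_read(scaffold_id, pos, seq, *, read_id="r", mate_index=1, strand="+",
              is_multi=False, **kw) -> ReadAlignment:
    return ReadAlignment(read_id=read_id, mate_index=mate_index,
                         scaffold_id=scaffold_id, pos=pos, end=pos + len(seq),
                         strand=strand, is_multi=is_multi, seq=seq, **kw)


def random_scaffold(length: int, seed: int = 0, name: str = "s") -> SequenceRecord:
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return SequenceRecord(name, seq)
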