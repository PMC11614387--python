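import numpy as np
import pytest

from bashmap.io_formats import BitVector, ReadSet, SequenceRecord


def make_readset(seq: str, rows: list[str], start: int | None = None) -> ReadSet:
    """ReadSet from bitstrings; rows may be (start, bits) tuples for partial reads."""
    ref = SequenceRecord("ref", seq)
    reads = []
    for k, row in enumerate(rows):
        if isinstance(row, tuple):
            s, bits = row
        else:
            s, bits = (start or 1), row
        arr = np.array([int(c) for c in bits], dtype=np.uint8)
        reads.append(BitVector(f"r{k}", s, s + len(arr) - 1, arr))
    return ReadSet(ref, reads)


@pytest.fixture
def tiny_readset():
    return make_readset("ACGU", ["0100", "0100"])
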