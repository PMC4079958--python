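"""Shared fixtures and builders for constructing tiny alignments in memory."""

from __future__ import annotations

import pytest
from hypothesis import settings

from flowindel.alignment import AlignedRead

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def read_from_ref(
    reference: str,
    ref_start: int,
    ops,
    read_id: str = "r1",
    mapq: int = 60,
):
    """Build an AlignedRead whose sequence is consistent with the reference
    and the given ops.

    ``ops`` entries: ("M", n) copies n reference bases; ("D", n) skips n
    reference bases; ("I", "SEQ") inserts the literal bases; ("S", "SEQ")
    soft-clips the literal bases.
    """
    cigar = []
    seq = []
    r = ref_start
    for op, arg in ops:
        if op == "M":
            seq.append(reference[r:r + arg])
            cigar.append(("M", arg))
            r += arg
        elif op == "D":
            cigar.append(("D", arg))
            r += arg
        elif op == "I":
            seq.append(arg)
            cigar.append(("I", len(arg)))
        elif op == "S":
            seq.append(arg)
            cigar.append(("S", len(arg)))
        else:
            raise ValueError(op)
    return AlignedRead(
        read_id=read_id,
        ref_start=ref_start,
        cigar=tuple(cigar),
        mapq=mapq,
        sequence="".join(seq),
    )


@pytest.fixture
def flat_reference() -> str:
    """Non-repetitive reference: no two adjacent bases equal anywhere."""
    return "ACGT" * 64  # 256 bp


@pytest.fixture
def pileup_reads(flat_reference):
    """100 reads spanning positions 0..120 of the flat reference, half of
    them carrying a 1-base deletion at reference position 50 (anchor 49)."""
    reads = []
    for i in range(100):
        if i < 50:
            reads.append(
                read_from_ref(
                    flat_reference, 0, [("M", 50), ("D", 1), ("M", 70)],
                    read_id=f"alt{i}",
                )
            )
        else:
            reads.append(
                read_from_ref(flat_reference, 0, [("M", 121)], read_id=f"ref{i}")
            )
    return reads
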