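"""Read-level indel evidence extraction.

Flow-based sequencers (the Ion Torrent PGM family) determine homopolymer run
lengths from the intensity of a single incorporation signal.  The signal scales
imperfectly with run length, so reads over- or under-call long runs and the
resulting alignments carry spurious one-base gaps and inserts.  A true indel,
by contrast, is reported consistently by the reads that carry it.

This module turns aligned reads into per-locus evidence that makes this
distinction quantitative:

* ``IndelObservation`` — one gap/insert event extracted from one read,
  left-aligned against the reference and carrying a signed width
  (+k insertion, -k deletion).
* VARW — the population variance of the signed widths observed at one locus.
  VARW is exactly 0 when every read reports the same event and grows when
  reads disagree (the signature of homopolymer slippage).
* BAF — the fraction of spanning reads that support a non-reference allele.
* HRun — the length of the reference homopolymer run immediately right of a
  call's anchor base.
* MAPQ profile — median/quartiles of mapping quality over spanning reads,
  useful to diagnose loci where mis-mapping rather than miscalls drives the
  evidence.

Coordinates are 0-based half-open throughout; VCF-style 1-based coordinates
appear only at the I/O boundary.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import BoundsError, CigarError, ContractError, EvidenceError

# CIGAR operation classes. '=' and 'X' are treated as matches.
_MATCH_OPS = frozenset("M=X")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MD=X")
_VALID_OPS = _MATCH_OPS | frozenset("IDS")

_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S", 7: "=", 8: "X"}


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to the fields the evidence extraction needs.

    ``cigar`` is a tuple of ``(op, length)`` pairs with op one of
    M/=/X (match), I (insertion), D (deletion), S (soft clip).
    """

    read_id: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    sequence: str

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise CigarError(f"read {self.read_id}: negative ref_start")
        if not (0 <= self.mapq <= 254):
            raise CigarError(f"read {self.read_id}: MAPQ {self.mapq} outside [0, 254]")
        if not self.cigar:
            raise CigarError(f"read {self.read_id}: empty CIGAR")
        qlen = 0
        for op, length in self.cigar:
            if op not in _VALID_OPS:
                raise CigarError(f"read {self.read_id}: unsupported CIGAR op {op!r}")
            if length <= 0:
                raise CigarError(f"read {self.read_id}: non-positive CIGAR length")
            if op in _QUERY_OPS:
                qlen += length
        if qlen != len(self.sequence):
            raise CigarError(
                f"read {self.read_id}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def ref_end(self) -> int:
        """One past the last reference base this alignment covers."""
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    def spans(self, position: int) -> bool:
        """True when the aligned span covers ``position``.

        Deletion-spanning reads count: a read whose alignment jumps over the
        base still constrains what is there, pileup-style.
        """
        return self.ref_start <= position < self.ref_end

    @classmethod
    def from_pysam(cls, aln) -> "AlignedRead":
        """Convert a :class:`pysam.AlignedSegment` (mapped, primary)."""
        if aln.cigartuples is None:
            raise CigarError(f"read {aln.query_name}: missing CIGAR")
        cigar = []
        for code, length in aln.cigartuples:
            if code == 5:  # hard clip consumes nothing we track
                continue
            if code not in _PYSAM_OPS:
                raise CigarError(
                    f"read {aln.query_name}: unsupported CIGAR op code {code}"
                )
            cigar.append((_PYSAM_OPS[code], length))
        return cls(
            read_id=aln.query_name,
            ref_start=aln.reference_start,
            cigar=tuple(cigar),
            mapq=aln.mapping_quality,
            sequence=aln.query_sequence or "",
        )


@dataclass(frozen=True)
class IndelObservation:
    """One gap (deletion) or insert extracted from one aligned read.

    ``anchor_pos`` is the 0-based reference coordinate of the base immediately
    left of the event after left alignment.  ``signed_width`` is +k for a
    k-base insertion and -k for a k-base deletion.  ``inserted_seq`` carries
    the (left-aligned) inserted bases for insertions, ``None`` for deletions.
    """

    anchor_pos: int
    signed_width: int
    read_id: str
    inserted_seq: str | None = None

    def __post_init__(self) -> None:
        if self.signed_width == 0:
            raise ContractError("signed_width must be non-zero")
        if self.signed_width > 0:
            if self.inserted_seq is None or len(self.inserted_seq) != self.signed_width:
                raise ContractError("insertion observation needs inserted_seq of matching length")
        elif self.inserted_seq is not None:
            raise ContractError("deletion observation must not carry inserted_seq")


def left_align_deletion(reference: str, start: int, length: int) -> int:
    """Slide a deletion of ``reference[start:start+length]`` to its leftmost
    equivalent placement and return the new start.

    A deletion may shift left one base whenever the base entering the gap on
    the right equals the base leaving it on the left, i.e. when
    ``reference[start-1] == reference[start+length-1]``.
    """
    if start < 0 or start + length > len(reference):
        raise BoundsError("deletion outside reference")
    s = start
    while s > 0 and reference[s - 1] == reference[s + length - 1]:
        s -= 1
    if s == 0:
        raise BoundsError("deletion left-aligns to the contig start; no anchor base exists")
    return s


def left_align_insertion(reference: str, pos: int, inserted: str) -> tuple[int, str]:
    """Left-align an insertion placed before ``reference[pos]``.

    Returns the new ``(pos, inserted)``; shifting rotates the inserted string
    so the represented alternative sequence is unchanged.
    """
    if pos < 0 or pos > len(reference):
        raise BoundsError("insertion position outside reference")
    seq = inserted
    p = pos
    while p > 1 and seq[-1] == reference[p - 1]:
        seq = reference[p - 1] + seq[:-1]
        p -= 1
    if p == 0 or (p == 1 and seq[-1] == reference[0]):
        raise BoundsError("insertion left-aligns to the contig start; no anchor base exists")
    return p, seq


def extract_indel_observations(
    reads: Iterable[AlignedRead],
    reference: str,
    region: tuple[int, int] | None = None,
) -> list[IndelObservation]:
    """Extract one left-aligned observation per I/D CIGAR element.

    ``region`` is a 0-based half-open interval; observations whose left-aligned
    anchor falls outside it are dropped.  Match-only reads contribute nothing;
    soft-clipped bases contribute neither observations nor reference span.
    """
    if region is None:
        start, end = 0, len(reference)
    else:
        start, end = region
        if start < 0 or end > len(reference) or start > end:
            raise BoundsError(f"region ({start}, {end}) outside reference of length {len(reference)}")
    out: list[IndelObservation] = []
    for read in reads:
        if read.ref_end > len(reference):
            raise BoundsError(
                f"read {read.read_id} extends to {read.ref_end}, past reference end {len(reference)}"
            )
        r = read.ref_start
        q = 0
        for op, length in read.cigar:
            if op in _MATCH_OPS:
                r += length
                q += length
            elif op == "S":
                q += length
            elif op == "I":
                ins = read.sequence[q:q + length]
                p, seq = left_align_insertion(reference, r, ins)
                anchor = p - 1
                if start <= anchor < end:
                    out.append(IndelObservation(anchor, length, read.read_id, seq))
                q += length
            elif op == "D":
                s = left_align_deletion(reference, r, length)
                anchor = s - 1
                if start <= anchor < end:
                    out.append(IndelObservation(anchor, -length, read.read_id))
                r += length
    return out


def compute_varw(
    observations: Sequence[IndelObservation],
    *,
    require_common_anchor: bool = True,
) -> float | None:
    """VARW: population variance of the signed widths of the observations.

    Returns ``None`` (undefined, distinct from 0) for an empty collection and
    exactly ``0.0`` when all widths agree.  Insertions are positive and
    deletions negative, so mixed event types at one locus always yield
    VARW > 0.
    """
    if not observations:
        return None
    if require_common_anchor:
        anchors = {o.anchor_pos for o in observations}
        if len(anchors) != 1:
            raise ContractError(f"observations span multiple anchors: {sorted(anchors)}")
    widths = np.array([o.signed_width for o in observations], dtype=float)
    return float(np.var(widths))


def compute_baf(depth: int, observations: Sequence[IndelObservation]) -> float:
    """Fraction of spanning reads carrying a non-reference (gap/insert) allele.

    Counts distinct reads, so a read contributing several observations at the
    locus is counted once.
    """
    if depth <= 0:
        raise EvidenceError("BAF undefined at zero depth")
    supporting = len({o.read_id for o in observations})
    if supporting > depth:
        raise ContractError(f"{supporting} supporting reads exceed depth {depth}")
    return supporting / depth


@dataclass(frozen=True)
class MapqProfile:
    median: float
    q1: float
    q3: float
    n: int


def mapq_profile(reads: Iterable[AlignedRead], position: int) -> MapqProfile:
    """Median and quartiles of MAPQ over reads spanning ``position``.

    Even counts take the mean of the two central values (numpy convention).
    """
    mapqs = [r.mapq for r in reads if r.spans(position)]
    if not mapqs:
        raise EvidenceError(f"no read spans position {position}")
    arr = np.array(mapqs, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return MapqProfile(median=float(med), q1=float(q1), q3=float(q3), n=len(mapqs))


def compute_hrun(reference: str, anchor_pos: int) -> int:
    """Homopolymer run length at an indel locus.

    Measures the maximal run of identical reference bases starting at the base
    immediately right of the left-aligned anchor.  For a deletion inside a run
    this is the run's full length regardless of which copy was deleted; for an
    insertion of a repeated base it is the length of the run the insertion
    extends.  Always >= 1.
    """
    p = anchor_pos + 1
    if anchor_pos < 0 or p >= len(reference):
        raise BoundsError(f"anchor {anchor_pos} leaves no run start inside reference")
    base = reference[p]
    n = 1
    while p + n < len(reference) and reference[p + n] == base:
        n += 1
    return n


def coverage_array(reads: Iterable[AlignedRead], ref_length: int) -> np.ndarray:
    """Per-position spanning-read depth over ``[0, ref_length)``."""
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    for r in reads:
        diff[r.ref_start] += 1
        diff[min(r.ref_end, ref_length)] -= 1
    return np.cumsum(diff)[:-1]


@dataclass
class LocusEvidence:
    """Alignment-derived evidence summarised at one anchor position."""

    position: int
    depth: int
    observations: list[IndelObservation] = field(default_factory=list)
    baf: float = 0.0
    varw: float | None = None
    mapq_median: float = 0.0
    hrun: int = 1


def gather_locus_evidence(
    reads: Sequence[AlignedRead],
    reference: str,
    positions: Iterable[int],
    window: int = 0,
) -> dict[int, LocusEvidence]:
    """Summarise evidence at each requested anchor position.

    ``window`` widens the pooling window to anchors within +-window bases of
    the locus (default 0: only observations left-aligning to the exact
    anchor).  Raises :class:`EvidenceError` for positions no read spans.
    """
    reads = list(reads)
    obs = extract_indel_observations(reads, reference)
    by_anchor: dict[int, list[IndelObservation]] = defaultdict(list)
    for o in obs:
        by_anchor[o.anchor_pos].append(o)
    cov = coverage_array(reads, len(reference))
    out: dict[int, LocusEvidence] = {}
    for pos in positions:
        if not (0 <= pos < len(reference)):
            raise BoundsError(f"position {pos} outside reference")
        depth = int(cov[pos])
        if depth == 0:
            raise EvidenceError(f"no read spans locus {pos}; cannot annotate")
        if window == 0:
            here = list(by_anchor.get(pos, []))
        else:
            here = [
                o
                for a in range(pos - window, pos + window + 1)
                for o in by_anchor.get(a, [])
            ]
        ev = LocusEvidence(
            position=pos,
            depth=depth,
            observations=here,
            baf=compute_baf(depth, here),
            varw=compute_varw(here, require_common_anchor=(window == 0)) if here else None,
            mapq_median=mapq_profile(reads, pos).median,
            hrun=compute_hrun(reference, pos),
        )
        out[pos] = ev
    return out


def write_evidence_table(path, evidence: Mapping[int, LocusEvidence], chrom: str) -> None:
    """Export evidence as TSV (1-based positions, NA for undefined VARW)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tdepth\tn_obs\tbaf\tvarw\thrun\tmapq_median\n")
        for pos in sorted(evidence):
            ev = evidence[pos]
            varw = "NA" if ev.varw is None else f"{ev.varw:.6g}"
            fh.write(
                f"{chrom}\t{pos + 1}\t{ev.depth}\t{len(ev.observations)}\t"
                f"{ev.baf:.6g}\t{varw}\t{ev.hrun}\t{ev.mapq_median:.6g}\n"
            )
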