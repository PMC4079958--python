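"""Synthetic flow-sequencing data with homopolymer length-miscall errors.

The generator stands in for amplicon resequencing of a diploid sample on a
flow-based benchtop instrument.  It emits, deterministically per seed:

* a reference with a controllable homopolymer run-length composition,
* a diploid sample with planted heterozygous indels (truth records
  normalized, expected allele fraction 0.5),
* reads drawn uniformly from both haplotypes and emitted *pre-aligned*
  (placement is known by construction; planted indels and injected errors
  are expressed in the CIGAR), so no external mapper is required,
* a naive pileup indel caller so the annotate/filter/evaluate stack runs
  end-to-end without any third-party caller.

Error model.  Flow instruments read a homopolymer of length L from one
incorporation signal whose relative precision degrades with L, so the
dominant artifact is an off-by-one run length.  Each maximal run of length L
in a read is miscalled to L+-1 with probability

    p(L) = min(p0 * L**gamma, pmax)

with the miscall a deletion with probability ``indel_bias`` (undercalls
dominate on real instruments) and an insertion otherwise.  The power-law form
captures the qualitative behaviour — error rate rising steeply with run
length — and its parameters are exposed, not calibrated to any particular
chemistry.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .alignment import AlignedRead, coverage_array, extract_indel_observations
from .errors import ConfigError
from .filtering import IndelCall, normalize_indel

ALPHABET = "ACGT"

DEFAULT_SEED = 20140624

#: Run-length composition of the default synthetic amplicon target:
#: mostly non-repetitive sequence with a tail of long homopolymers so that
#: length-miscall artifacts actually arise at callable rates.
DEFAULT_RUN_LENGTH_DIST: dict[int, float] = {
    1: 0.68,
    2: 0.17,
    3: 0.07,
    4: 0.035,
    5: 0.02,
    6: 0.012,
    7: 0.008,
    8: 0.005,
}


@dataclass(frozen=True)
class ErrorModelParams:
    """Homopolymer length-miscall model: p(L) = min(p0 * L**gamma, pmax);
    a miscall shortens the run with probability ``indel_bias``."""

    p0: float = 0.002
    gamma: float = 2.0
    pmax: float = 0.3
    indel_bias: float = 0.7

    def __post_init__(self) -> None:
        if not (0 <= self.p0 <= self.pmax <= 1):
            raise ConfigError("need 0 <= p0 <= pmax <= 1")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if not (0 <= self.indel_bias <= 1):
            raise ConfigError("indel_bias must be in [0, 1]")

    def miscall_prob(self, run_length: int) -> float:
        return min(self.p0 * run_length ** self.gamma, self.pmax)


@dataclass(frozen=True)
class SimulatedSample:
    """A diploid sample: two haplotypes, each haplotype's planted events
    (as (ref_pos, signed_width, inserted_seq) in reference coordinates), and
    the normalized truth records."""

    sample_id: str
    haplotypes: tuple[str, str]
    hap_events: tuple[tuple[tuple[int, int, str | None], ...], ...]
    truth_indels: tuple[IndelCall, ...]
    seed: int


def _validate_run_dist(run_dist: Mapping[int, float], length: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array(sorted(run_dist), dtype=int)
    probs = np.array([run_dist[int(l)] for l in lengths], dtype=float)
    if (lengths < 1).any():
        raise ConfigError("run lengths must be >= 1")
    if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
        raise ConfigError("run-length probabilities must be non-negative and sum to 1")
    if probs[lengths > length].sum() > 0:
        raise ConfigError("run-length spec puts mass on runs longer than the reference")
    return lengths, probs / probs.sum()


def generate_reference(
    length: int,
    run_dist: Mapping[int, float] | None = None,
    seed: int = DEFAULT_SEED,
) -> str:
    """Random reference built run by run: run lengths are drawn i.i.d. from
    ``run_dist`` and each run's base differs from its predecessor, so the
    realized maximal-run histogram follows the spec up to sampling error and
    the trimmed final run."""
    if length < 1:
        raise ConfigError("reference length must be >= 1")
    dist = DEFAULT_RUN_LENGTH_DIST if run_dist is None else dict(run_dist)
    lengths, probs = _validate_run_dist(dist, length)
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    total = 0
    prev = ""
    while total < length:
        run_len = int(rng.choice(lengths, p=probs))
        choices = [b for b in ALPHABET if b != prev]
        base = choices[int(rng.integers(len(choices)))]
        chunks.append(base * run_len)
        prev = base
        total += run_len
    return "".join(chunks)[:length]


def _clean_deletion_sites(reference: str, size: int, margin: int) -> list[int]:
    """Positions p where deleting reference[p:p+size] anchors cleanly:
    the anchor base, the deleted bases and the right flank are mutually
    distinct, so the event does not left-shift and sits in an hrun-1 context.
    Heterozygous germ-line indels in coding sequence are typically outside
    homopolymers; artifact indels are inside them — planting in clean context
    keeps the two populations distinct, as in real amplicon panels."""
    sites = []
    for p in range(margin, len(reference) - margin - size):
        window = reference[p - 1:p + size + 1]
        if len(set(window)) == len(window):
            sites.append(p)
    return sites


def plant_variants(
    reference: str,
    n_indels: int = 5,
    size_range: tuple[int, int] = (1, 1),
    seed: int = DEFAULT_SEED,
    sample_id: str = "sim",
    spacing: int = 300,
    margin: int = 200,
    kinds: Sequence[str] = ("deletion",),
    homozygous: bool = False,
) -> SimulatedSample:
    """Plant heterozygous indels at uniformly chosen non-repetitive sites.

    Each indel lands on one random haplotype (both, with ``homozygous``).
    Truth records are normalized; anchors are pairwise >= ``spacing`` apart
    and >= ``margin`` from the reference ends.  Defaults plant 1-bp
    deletions, the dominant class of short germ-line indels in coding exons.
    """
    if n_indels < 0:
        raise ConfigError("n_indels must be >= 0")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ConfigError("invalid size_range")
    for k in kinds:
        if k not in ("deletion", "insertion"):
            raise ConfigError(f"unknown indel kind {k!r}")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int, str | None, int]] = []  # (pos, width, ins_seq, hap)
    if n_indels:
        sites = _clean_deletion_sites(reference, hi, margin)
        if not sites:
            raise ConfigError("reference too short or too repetitive for requested planting")
        order = rng.permutation(len(sites))
        for idx in order:
            p = sites[int(idx)]
            if any(abs(p - q) < spacing for q, *_ in chosen):
                continue
            size = int(rng.integers(lo, hi + 1))
            kind = kinds[int(rng.integers(len(kinds)))]
            hap = int(rng.integers(2))
            if kind == "deletion":
                chosen.append((p, -size, None, hap))
            else:
                ins = "".join(ALPHABET[int(rng.integers(4))] for _ in range(size))
                chosen.append((p, size, ins, hap))
            if len(chosen) == n_indels:
                break
        if len(chosen) < n_indels:
            raise ConfigError(
                f"could only place {len(chosen)} of {n_indels} indels with spacing {spacing}"
            )
    chosen.sort()
    truth: list[IndelCall] = []
    hap_events: tuple[list, list] = ([], [])
    for pos, width, ins, hap in chosen:
        if width < 0:
            call = IndelCall(
                chrom="ref",
                pos=pos - 1,
                ref_allele=reference[pos - 1:pos - width],
                alt_allele=reference[pos - 1],
                sample_id=sample_id,
            )
        else:
            call = IndelCall(
                chrom="ref",
                pos=pos,
                ref_allele=reference[pos],
                alt_allele=reference[pos] + ins,
                sample_id=sample_id,
            )
        call = normalize_indel(call, reference)
        truth.append(call)
        targets = (0, 1) if homozygous else (hap,)
        for h in targets:
            hap_events[h].append((pos, width, ins))
    anchors = [t.pos for t in truth]
    if len(set(anchors)) != len(anchors):
        raise ConfigError("planted indels collide after normalization; lower n_indels or raise spacing")
    haplotypes = tuple(
        _apply_events(reference, events) for events in hap_events
    )
    return SimulatedSample(
        sample_id=sample_id,
        haplotypes=haplotypes,  # type: ignore[arg-type]
        hap_events=(tuple(hap_events[0]), tuple(hap_events[1])),
        truth_indels=tuple(truth),
        seed=seed,
    )


def _apply_events(reference: str, events: Sequence[tuple[int, int, str | None]]) -> str:
    out = []
    cursor = 0
    for pos, width, ins in sorted(events):
        if width < 0:
            out.append(reference[cursor:pos])
            cursor = pos - width
        else:
            out.append(reference[cursor:pos + 1])
            out.append(ins)
            cursor = pos + 1
    out.append(reference[cursor:])
    return "".join(out)


def _haplotype_layout(
    reference: str, events: Sequence[tuple[int, int, str | None]]
) -> tuple[str, np.ndarray]:
    """Haplotype sequence plus, per haplotype base, its reference coordinate
    (-1 for inserted bases)."""
    seq_parts: list[str] = []
    coord_parts: list[np.ndarray] = []
    cursor = 0
    for pos, width, ins in sorted(events):
        if width < 0:
            seq_parts.append(reference[cursor:pos])
            coord_parts.append(np.arange(cursor, pos))
            cursor = pos - width
        else:
            seq_parts.append(reference[cursor:pos + 1])
            coord_parts.append(np.arange(cursor, pos + 1))
            seq_parts.append(ins)
            coord_parts.append(np.full(len(ins), -1, dtype=np.int64))
            cursor = pos + 1
    seq_parts.append(reference[cursor:])
    coord_parts.append(np.arange(cursor, len(reference)))
    seq = "".join(seq_parts)
    coords = np.concatenate(coord_parts) if coord_parts else np.arange(len(reference))
    return seq, coords


def _runs(chars: Sequence[str]) -> list[tuple[int, int]]:
    """Maximal (start, length) runs of identical characters."""
    runs = []
    i = 0
    n = len(chars)
    while i < n:
        j = i + 1
        while j < n and chars[j] == chars[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


def _entries_to_read(
    entries: list[tuple[int, str]], read_id: str, mapq: int
) -> AlignedRead | None:
    # drop leading/trailing inserted bases with no flanking match to anchor to
    while entries and entries[0][0] < 0:
        entries.pop(0)
    while entries and entries[-1][0] < 0:
        entries.pop()
    if not entries:
        return None
    ref_start = entries[0][0]
    cigar: list[tuple[str, int]] = []
    seq: list[str] = []
    prev_ref = None
    for ref_pos, base in entries:
        if ref_pos < 0:
            op = ("I", 1)
        else:
            if prev_ref is not None and ref_pos > prev_ref + 1:
                gap = ref_pos - prev_ref - 1
                if cigar and cigar[-1][0] == "D":
                    cigar[-1] = ("D", cigar[-1][1] + gap)
                else:
                    cigar.append(("D", gap))
            op = ("M", 1)
            prev_ref = ref_pos
        if cigar and cigar[-1][0] == op[0]:
            cigar[-1] = (op[0], cigar[-1][1] + op[1])
        else:
            cigar.append(op)
        seq.append(base)
    return AlignedRead(
        read_id=read_id,
        ref_start=ref_start,
        cigar=tuple(cigar),
        mapq=mapq,
        sequence="".join(seq),
    )


def simulate_reads(
    sample: SimulatedSample,
    reference: str,
    coverage: float = 100.0,
    read_length: int = 150,
    model: ErrorModelParams | None = None,
    seed: int = DEFAULT_SEED,
    mapq: int = 60,
) -> list[AlignedRead]:
    """Draw reads uniformly from both haplotypes to a target mean depth and
    inject homopolymer length miscalls.

    Each read is a contiguous haplotype fragment of ``read_length`` bases;
    every maximal run of length L within it is independently miscalled to
    L+-1 with probability ``model.miscall_prob(L)`` (runs truncated by the
    read boundary are seen, and erred, at their truncated length).  Reads are
    emitted pre-aligned: the CIGAR expresses planted indels and injected
    errors against the reference.  Deterministic per seed.
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    model = model or ErrorModelParams()
    if read_length > min(len(h) for h in sample.haplotypes):
        raise ConfigError("read_length exceeds haplotype length")
    rng = np.random.default_rng(seed)
    layouts = [_haplotype_layout(reference, ev) for ev in sample.hap_events]
    n_reads = int(round(coverage * len(reference) / read_length))
    reads: list[AlignedRead] = []
    for i in range(n_reads):
        hap = int(rng.integers(2))
        hap_seq, hap_coords = layouts[hap]
        start = int(rng.integers(0, len(hap_seq) - read_length + 1))
        chars = list(hap_seq[start:start + read_length])
        coords = hap_coords[start:start + read_length].tolist()
        entries = list(zip(coords, chars))
        for run_start, run_len in reversed(_runs(chars)):
            if rng.random() >= model.miscall_prob(run_len):
                continue
            if rng.random() < model.indel_bias:
                del entries[run_start + run_len - 1]  # undercall: drop one base
            else:
                base = chars[run_start]
                entries.insert(run_start + run_len, (-1, base))  # overcall
        read = _entries_to_read(entries, f"{sample.sample_id}:r{i:06d}", mapq)
        if read is not None:
            reads.append(read)
    return reads


def naive_caller(
    reads: Sequence[AlignedRead],
    reference: str,
    min_frac: float = 0.15,
    err: float = 0.01,
    min_support: int = 2,
    sample_id: str = "sample",
    qual_cap: float = 3000.0,
    chrom: str = "ref",
) -> list[IndelCall]:
    """Minimal pileup indel caller over pre-aligned reads.

    Emits a call at every anchor where the modal gap/insert width is supported
    by at least ``min_support`` reads and at least ``min_frac`` of the
    spanning reads.  QUAL is the Phred-scaled binomial tail probability of
    observing that much support from a per-read artifact rate ``err``
    (capped at ``qual_cap``); depth is the count of spanning reads.  Exists
    so the filter stack is exercisable standalone; it is not a production
    caller.
    """
    if not reads:
        return []
    obs = extract_indel_observations(reads, reference)
    if not obs:
        return []
    by_anchor: dict[int, list] = {}
    for o in obs:
        by_anchor.setdefault(o.anchor_pos, []).append(o)
    cov = coverage_array(reads, len(reference))
    calls: list[IndelCall] = []
    ln10 = math.log(10.0)
    for anchor in sorted(by_anchor):
        group = by_anchor[anchor]
        width_counts = Counter(o.signed_width for o in group)
        # modal width; ties broken toward the narrower, deletion-first event
        modal_width, _ = max(
            width_counts.items(), key=lambda kv: (kv[1], -abs(kv[0]), kv[0])
        )
        supporting = {o.read_id for o in group if o.signed_width == modal_width}
        k = len(supporting)
        depth = int(cov[anchor])
        if depth == 0 or k < min_support or k / depth < min_frac:
            continue
        logsf = float(binom.logsf(k - 1, depth, err))
        qual = qual_cap if not math.isfinite(logsf) else min(qual_cap, -10.0 * logsf / ln10)
        anchor_base = reference[anchor]
        if modal_width < 0:
            ref_allele = reference[anchor:anchor - modal_width + 1]
            alt_allele = anchor_base
        else:
            seq_counts = Counter(
                o.inserted_seq for o in group if o.signed_width == modal_width
            )
            ins_seq, _ = max(seq_counts.items(), key=lambda kv: (kv[1], kv[0]))
            ref_allele = anchor_base
            alt_allele = anchor_base + ins_seq
        call = IndelCall(
            chrom=chrom,
            pos=anchor,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            qual=qual,
            depth=depth,
            sample_id=sample_id,
        )
        calls.append(normalize_indel(call, reference))
    return calls
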