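"""Indel call annotation and hard filtering.

Candidate indel calls from any caller are joined to alignment evidence and
scored with two statistics:

* QD (quality by depth) — the caller's Phred-scaled QUAL divided by read depth
  at the site.  Artifact calls ride on few discordant reads and score low QD;
  true heterozygous indels are supported by roughly half the pileup and score
  high.
* VARW — the variance of the signed gap/insert widths observed across reads
  at the call's left-aligned anchor (see :mod:`flowindel.alignment`).
  Homopolymer length miscalls scatter over widths; real indels are reported
  with one consistent width, giving VARW = 0.

A call PASSes a threshold profile iff ``qd >= qd_th`` and ``varw <= varw_th``
(boundaries inclusive, so the published profiles with ``varw_th = 0`` keep a
call whose reads all agree).  QUAL scales are caller-specific, so thresholds
live in named profiles rather than global defaults: the bundled ``gatk``
(2.5 / 0) and ``samtools`` (1 / 0) profiles carry the values tuned for those
callers on PGM amplicon data, and ``naive`` (3 / 0.5) matches the binomial
QUAL scale of :func:`flowindel.simulate.naive_caller`.

A third, cross-sample rule targets recurrent systematic artifacts: a PASS
call in one sample is demoted when the identical indel sits in the
threshold-failed set of any other sample.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .alignment import AlignedRead, compute_hrun, gather_locus_evidence
from .errors import ConfigError, ContractError, EvidenceError, SchemaError

PASS = "PASS"
FAIL_QD = "fail_qd"
FAIL_VARW = "fail_varw"
FAIL_RECURRENT = "fail_recurrent"

_STATUSES = frozenset({PASS, FAIL_QD, FAIL_VARW, FAIL_RECURRENT})


@dataclass
class IndelCall:
    """One candidate or truth indel.

    ``pos`` is the 0-based coordinate of the anchor base (the single shared
    base of the normalized allele pair); VCF 1-based POS appears only at I/O.
    ``qual`` may be ``None`` for truth records that never carried a score.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float | None = None
    depth: int | None = None
    qd: float | None = None
    varw: float | None = None
    baf: float | None = None
    hrun: int | None = None
    sample_id: str = "sample"
    filter_status: str = PASS
    depth_source: str | None = None
    annotated: bool = False

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise SchemaError(f"{self.locus_label()}: empty allele")
        if self.ref_allele == self.alt_allele:
            raise SchemaError(f"{self.locus_label()}: ref and alt alleles identical")
        if self.qual is not None and self.qual < 0:
            raise SchemaError(f"{self.locus_label()}: negative QUAL")
        if self.filter_status not in _STATUSES:
            raise SchemaError(f"{self.locus_label()}: unknown filter status {self.filter_status!r}")

    def locus_label(self) -> str:
        return f"{self.chrom}:{self.pos + 1}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Sample-agnostic identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def indel_length(self) -> int:
        """Signed width: +k insertion, -k deletion."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_normalized_indel(self) -> bool:
        """Minimal left-anchored representation: exactly one allele of length 1."""
        return (len(self.ref_allele) == 1) != (len(self.alt_allele) == 1)


@dataclass(frozen=True)
class FilterThresholds:
    """Caller-specific QD/VARW thresholds (PASS: qd >= qd_th, varw <= varw_th)."""

    qd_th: float
    varw_th: float
    profile_name: str = "custom"

    def __post_init__(self) -> None:
        if self.qd_th < 0 or self.varw_th < 0:
            raise ConfigError("thresholds must be non-negative")


BUILTIN_PROFILES: dict[str, FilterThresholds] = {
    "gatk": FilterThresholds(qd_th=2.5, varw_th=0.0, profile_name="gatk"),
    "samtools": FilterThresholds(qd_th=1.0, varw_th=0.0, profile_name="samtools"),
    # Calibrated to naive_caller's binomial QUAL scale and the +-1 miscall
    # model: artifact QD stays below ~2.2 while heterozygous indels score >~5,
    # and mixed-direction artifact VARW ~ 4*bias*(1-bias) ~ 0.84 sits well
    # above the <=4/n variance a single discordant read induces at a true
    # locus with n supporting observations.
    "naive": FilterThresholds(qd_th=3.0, varw_th=0.5, profile_name="naive"),
}


def load_profiles(path=None) -> dict[str, FilterThresholds]:
    """Built-in profiles, optionally extended/overridden from an INI-style
    key-value file::

        [mycaller]
        qd_th = 2.0
        varw_th = 0
    """
    profiles = dict(BUILTIN_PROFILES)
    if path is None:
        return profiles
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError(f"cannot read profile config {path}")
    for name in parser.sections():
        sect = parser[name]
        try:
            profiles[name] = FilterThresholds(
                qd_th=float(sect["qd_th"]),
                varw_th=float(sect["varw_th"]),
                profile_name=name,
            )
        except KeyError as exc:
            raise ConfigError(f"profile {name!r} missing key {exc}") from exc
    return profiles


def compute_qd(qual: float, depth: int) -> float:
    """Quality by depth: QUAL / depth."""
    if depth is None or depth <= 0:
        raise EvidenceError("QD undefined at zero depth")
    if qual is None or qual < 0:
        raise SchemaError("QD needs a non-negative QUAL")
    return qual / depth


def normalize_indel(call: IndelCall, reference: str) -> IndelCall:
    """Left-aligned minimal representation of an indel call.

    Shared trailing bases are trimmed (extending left through repeats as
    needed), then shared leading bases are trimmed down to a single anchor
    base.  Idempotent; raises when the REF allele disagrees with the
    reference sequence or the record is not a simple indel.
    """
    pos, ref, alt = call.pos, call.ref_allele.upper(), call.alt_allele.upper()
    if pos < 0 or pos + len(ref) > len(reference):
        raise ContractError(f"{call.locus_label()}: allele outside reference")
    if reference[pos:pos + len(ref)].upper() != ref:
        raise ContractError(
            f"{call.locus_label()}: REF allele {ref} disagrees with reference "
            f"{reference[pos:pos + len(ref)]}"
        )
    if len(ref) == len(alt):
        raise SchemaError(f"{call.locus_label()}: not an indel (equal allele lengths)")
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > 0:
            base = reference[pos - 1].upper()
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    out = replace(call, pos=pos, ref_allele=ref, alt_allele=alt)
    if not out.is_normalized_indel:
        raise SchemaError(f"{call.locus_label()}: complex variant cannot be normalized to an indel")
    return out


def annotate_calls(
    calls: Sequence[IndelCall],
    reads: Sequence[AlignedRead],
    reference: str,
    *,
    window: int = 0,
) -> list[IndelCall]:
    """Join calls to alignment evidence: populate qd, varw, baf, hrun.

    Depth for QD comes from the call record when present (``depth_source``
    "vcf"), otherwise from the pileup ("alignments").  BAF and VARW are always
    alignment-derived.  Calls at loci no read spans raise
    :class:`~flowindel.errors.EvidenceError` rather than receiving silent
    defaults.
    """
    for call in calls:
        if call.qual is None:
            raise SchemaError(f"{call.locus_label()}: missing QUAL; call cannot be scored")
        if not call.is_normalized_indel:
            raise ContractError(f"{call.locus_label()}: call is not a normalized indel")
    evidence = gather_locus_evidence(
        reads, reference, sorted({c.pos for c in calls}), window=window
    )
    out = []
    for call in calls:
        ev = evidence[call.pos]
        if call.depth is not None and call.depth > 0:
            depth, source = call.depth, "vcf"
        else:
            depth, source = ev.depth, "alignments"
        out.append(
            replace(
                call,
                depth=depth,
                depth_source=source,
                qd=compute_qd(call.qual, depth),
                varw=ev.varw,
                baf=ev.baf,
                hrun=ev.hrun,
                annotated=True,
            )
        )
    return out


def apply_thresholds(
    calls: Sequence[IndelCall], thresholds: FilterThresholds
) -> list[IndelCall]:
    """Set PASS/fail_qd/fail_varw on every call; cardinality preserved.

    PASS requires ``qd >= qd_th`` and ``varw <= varw_th`` (inclusive).  A call
    with undefined VARW — no read-level gap/insert at its anchor — fails the
    VARW filter: a called indel with zero alignment support is suspect.
    """
    out = []
    for call in calls:
        if not call.annotated or call.qd is None:
            raise ContractError(f"{call.locus_label()}: call not annotated; run annotate_calls first")
        if call.qd < thresholds.qd_th:
            status = FAIL_QD
        elif call.varw is None or call.varw > thresholds.varw_th:
            status = FAIL_VARW
        else:
            status = PASS
        out.append(replace(call, filter_status=status))
    return out


def cross_sample_filter(
    per_sample_pass: Mapping[str, Sequence[IndelCall]],
    per_sample_fail: Mapping[str, Sequence[IndelCall]],
) -> dict[str, list[IndelCall]]:
    """Demote recurrent artifacts escaping the thresholds in one sample.

    A PASS call in sample *s* becomes ``fail_recurrent`` iff its identity key
    (chrom, pos, ref, alt) appears in the threshold-failed set of at least one
    *other* sample.  Returns per-sample call lists (demoted PASS calls plus
    the unchanged failed calls).  Order-independent in sample iteration.
    """
    fail_keys: dict[str, set] = {}
    for sample, fails in per_sample_fail.items():
        fail_keys[sample] = {c.key for c in fails}
    out: dict[str, list[IndelCall]] = {}
    for sample, passes in per_sample_pass.items():
        seen = set()
        for c in passes:
            if c.key in seen:
                raise SchemaError(
                    f"sample {sample}: duplicate PASS call {c.locus_label()} {c.ref_allele}>{c.alt_allele}"
                )
            seen.add(c.key)
        other_fail: set = set()
        for s, keys in fail_keys.items():
            if s != sample:
                other_fail |= keys
        demoted = [
            replace(c, filter_status=FAIL_RECURRENT) if c.key in other_fail else replace(c)
            for c in passes
        ]
        out[sample] = demoted + [replace(c) for c in per_sample_fail.get(sample, [])]
    return out
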