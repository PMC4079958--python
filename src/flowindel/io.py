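"""Format plumbing: FASTA, SAM, VCF, BED, FASTQ and the run manifest.

VCF is the interchange format between pipeline stages.  Annotations are
written as INFO keys ``DP, DPSRC, QD, VARW, BAF, HRUN``; filter outcomes go
to FILTER as ``qd_th`` / ``varw_th`` / ``recurrent`` (PASS otherwise).
Coordinates are 1-based in VCF/SAM files and 0-based half-open everywhere
else (BED is already 0-based half-open).
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import pysam

from .alignment import AlignedRead
from .errors import SchemaError, ValidationError
from .evaluation import CallableRegion
from .filtering import (
    FAIL_QD,
    FAIL_RECURRENT,
    FAIL_VARW,
    PASS,
    IndelCall,
)

_STATUS_TO_FILTER = {
    PASS: "PASS",
    FAIL_QD: "qd_th",
    FAIL_VARW: "varw_th",
    FAIL_RECURRENT: "recurrent",
}
_FILTER_TO_STATUS = {v: k for k, v in _STATUS_TO_FILTER.items()}

_CIGAR_CODES = {"M": 0, "I": 1, "D": 2, "S": 4, "=": 7, "X": 8}


# ---------------------------------------------------------------- FASTA

def write_fasta(path, name: str, sequence: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """All contigs of a FASTA file as {name: sequence}."""
    with pysam.FastxFile(str(path)) as fx:
        return {entry.name: entry.sequence for entry in fx}


# ------------------------------------------------------------------ SAM

def write_sam(path, reads: Sequence[AlignedRead], ref_name: str, ref_length: int,
              sample_id: str = "sample") -> None:
    """Coordinate-sorted single-contig SAM with one read group per sample."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref_name, "LN": ref_length}],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in sorted(reads, key=lambda r: (r.ref_start, r.read_id)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.read_id
            seg.query_sequence = read.sequence
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = read.ref_start
            seg.mapping_quality = read.mapq
            seg.cigartuples = [(_CIGAR_CODES[op], n) for op, n in read.cigar]
            seg.set_tag("RG", sample_id)
            out.write(seg)


def read_sam(path) -> tuple[list[AlignedRead], dict[str, int]]:
    """Mapped primary reads plus contig lengths from a SAM/BAM file."""
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        contigs = dict(zip(fh.references, fh.lengths))
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            reads.append(AlignedRead.from_pysam(aln))
    return reads, contigs


# ------------------------------------------------------------------ VCF

def _vcf_header(contigs: Mapping[str, int], annotated: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Read depth at the call locus")
    if annotated:
        header.info.add("DPSRC", 1, "String", "Depth source: vcf or alignments")
        header.info.add("QD", 1, "Float", "Quality by depth (QUAL/DP)")
        header.info.add("VARW", 1, "Float",
                        "Variance of gap/insert widths across reads at the anchor")
        header.info.add("BAF", 1, "Float", "Fraction of spanning reads with the non-reference allele")
        header.info.add("HRUN", 1, "Integer", "Reference homopolymer run length at the anchor")
        header.filters.add("qd_th", None, None, "QD below the profile threshold")
        header.filters.add("varw_th", None, None,
                           "VARW above the profile threshold, or no read-level indel evidence")
        header.filters.add("recurrent", None, None,
                           "Indel present in the threshold-failed set of another sample")
    return header


def write_vcf(path, calls: Sequence[IndelCall], contigs: Mapping[str, int],
              annotated: bool = False) -> None:
    """Site-only VCF (1-based POS = anchor + 1)."""
    header = _vcf_header(contigs, annotated)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt_allele)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                alleles=(call.ref_allele, call.alt_allele),
            )
            if call.qual is not None:
                rec.qual = call.qual
            if call.depth is not None:
                rec.info["DP"] = call.depth
            if annotated:
                if call.depth_source is not None:
                    rec.info["DPSRC"] = call.depth_source
                if call.qd is not None:
                    rec.info["QD"] = call.qd
                if call.varw is not None:
                    rec.info["VARW"] = call.varw
                if call.baf is not None:
                    rec.info["BAF"] = call.baf
                if call.hrun is not None:
                    rec.info["HRUN"] = call.hrun
                rec.filter.add(_STATUS_TO_FILTER[call.filter_status])
            out.write(rec)


def read_vcf(path, sample_id: str = "sample") -> tuple[list[IndelCall], int]:
    """Read indel records; multi-allelic sites are split into biallelic
    calls.  Returns (calls, number of skipped non-indel alleles)."""
    calls: list[IndelCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            if rec.alts is None:
                skipped += 1
                continue
            for alt in rec.alts:
                if (
                    alt is None
                    or not alt.strip("ACGTNacgtn") == ""
                    or "<" in alt
                    or len(alt) == len(rec.ref)
                ):
                    skipped += 1
                    continue
                info = dict(rec.info)
                status = PASS
                filters = list(rec.filter.keys())
                for f in filters:
                    if f in _FILTER_TO_STATUS and f != "PASS":
                        status = _FILTER_TO_STATUS[f]
                        break
                varw = info.get("VARW")
                calls.append(
                    IndelCall(
                        chrom=rec.chrom,
                        pos=rec.start,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        qual=rec.qual,
                        depth=info.get("DP"),
                        qd=info.get("QD"),
                        varw=float(varw) if varw is not None else None,
                        baf=info.get("BAF"),
                        hrun=info.get("HRUN"),
                        sample_id=sample_id,
                        filter_status=status,
                        depth_source=info.get("DPSRC"),
                        annotated="QD" in info,
                    )
                )
    return calls, skipped


# ------------------------------------------------------------------ BED

def read_bed(path) -> CallableRegion:
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{line_no}: BED line needs >= 3 fields")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    if not intervals:
        raise ValidationError(f"{path}: no intervals")
    return CallableRegion.from_intervals(intervals)


def write_bed(path, regions: CallableRegion) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------- FASTQ

def write_fastq(path, reads: Iterable[AlignedRead], quality_char: str = "I") -> None:
    """Reads as plain FASTQ (constant base quality) for users who want to
    run a real mapper on the simulated data."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{quality_char * len(read.sequence)}\n")


# -------------------------------------------------------------- manifest

def write_manifest(path, params: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(dict(params), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
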