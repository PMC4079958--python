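"""Benchmarking call sets against a truth set with per-base accounting.

Amplicon validation studies report specificity over *bases*, not variants:
every base of the callable target (per sample) is a trial, each indel event —
true or called — occupies exactly one base at its left-aligned anchor, and
the vast remainder are true negatives.  With N samples over a callable target
of B bases the confusion matrix must satisfy tp + fp + fn + tn = N x B.

Metrics follow the usual definitions

    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    FDR         = fp / (fp + tp)

with a metric reported as NA (never 0) when its denominator is empty.
Confidence intervals are exact Clopper-Pearson by default (Wilson score
available); displayed percentages round half-up to two decimals with
trailing zeros trimmed, the convention of clinical validation tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .errors import ContractError, EvidenceError, SchemaError
from .filtering import IndelCall


@dataclass(frozen=True)
class CallableRegion:
    """Merged half-open intervals per contig over which calls are evaluated."""

    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_intervals(cls, raw: Iterable[tuple[str, int, int]]) -> "CallableRegion":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in raw:
            if start < 0 or end < start:
                raise SchemaError(f"bad interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        return cls(intervals=tuple(merged))

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in self.intervals)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def match_calls(
    calls: Sequence[IndelCall],
    truth: Sequence[IndelCall],
    regions: CallableRegion,
) -> tuple[list[IndelCall], list[IndelCall], list[IndelCall]]:
    """Exact-identity matching of normalized calls against normalized truth.

    Calls (and truth records) outside the callable regions are excluded before
    matching.  Identity is the full key (chrom, pos, ref, alt): a call at a
    truth anchor with a different allele counts as one FP plus one FN.
    Returns disjoint, exhaustive (tp, fp, fn) lists.
    """
    for rec in list(calls) + list(truth):
        if not rec.is_normalized_indel:
            raise ContractError(
                f"{rec.locus_label()}: record {rec.ref_allele}>{rec.alt_allele} is not normalized"
            )
    calls_in = [c for c in calls if regions.contains(c.chrom, c.pos)]
    truth_in = [t for t in truth if regions.contains(t.chrom, t.pos)]
    call_keys = [c.key for c in calls_in]
    if len(set(call_keys)) != len(call_keys):
        raise SchemaError("duplicate identity keys in call set")
    truth_keys = {t.key for t in truth_in}
    tp = [c for c in calls_in if c.key in truth_keys]
    fp = [c for c in calls_in if c.key not in truth_keys]
    matched = {c.key for c in tp}
    fn = [t for t in truth_in if t.key not in matched]
    return tp, fp, fn


def _count(x) -> int:
    return x if isinstance(x, int) else len(x)


def confusion_counts(
    tp_set, fp_set, fn_set, regions: CallableRegion, n_samples: int
) -> ConfusionMatrix:
    """Per-base confusion matrix over ``n_samples`` copies of the callable
    target.  Each event occupies one base; everything else is a true negative.
    """
    tp, fp, fn = _count(tp_set), _count(fp_set), _count(fn_set)
    total = n_samples * regions.total_bases
    tn = total - tp - fp - fn
    if tn < 0:
        raise ContractError(
            f"event counts ({tp + fp + fn}) exceed callable bases ({total})"
        )
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def binomial_ci(
    successes: int,
    trials: int,
    confidence: float = 0.95,
    method: str = "clopper-pearson",
) -> tuple[float, float]:
    """Binomial proportion confidence interval.

    ``clopper-pearson`` (default) is the exact beta-quantile interval:
    lower = 0 at zero successes and upper = 1 when all trials succeed.
    ``wilson`` is the score interval.
    """
    if trials < 1:
        raise EvidenceError("CI undefined for zero trials")
    if not (0 <= successes <= trials):
        raise ContractError("successes outside [0, trials]")
    alpha = 1.0 - confidence
    if method == "clopper-pearson":
        lo = 0.0 if successes == 0 else float(
            beta_dist.ppf(alpha / 2, successes, trials - successes + 1)
        )
        hi = 1.0 if successes == trials else float(
            beta_dist.ppf(1 - alpha / 2, successes + 1, trials - successes)
        )
        return lo, hi
    if method == "wilson":
        z = float(norm.ppf(1 - alpha / 2))
        p = successes / trials
        denom = 1 + z * z / trials
        centre = (p + z * z / (2 * trials)) / denom
        half = z * ((p * (1 - p) / trials + z * z / (4 * trials * trials)) ** 0.5) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ContractError(f"unknown CI method {method!r}")


@dataclass(frozen=True)
class MetricValue:
    """A proportion with its CI; ``estimate`` is None when the denominator
    is empty (reported NA, never 0)."""

    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    def percent(self) -> str:
        if self.estimate is None:
            return "NA"
        return format_percent(self.estimate)


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: MetricValue
    specificity: MetricValue
    fdr: MetricValue
    counts: ConfusionMatrix

    def to_dict(self) -> dict:
        def mv(m: MetricValue) -> dict:
            return {
                "estimate": m.estimate,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "numerator": m.numerator,
                "denominator": m.denominator,
                "percent": m.percent(),
            }

        return {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "sensitivity": mv(self.sensitivity),
            "specificity": mv(self.specificity),
            "fdr": mv(self.fdr),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        def mv(x: dict) -> MetricValue:
            return MetricValue(
                estimate=x["estimate"],
                ci_low=x["ci_low"],
                ci_high=x["ci_high"],
                numerator=x["numerator"],
                denominator=x["denominator"],
            )

        c = d["counts"]
        return cls(
            sensitivity=mv(d["sensitivity"]),
            specificity=mv(d["specificity"]),
            fdr=mv(d["fdr"]),
            counts=ConfusionMatrix(tp=c["tp"], fp=c["fp"], fn=c["fn"], tn=c["tn"]),
        )


def _metric(num: int, den: int, confidence: float, method: str) -> MetricValue:
    if den == 0:
        return MetricValue(None, None, None, num, den)
    lo, hi = binomial_ci(num, den, confidence, method)
    return MetricValue(num / den, lo, hi, num, den)


def compute_metrics(
    cm: ConfusionMatrix,
    confidence: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> MetricsReport:
    """Sensitivity, specificity and FDR with CIs from a confusion matrix."""
    return MetricsReport(
        sensitivity=_metric(cm.tp, cm.tp + cm.fn, confidence, ci_method),
        specificity=_metric(cm.tn, cm.tn + cm.fp, confidence, ci_method),
        fdr=_metric(cm.fp, cm.fp + cm.tp, confidence, ci_method),
        counts=cm,
    )


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Display a fraction as a percentage, half-up at ``decimals`` places,
    trailing zeros trimmed: 0.625 -> '62.5%', 2/3 -> '66.67%', 1.0 -> '100%'.

    A proportion strictly below 1 never displays as 100%: when rounding
    would reach 100 it is floored instead (96134/96135 -> '99.99%'), the
    convention of clinical validation tables, which reserve 100% for a
    literally error-free count.
    """
    q = Decimal(1).scaleb(-decimals)
    exact = Decimal(repr(fraction)) * 100
    val = exact.quantize(q, rounding=ROUND_HALF_UP)
    if val == 100 and fraction < 1:
        val = exact.quantize(q, rounding=ROUND_FLOOR)
    text = format(val.normalize(), "f")
    return f"{text}%"


def hrun_stratify(
    fp_set: Sequence[IndelCall], hrun_threshold: int = 4
) -> tuple[int, int]:
    """Partition false positives into homopolymer-associated (hrun >=
    threshold) and other; counts sum to len(fp_set)."""
    if hrun_threshold < 1:
        raise ContractError("hrun threshold must be >= 1")
    hi = lo = 0
    for call in fp_set:
        if call.hrun is None:
            raise ContractError(f"{call.locus_label()}: missing hrun annotation")
        if call.hrun >= hrun_threshold:
            hi += 1
        else:
            lo += 1
    return hi, lo


def write_report(
    prefix: str,
    report: MetricsReport,
    fp_calls: Sequence[IndelCall] = (),
    hrun_threshold: int = 4,
) -> tuple[str, str]:
    """Write ``<prefix>.json`` and ``<prefix>.tsv`` (plus the per-FP HRun
    table appended to the TSV).  Returns the two paths."""
    json_path, tsv_path = f"{prefix}.json", f"{prefix}.tsv"
    payload = report.to_dict()
    if fp_calls:
        hi, lo = hrun_stratify(fp_calls, hrun_threshold)
        payload["fp_hrun"] = {
            "threshold": hrun_threshold,
            "homopolymer": hi,
            "other": lo,
        }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(tsv_path, "w") as fh:
        fh.write("metric\testimate\tci_low\tci_high\tnumerator\tdenominator\tpercent\n")
        for name in ("sensitivity", "specificity", "fdr"):
            m: MetricValue = getattr(report, name)
            est = "NA" if m.estimate is None else f"{m.estimate:.6g}"
            lo_ = "NA" if m.ci_low is None else f"{m.ci_low:.6g}"
            hi_ = "NA" if m.ci_high is None else f"{m.ci_high:.6g}"
            fh.write(f"{name}\t{est}\t{lo_}\t{hi_}\t{m.numerator}\t{m.denominator}\t{m.percent()}\n")
        fh.write(
            f"counts\ttp={report.counts.tp}\tfp={report.counts.fp}\t"
            f"fn={report.counts.fn}\ttn={report.counts.tn}\t-\t-\n"
        )
        if fp_calls:
            fh.write("\n# false positives by homopolymer run length\n")
            fh.write("chrom\tpos\tref\talt\thrun\tqd\tvarw\n")
            for c in sorted(fp_calls, key=lambda c: c.key):
                qd = "NA" if c.qd is None else f"{c.qd:.6g}"
                varw = "NA" if c.varw is None else f"{c.varw:.6g}"
                fh.write(
                    f"{c.chrom}\t{c.pos + 1}\t{c.ref_allele}\t{c.alt_allele}\t"
                    f"{c.hrun}\t{qd}\t{varw}\n"
                )
    return json_path, tsv_path
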