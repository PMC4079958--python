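"""Call annotation, threshold filtering, normalization and the cross-sample
recurrence rule."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flowindel.errors import (
    ConfigError,
    ContractError,
    EvidenceError,
    SchemaError,
)
from flowindel.filtering import (
    BUILTIN_PROFILES,
    FAIL_QD,
    FAIL_RECURRENT,
    FAIL_VARW,
    PASS,
    FilterThresholds,
    IndelCall,
    annotate_calls,
    apply_thresholds,
    compute_qd,
    cross_sample_filter,
    load_profiles,
    normalize_indel,
)

from conftest import read_from_ref


def make_call(pos=0, ref="AT", alt="A", chrom="ref", sample="s1", **kw):
    return IndelCall(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt, **kw,
                     sample_id=sample)


def annotated_call(qd, varw, **kw):
    return make_call(qual=qd * 10, depth=10, qd=qd, varw=varw, baf=0.5, hrun=1,
                     annotated=True, **kw)


# -------------------------------------------------------------------- QD

@pytest.mark.parametrize("qual,depth,expected", [(50, 20, 2.5), (0, 10, 0.0)])
def test_qd_division(qual, depth, expected):
    assert compute_qd(qual, depth) == expected


def test_qd_zero_depth_is_an_error():
    with pytest.raises(EvidenceError):
        compute_qd(100, 0)


# ----------------------------------------------------------- normalization

def brute_force_leftmost_indel(reference, pos, ref, alt):
    """Enumerate every placement of the same net edit and return the leftmost
    minimal (pos, ref, alt)."""
    mutated = reference[:pos] + alt + reference[pos + len(ref):]
    best = None
    size = abs(len(ref) - len(alt))
    if len(ref) > len(alt):  # deletion of `size` bases
        for s in range(len(reference) - size + 1):
            if reference[:s] + reference[s + size:] == mutated:
                best = (s - 1, reference[s - 1:s + size], reference[s - 1])
                break
    else:  # insertion of `size` bases
        for s in range(len(reference) + 1):
            for_ins = mutated[s:s + size]
            if reference[:s] + for_ins + reference[s:] == mutated:
                best = (s - 1, reference[s - 1], reference[s - 1] + for_ins)
                break
    return best


def test_normalize_repeat_deletion():
    # CAAAT, deletion of one A written at the right end of the run
    call = make_call(pos=2, ref="AA", alt="A")
    out = normalize_indel(call, "CAAAT")
    assert (out.pos, out.ref_allele, out.alt_allele) == (0, "CA", "C")


def test_normalize_idempotent():
    call = make_call(pos=0, ref="CA", alt="C")
    once = normalize_indel(call, "CAAAT")
    twice = normalize_indel(once, "CAAAT")
    assert (once.pos, once.ref_allele, once.alt_allele) == (
        twice.pos, twice.ref_allele, twice.alt_allele
    )


def test_normalize_non_repetitive_insertion_unchanged():
    call = make_call(pos=1, ref="C", alt="CTG")
    out = normalize_indel(call, "ACGT")
    assert (out.pos, out.ref_allele, out.alt_allele) == (1, "C", "CTG")


def test_normalize_rejects_reference_mismatch():
    with pytest.raises(ContractError):
        normalize_indel(make_call(pos=0, ref="TT", alt="T"), "CAAAT")


@given(st.data())
def test_normalize_matches_enumeration_oracle(data):
    reference = data.draw(st.text(alphabet="ACG", min_size=8, max_size=20))
    size = data.draw(st.integers(1, 2))
    pos = data.draw(st.integers(2, len(reference) - size - 1))
    if data.draw(st.booleans(), label="is_deletion"):
        call = make_call(pos=pos - 1,
                         ref=reference[pos - 1:pos + size],
                         alt=reference[pos - 1])
    else:
        ins = data.draw(st.text(alphabet="ACG", min_size=size, max_size=size))
        call = make_call(pos=pos, ref=reference[pos], alt=reference[pos] + ins)
    expected = brute_force_leftmost_indel(
        reference, call.pos, call.ref_allele, call.alt_allele
    )
    if expected is None or expected[0] < 0:
        return  # event slides off the contig start; covered by bounds tests
    out = normalize_indel(call, reference)
    assert (out.pos, out.ref_allele, out.alt_allele) == expected
    again = normalize_indel(out, reference)
    assert (again.pos, again.ref_allele, again.alt_allele) == expected


# -------------------------------------------------------------- annotation

def test_annotate_populates_evidence(flat_reference, pileup_reads):
    call = make_call(pos=49, ref=flat_reference[49:51], alt=flat_reference[49],
                     qual=300.0)
    (out,) = annotate_calls([call], pileup_reads, flat_reference)
    assert out.annotated
    assert out.depth == 100 and out.depth_source == "alignments"
    assert out.qd == pytest.approx(3.0)
    assert out.varw == 0.0
    assert out.baf == pytest.approx(0.5)
    assert out.hrun == 1


def test_annotate_prefers_vcf_depth(flat_reference, pileup_reads):
    call = make_call(pos=49, ref=flat_reference[49:51], alt=flat_reference[49],
                     qual=300.0, depth=60)
    (out,) = annotate_calls([call], pileup_reads, flat_reference)
    assert out.depth == 60 and out.depth_source == "vcf"
    assert out.qd == pytest.approx(5.0)


def test_annotate_mixed_widths_give_varw(flat_reference):
    reads = [
        read_from_ref(flat_reference, 0, [("M", 50), ("D", 1), ("M", 30)], read_id="a"),
        read_from_ref(flat_reference, 0, [("M", 51), ("I", flat_reference[50]), ("M", 30)], read_id="b"),
    ]
    # duplicating base 50 left-aligns to anchor 49, same as deleting base 50
    call = make_call(pos=49, ref=flat_reference[49:51], alt=flat_reference[49], qual=10.0)
    (out,) = annotate_calls([call], reads, flat_reference)
    assert out.varw == pytest.approx(1.0)  # widths {-1, +1}


def test_annotate_missing_qual_is_schema_error(flat_reference, pileup_reads):
    call = make_call(pos=49, ref=flat_reference[49:51], alt=flat_reference[49])
    with pytest.raises(SchemaError):
        annotate_calls([call], pileup_reads, flat_reference)


def test_annotate_uncovered_locus_raises(flat_reference, pileup_reads):
    call = make_call(pos=200, ref=flat_reference[200:202], alt=flat_reference[200],
                     qual=50.0)
    with pytest.raises(EvidenceError):
        annotate_calls([call], pileup_reads, flat_reference)


# -------------------------------------------------------------- thresholds

def test_published_profiles():
    assert BUILTIN_PROFILES["gatk"].qd_th == 2.5
    assert BUILTIN_PROFILES["gatk"].varw_th == 0.0
    assert BUILTIN_PROFILES["samtools"].qd_th == 1.0
    assert BUILTIN_PROFILES["samtools"].varw_th == 0.0


def test_thresholds_are_inclusive_boundaries():
    call = annotated_call(qd=2.5, varw=0.0)
    (out,) = apply_thresholds([call], BUILTIN_PROFILES["gatk"])
    assert out.filter_status == PASS


@pytest.mark.parametrize(
    "qd,varw,expected",
    [
        (0.4, 0.0, FAIL_QD),
        (5.0, 0.25, FAIL_VARW),
        (0.4, 0.25, FAIL_QD),  # QD failure reported first
        (1.0, 0.0, PASS),
    ],
)
def test_threshold_outcomes_samtools_profile(qd, varw, expected):
    (out,) = apply_thresholds([annotated_call(qd=qd, varw=varw)],
                              BUILTIN_PROFILES["samtools"])
    assert out.filter_status == expected


def test_undefined_varw_fails_filter():
    (out,) = apply_thresholds([annotated_call(qd=5.0, varw=None)],
                              BUILTIN_PROFILES["samtools"])
    assert out.filter_status == FAIL_VARW


def test_unannotated_call_rejected():
    with pytest.raises(ContractError):
        apply_thresholds([make_call(qual=10.0)], BUILTIN_PROFILES["gatk"])


def test_filtering_preserves_cardinality_and_partitions():
    rng = np.random.default_rng(11)
    calls = [
        annotated_call(qd=float(rng.uniform(0, 5)), varw=float(rng.uniform(0, 1)),
                       pos=i * 10)
        for i in range(50)
    ]
    out = apply_thresholds(calls, FilterThresholds(2.0, 0.3))
    assert len(out) == len(calls)
    assert {c.filter_status for c in out} <= {PASS, FAIL_QD, FAIL_VARW}
    for before, after in zip(calls, out):
        assert before.key == after.key


@given(
    st.lists(
        st.tuples(st.floats(0, 10), st.floats(0, 2)), min_size=1, max_size=40
    ),
    st.floats(0, 10),
    st.floats(0, 10),
    st.floats(0, 2),
)
def test_pass_count_monotone_in_thresholds(calls_qv, qd_a, qd_b, varw_th):
    """Raising qd_th never increases PASS; raising varw_th never decreases."""
    calls = [
        annotated_call(qd=qd, varw=vw, pos=i * 5)
        for i, (qd, vw) in enumerate(calls_qv)
    ]
    lo, hi = sorted([qd_a, qd_b])
    n_lo = sum(
        c.filter_status == PASS
        for c in apply_thresholds(calls, FilterThresholds(lo, varw_th))
    )
    n_hi = sum(
        c.filter_status == PASS
        for c in apply_thresholds(calls, FilterThresholds(hi, varw_th))
    )
    assert n_hi <= n_lo
    n_wider = sum(
        c.filter_status == PASS
        for c in apply_thresholds(calls, FilterThresholds(lo, varw_th + 0.5))
    )
    assert n_wider >= n_lo


# ----------------------------------------------------------- cross-sample

def test_recurrent_call_demoted():
    x = annotated_call(qd=3.0, varw=0.0, pos=10, sample="A")
    x_fail_b = annotated_call(qd=0.2, varw=0.0, pos=10, sample="B",
                              filter_status=FAIL_QD)
    out = cross_sample_filter({"A": [x], "B": []}, {"A": [], "B": [x_fail_b]})
    assert out["A"][0].filter_status == FAIL_RECURRENT


def test_unique_pass_call_retained():
    y = annotated_call(qd=3.0, varw=0.0, pos=20, sample="A")
    out = cross_sample_filter({"A": [y], "B": []}, {"A": [], "B": []})
    assert out["A"][0].filter_status == PASS


def test_own_failed_set_does_not_demote():
    x_fail_a = annotated_call(qd=0.2, varw=0.0, pos=10, sample="A",
                              filter_status=FAIL_QD)
    out = cross_sample_filter({"A": [], "B": []}, {"A": [x_fail_a], "B": []})
    assert all(c.filter_status != FAIL_RECURRENT for c in out["A"])
    assert len(out["A"]) == 1


def test_cross_sample_order_independent_and_subset():
    calls = {
        s: [annotated_call(qd=3.0, varw=0.0, pos=p, sample=s) for p in ps]
        for s, ps in [("A", [10, 20]), ("B", [10, 30]), ("C", [40])]
    }
    fails = {
        "A": [annotated_call(qd=0.1, varw=0.0, pos=30, sample="A", filter_status=FAIL_QD)],
        "B": [],
        "C": [annotated_call(qd=0.1, varw=0.0, pos=10, sample="C", filter_status=FAIL_QD)],
    }
    out1 = cross_sample_filter(calls, fails)
    reversed_calls = dict(reversed(list(calls.items())))
    reversed_fails = dict(reversed(list(fails.items())))
    out2 = cross_sample_filter(reversed_calls, reversed_fails)
    for s in calls:
        st1 = sorted((c.key, c.filter_status) for c in out1[s])
        st2 = sorted((c.key, c.filter_status) for c in out2[s])
        assert st1 == st2
        passed = {c.key for c in out1[s] if c.filter_status == PASS}
        assert passed <= {c.key for c in calls[s]}
    # A's PASS at pos 10 demoted (C failed it); B's at 30 demoted (A failed it)
    assert dict(sorted((c.pos, c.filter_status) for c in out1["A"]))[10] == FAIL_RECURRENT
    assert dict(sorted((c.pos, c.filter_status) for c in out1["B"]))[30] == FAIL_RECURRENT


def test_duplicate_pass_keys_rejected():
    dup = annotated_call(qd=3.0, varw=0.0, pos=10, sample="A")
    with pytest.raises(SchemaError):
        cross_sample_filter({"A": [dup, dup]}, {"A": []})


# ---------------------------------------------------------------- profiles

def test_load_profiles_from_config(tmp_path):
    cfg = tmp_path / "profiles.ini"
    cfg.write_text("[mycaller]\nqd_th = 2.0\nvarw_th = 0.1\n")
    profiles = load_profiles(cfg)
    assert profiles["mycaller"] == FilterThresholds(2.0, 0.1, "mycaller")
    assert "gatk" in profiles  # built-ins survive


def test_load_profiles_missing_key(tmp_path):
    cfg = tmp_path / "bad.ini"
    cfg.write_text("[x]\nqd_th = 2.0\n")
    with pytest.raises(ConfigError):
        load_profiles(cfg)


def test_negative_threshold_rejected():
    with pytest.raises(ConfigError):
        FilterThresholds(-1.0, 0.0)
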