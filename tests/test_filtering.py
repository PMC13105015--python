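"""Dataset-construction rules: indel typing, filters, overlap, cropping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelcal import (
    InputError,
    classify_indel,
    crop_window,
    exclude_overlap,
    filter_clinical,
    filter_genotypes,
    filter_population,
    gen_filter_fixture,
)
from indelcal.filtering import VARIANT_COLUMNS

allele = st.text(alphabet="ACGT", min_size=1, max_size=80)


@pytest.mark.parametrize(
    "ref,alt,kind,net,in_frame",
    [
        ("ATG", "A", "deletion", -2, False),
        ("A", "ATTT", "insertion", 3, True),
        ("AT", "GCCAT", "insertion", 3, True),  # complex indel typed by net change
        ("ACGTACG", "A", "deletion", -6, True),
        ("AC", "GT", "balanced", 0, True),
    ],
)
def test_classify_indel_examples(ref, alt, kind, net, in_frame):
    cls = classify_indel(ref, alt)
    assert (cls.kind, cls.net_nt, cls.in_frame) == (kind, net, in_frame)


def test_classify_indel_rejects_bad_alleles():
    with pytest.raises(InputError):
        classify_indel("", "A")
    with pytest.raises(InputError):
        classify_indel("ANA", "A")


@settings(max_examples=200, deadline=None)
@given(ref=allele, alt=allele)
def test_classify_indel_net_matches_length_arithmetic(ref, alt):
    cls = classify_indel(ref, alt)
    assert cls.net_nt == len(alt) - len(ref)
    assert cls.in_frame == (cls.net_nt % 3 == 0)
    assert (cls.kind == "insertion") == (cls.net_nt > 0)
    assert (cls.kind == "deletion") == (cls.net_nt < 0)


def _record(**overrides):
    base = {
        "assembly": "GRCh38",
        "chrom": "chr1",
        "pos": 100,
        "ref_allele": "ATTTA",
        "alt_allele": "AT",  # net -3, in-frame deletion
        "gene": "GENE1",
        "gene_validity": "definitive",
        "consequence": "inframe_deletion",
        "classification": "P",
        "review_stars": 2,
        "has_conflict": False,
        "allele_freq": np.nan,
        "qc_pass": True,
        "genotype_quality": 60.0,
        "depth": 30.0,
        "allele_balance": 0.5,
    }
    base.update(overrides)
    return base


def _table(rows):
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


@pytest.mark.parametrize(
    "override,kept",
    [
        ({}, True),
        ({"review_stars": 0}, False),
        ({"has_conflict": True}, False),
        ({"allele_freq": 0.005}, True),  # rare enough
        ({"allele_freq": 0.02}, False),  # above the 1% bound
        ({"allele_freq": np.nan}, True),  # absent from the reference population
        ({"ref_allele": "A" * 61, "alt_allele": "A"}, False),  # 60 bp, over 50 bp cap
        ({"classification": "VUS"}, False),
        ({"classification": "conflicting"}, False),
        ({"gene_validity": "limited"}, False),
        ({"alt_allele": "ATTTAG"}, False),  # net +1 frameshift
        ({"alt_allele": "ATTTA"}, False),  # balanced, not an indel
    ],
)
def test_filter_clinical_rule_boundaries(override, kept):
    df = _table([_record(**override)])
    out, audit = filter_clinical(df)
    assert (len(out) == 1) == kept
    assert audit.final_kept == len(out)


def test_filter_clinical_rejects_unknown_classification_token():
    df = _table([_record(classification="Pathogenic???")])
    with pytest.raises(InputError, match="classification"):
        filter_clinical(df)


@pytest.mark.parametrize(
    "override,kept",
    [
        ({"qc_pass": False}, False),
        ({"ref_allele": "A" * 49, "alt_allele": "A"}, True),  # 48 bp in-frame deletion
        ({"ref_allele": "A", "alt_allele": "ATGCA"}, False),  # net +4 frameshift
    ],
)
def test_filter_population_rule_boundaries(override, kept):
    df = _table([_record(allele_freq=0.001, **override)])
    out, _ = filter_population(df)
    assert (len(out) == 1) == kept


@pytest.mark.parametrize(
    "override,kept",
    [
        ({"genotype_quality": 39.0}, False),
        ({"genotype_quality": 40.0, "depth": 10.0, "allele_balance": 0.2}, True),
        ({"allele_balance": 0.19}, False),
        ({"depth": 9.0}, False),
    ],
)
def test_filter_genotypes_inclusive_bounds(override, kept):
    df = _table([_record(**override)])
    out, _ = filter_genotypes(df)
    assert (len(out) == 1) == kept


def test_filter_genotypes_missing_fields_excluded_via_audit_tag():
    df = _table([_record(genotype_quality=np.nan)])
    out, audit = filter_genotypes(df)
    assert len(out) == 0
    step = audit.steps[0]
    assert step.rule == "genotype_fields_present" and step.n_kept == 0


@pytest.mark.parametrize("filt", [filter_clinical, filter_population, filter_genotypes])
def test_filter_idempotence_and_accounting(filt):
    df, _ = gen_filter_fixture(400, seed=11)
    once, audit1 = filt(df)
    twice, audit2 = filt(once)
    pd.testing.assert_frame_equal(once, twice)
    assert audit2.final_kept == audit1.final_kept
    # counts chain: each step starts where the previous ended and never grows
    for prev, step in zip(audit1.steps, audit1.steps[1:]):
        assert step.n_in == prev.n_kept
    for step in audit1.steps:
        assert 0 <= step.n_kept <= step.n_in


def test_filters_match_planted_fixture_audits():
    df, expected = gen_filter_fixture(800, seed=3)
    for name, filt in (
        ("clinical", filter_clinical),
        ("population", filter_population),
        ("genotype", filter_genotypes),
    ):
        _, audit = filt(df)
        assert audit.to_dict() == expected[name].to_dict()


def _keyed_records(n, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            _record(
                chrom=f"chr{1 + i % 22}",
                pos=int(rng.integers(1, 10_000_000)),
                ref_allele="ATTTA",
                alt_allele="AT",
            )
        )
    df = _table(rows)
    df["pos"] = np.arange(n)  # guarantee unique keys
    return df


def test_exclude_overlap_counts():
    df = _keyed_records(500, seed=5)
    keys = list(
        zip(df["assembly"], df["chrom"], df["pos"], df["ref_allele"], df["alt_allele"])
    )[:123]
    remaining, removed = exclude_overlap(df, keys)
    assert removed == 123 and len(remaining) == 377
    assert removed + len(remaining) == len(df)
    # identity on empty exclusion; empty output on full exclusion
    rem2, rm2 = exclude_overlap(df, [])
    assert rm2 == 0 and len(rem2) == len(df)
    all_keys = list(
        zip(df["assembly"], df["chrom"], df["pos"], df["ref_allele"], df["alt_allele"])
    )
    rem3, rm3 = exclude_overlap(df, all_keys)
    assert rm3 == len(df) and len(rem3) == 0


def test_exclude_overlap_mixed_assembly_guard():
    df = _keyed_records(10, seed=6)
    keys = [("GRCh37", "chr1", 0, "ATTTA", "AT")]
    with pytest.raises(InputError, match="assembl"):
        exclude_overlap(df, keys)
    remaining, removed = exclude_overlap(df, keys, allow_mixed_assembly=True)
    assert removed == 0


def _indexable_seq(n):
    # distinct residues by position so window coordinates are verifiable
    return "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(n))


def test_crop_window_short_sequences_unchanged():
    wt, var = _indexable_seq(100), _indexable_seq(101)
    assert crop_window(wt, var, 40, 42) == (wt, var)


def test_crop_window_centered_coordinates():
    seq = _indexable_seq(3000)
    wt, var = crop_window(seq, seq, 1500, 1502)
    # centre floor((1500+1502)/2) = 1501; window residues 478..2523 (1-based)
    assert wt == seq[477:2523]
    assert len(wt) == 2046 and var == wt


def test_crop_window_shifts_to_stay_in_bounds():
    seq = _indexable_seq(3000)
    wt, _ = crop_window(seq, seq, 10, 12)
    assert wt == seq[:2046]
    wt2, _ = crop_window(seq, seq, 2995, 2997)
    assert wt2 == seq[-2046:]


def test_crop_window_invalid_coordinates():
    seq = _indexable_seq(50)
    with pytest.raises(InputError):
        crop_window(seq, seq, 60, 61)
    with pytest.raises(InputError):
        crop_window(seq, seq, 5, 3)


@settings(max_examples=100, deadline=None)
@given(
    length=st.integers(min_value=1, max_value=5000),
    start=st.integers(min_value=1, max_value=5000),
    span=st.integers(min_value=0, max_value=30),
)
def test_crop_window_length_and_midpoint_invariants(length, start, span):
    if start > length:
        return
    end = start + span
    # unique marker at the variant midpoint; it must survive the crop
    center = (start + min(end, length)) // 2
    seq = "A" * (center - 1) + "C" + "A" * (length - center)
    wt, _ = crop_window(seq, seq, start, end)
    assert len(wt) == min(length, 2046)
    assert "C" in wt
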