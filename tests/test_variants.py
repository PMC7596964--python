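"""The 3-step somatic filter, record validation, table IO, matrix build."""

import numpy as np
import pandas as pd
import pytest

from dcfs.matrix import FeatureMatrix
from dcfs.simulate import FilterMix, generate_variant_records
from dcfs.variants import (
    Consequence,
    Region,
    build_matrix,
    compute_freq,
    failed_step,
    filter_step1,
    filter_step2,
    filter_step3,
    filter_variants,
    fisher_exact_p,
    passes_step1,
    passes_step2,
    passes_step3,
    read_variant_table,
    records_to_frame,
)

from conftest import make_record


@pytest.mark.parametrize("alt, total, expected", [(6, 10, 60.0), (0, 10, 0.0), (10, 10, 100.0)])
def test_compute_freq(alt, total, expected):
    assert compute_freq(alt, total) == expected


def test_compute_freq_invalid():
    with pytest.raises(ValueError):
        compute_freq(1, 0)
    with pytest.raises(ValueError):
        compute_freq(11, 10)


def test_fisher_helper_matches_scipy_convention():
    # balanced table -> p = 1; extreme table -> small p
    assert fisher_exact_p(5, 5, 5, 5) == pytest.approx(1.0)
    assert fisher_exact_p(30, 0, 0, 30) < 1e-6


def test_record_validation():
    with pytest.raises(ValueError):
        make_record(ref="A", alt="A")
    with pytest.raises(ValueError):
        make_record(pos=0)
    with pytest.raises(ValueError):
        make_record(tumor_freq=120.0)
    with pytest.raises(ValueError):
        make_record(fisher_p=1.5)


@pytest.mark.parametrize(
    "overrides, kept",
    [
        ({}, True),  # exonic nonsynonymous
        ({"region": Region.UTR3}, True),
        ({"region": Region.UTR5}, True),
        ({"consequence": Consequence.SYNONYMOUS}, False),
        ({"consequence": Consequence.AMBIGUOUS}, False),
        ({"region": Region.INTRONIC}, False),
        ({"region": Region.INTERGENIC}, False),
    ],
)
def test_step1_predicate(overrides, kept):
    assert passes_step1(make_record(**overrides)) is kept


@pytest.mark.parametrize(
    "overrides, kept",
    [
        ({"in_gnomad": True}, False),
        ({"in_gnomad": True, "in_cosmic": True}, True),  # COSMIC rescue
        ({"in_esp6500": True}, False),
        ({"in_exac": True, "in_cosmic": True}, True),
        ({}, True),  # novel variant
        ({"in_cosmic": True}, True),
    ],
)
def test_step2_predicate(overrides, kept):
    assert passes_step2(make_record(**overrides)) is kept


@pytest.mark.parametrize(
    "overrides, kept",
    [
        ({"tumor_freq": 60.0, "normal_freq": 0.0, "fisher_p": 0.001}, True),
        ({"normal_freq": 5.0}, False),
        ({"fisher_p": 0.02}, False),
        ({"tumor_freq": 9.9}, False),
        ({"tumor_freq": 10.0}, True),  # boundary: FREQ >= 10 kept
        ({"fisher_p": 0.01}, True),  # boundary: p <= 0.01 kept
    ],
)
def test_step3_predicate(overrides, kept):
    assert passes_step3(make_record(**overrides)) is kept


def test_steps_preserve_order_and_are_idempotent():
    records = [
        make_record(pos=1),
        make_record(pos=2, consequence=Consequence.SYNONYMOUS),
        make_record(pos=3),
        make_record(pos=4, in_exac=True),
        make_record(pos=5, normal_freq=3.0),
    ]
    for step in (filter_step1, filter_step2, filter_step3):
        once = step(records)
        assert step(once) == once  # idempotent
        assert set(once) <= set(records)  # monotone
        assert [r.pos for r in once] == sorted(r.pos for r in once)  # order kept


def test_composite_filter_equals_predicate_conjunction(rng):
    records = generate_variant_records(
        120, FilterMix(fail_step1=0.2, fail_step2=0.15, fail_step3=0.25), seed=3
    )
    records = [records[i] for i in rng.permutation(len(records))]
    report = filter_variants(records)
    oracle = [
        r for r in records if passes_step1(r) and passes_step2(r) and passes_step3(r)
    ]
    assert report.survivors == oracle
    assert report.counts["step3"] == len(oracle)


def test_generated_mix_has_exact_survivor_count():
    mix = FilterMix(fail_step1=0.1, fail_step2=0.1, fail_step3=0.1)
    records = generate_variant_records(100, mix, seed=1)
    report = filter_variants(records)
    assert report.counts == {"input": 100, "step1": 90, "step2": 80, "step3": 70}


def test_audit_column_labels_first_failed_step():
    records = [
        make_record(pos=1),
        make_record(pos=2, region=Region.INTRONIC),
        make_record(pos=3, in_gnomad=True),
        make_record(pos=4, fisher_p=0.5),
        # fails step 1 AND 3; audit reports the first
        make_record(pos=5, consequence=Consequence.SYNONYMOUS, normal_freq=9.0),
    ]
    assert [failed_step(r) for r in records] == [0, 1, 2, 3, 1]
    df = records_to_frame(records)
    assert df["filter_step_failed"].tolist() == [0, 1, 2, 3, 1]


def test_build_matrix_shape_encoding_and_indicators():
    records = [
        make_record(sample_id="a", pos=1, tumor_freq=40.0),
        make_record(sample_id="a", pos=2),
        make_record(sample_id="b", pos=3),
    ]
    labels = {"a": "positive", "b": "positive", "c": "positive", "d": "negative", "e": "negative"}
    fm = build_matrix(records, labels)
    assert fm.X.shape == (5, 3)
    assert fm.X[0].tolist() == [1.0, 1.0, 0.0]
    assert fm.X[1].tolist() == [0.0, 0.0, 1.0]
    assert fm.c_pos.tolist() == [1, 1, 1, 0, 0]
    assert fm.c_neg.tolist() == [0, 0, 0, 1, 1]
    freq = build_matrix(records, labels, encoding="freq")
    assert freq.X[0, 0] == 40.0


def test_build_matrix_rejects_unlabeled_samples():
    with pytest.raises(ValueError, match="s0"):
        build_matrix([make_record()], {"other": "positive"})


def test_matrix_roundtrips_record_presence():
    records = generate_variant_records(40, seed=5, n_samples=6)
    labels = {f"s{i}": ("positive" if i % 2 else "negative") for i in range(6)}
    fm = build_matrix(records, labels)
    carried = {(r.sample_id, str(r.key)) for r in records}
    sidx = {s: i for i, s in enumerate(fm.sample_ids)}
    fidx = {f: j for j, f in enumerate(fm.feature_ids)}
    for (s, k) in carried:
        assert fm.X[sidx[s], fidx[k]] == 1.0
    assert fm.X.sum() == len(carried)


def test_table_io_roundtrip_and_missing_policy(tmp_path):
    records = generate_variant_records(25, FilterMix(fail_step1=0.2), seed=2)
    path = tmp_path / "variants.tsv"
    records_to_frame(records).drop(columns="filter_step_failed").to_csv(
        path, sep="\t", index=False
    )
    back = read_variant_table(path)
    assert back == records

    # blank a region field: dropped by default, kept as 'other' on request
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.loc[0, "region"] = None
    df.to_csv(path, sep="\t", index=False)
    assert len(read_variant_table(path)) == len(records) - 1
    kept = read_variant_table(path, missing_policy="keep")
    assert len(kept) == len(records)
    assert kept[0].region is Region.OTHER


def test_feature_matrix_validation():
    with pytest.raises(ValueError, match="duplicate"):
        FeatureMatrix(
            X=np.zeros((2, 2)),
            sample_ids=["a", "a"],
            feature_ids=["f1", "f2"],
            c_pos=np.array([1, 0]),
        )
    with pytest.raises(ValueError, match="indicator"):
        FeatureMatrix(
            X=np.zeros((2, 1)),
            sample_ids=["a", "b"],
            feature_ids=["f1"],
            c_pos=np.array([2, 0]),
        )
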