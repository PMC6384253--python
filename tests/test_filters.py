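"""Filter cascade: QC, functional/prevalence, segregation."""

import io

import numpy as np
import pytest

from pedprio import (
    FunctionalThresholds,
    QCThresholds,
    functional_filter,
    parse_ped,
    qc_filter,
    segregation_filter,
)
from conftest import (
    TEMPLATE_AFFECTED,
    TEMPLATE_MARRY_INS,
    brute_functional_pass,
    brute_qc_pass,
    brute_segregation_pass,
)

REQUIRED = TEMPLATE_AFFECTED | {"A03"}


# ---------------------------------------------------------------------------
# QC filter


def test_qc_boundaries_pass_on_the_stated_side(make_record):
    """'< 30 removes' means exactly 30 passes, and so on for each criterion."""
    boundary = make_record(mq=30.0, mq0=4, dp=5, qual=50.0, fs=10.0)
    passing, report = qc_filter([boundary])
    assert passing == [boundary]
    assert report.rejections == {}


@pytest.mark.parametrize(
    "kwargs, reason",
    [
        (dict(mq=29.0), "low_mapping_quality"),
        (dict(mq0=5), "mq0_reads"),
        (dict(dp=4), "low_site_depth"),
        (dict(qual=49.9), "low_qual"),
        (dict(fs=10.1), "strand_bias"),
        (dict(mq=29.0, qual=0.0), "low_mapping_quality"),  # first failure wins
    ],
)
def test_qc_rejection_reasons(make_record, kwargs, reason):
    _, report = qc_filter([make_record(**kwargs)])
    assert report.rejections == {reason: 1}


def test_qc_missing_field_policy(make_record):
    rec = make_record(mq=None)
    _, report = qc_filter([rec])
    assert report.rejections == {"missing_qc_field": 1}
    passing, _ = qc_filter([rec], QCThresholds(missing_field_passes=True))
    assert passing == [rec]


def test_qc_mq0_literal_reading(make_record):
    clean, dirty = make_record(mq0=0), make_record(mq0=6)
    passing, _ = qc_filter([clean, dirty], QCThresholds(mq0_literal=True))
    assert passing == [dirty]  # the literal clause keeps high-MQ0 sites


def test_qc_against_bruteforce_with_planted_violations(make_record):
    """100 records with exactly 17 planted violations -> 83 survivors,
    and the survivor set equals per-predicate re-evaluation."""
    rng = np.random.default_rng(5)
    records = []
    bad_kwargs = [
        dict(mq=20.0), dict(mq0=9), dict(dp=2), dict(qual=10.0), dict(fs=33.0),
    ]
    bad_idx = set(rng.choice(100, size=17, replace=False).tolist())
    for i in range(100):
        kw = dict(bad_kwargs[i % 5]) if i in bad_idx else {}
        records.append(make_record(pos=i + 1, **kw))
    passing, report = qc_filter(records)
    assert report.output_count == 83
    expected = [r for r in records if brute_qc_pass(r)]
    assert passing == expected
    assert report.is_conserved


# ---------------------------------------------------------------------------
# functional filter


def test_functional_frequency_cut(make_record):
    common = make_record(carriers=["S1"], freqs={"1000G": 0.06})
    _, report = functional_filter([common])
    assert report.rejections == {"common_in_population": 1}
    at_cut = make_record(carriers=["S1"], freqs={"1000G": 0.05})
    passing, _ = functional_filter([at_cut])
    assert passing == [at_cut]  # "> 5%" removes, 5% exactly stays


def test_functional_clear_pass_and_synonymous(make_record):
    clear = make_record(carriers=["S1"], depth=70, alt_reads=35)
    passing, _ = functional_filter([clear])
    assert passing == [clear]
    syn = make_record(carriers=["S1"], consequence="synonymous")
    _, report = functional_filter([syn])
    assert report.rejections == {"synonymous": 1}
    keep = FunctionalThresholds(drop_synonymous=False)
    assert functional_filter([syn], keep)[0] == [syn]


def test_functional_support_rules(make_record):
    no_carrier = make_record(carriers=[], samples=["S1", "S2"])
    shallow = make_record(carriers=["S1"], depth=4, alt_reads=2)
    skewed = make_record(carriers=["S1"], depth=70, alt_reads=14)  # VAF 0.2
    _, report = functional_filter([no_carrier, shallow, skewed])
    assert report.rejections == {
        "no_carrier": 1,
        "low_carrier_depth": 1,
        "low_alt_fraction": 1,
    }


def test_functional_min_aggregate_mode(make_record):
    # two carriers, depths 5 and 70: mean 37.5 passes, min 5 fails
    rec = make_record(carriers=["S1", "S2"], samples=["S1", "S2"])
    rec.calls["S1"].depth, rec.calls["S1"].alt_reads = 5, 3
    passing, _ = functional_filter([rec])
    assert passing == [rec]
    _, report = functional_filter([rec], FunctionalThresholds(aggregate="min"))
    assert report.rejections == {"low_carrier_depth": 1}


def test_functional_against_bruteforce(make_record):
    rng = np.random.default_rng(17)
    records = []
    for i in range(200):
        depth = int(rng.integers(3, 90))
        records.append(
            make_record(
                pos=i + 1,
                carriers=["S1"] if rng.random() < 0.9 else [],
                samples=["S1", "S2"],
                consequence=str(rng.choice(
                    ["synonymous", "nonsynonymous", "noncoding"])),
                freqs={"1000G": float(rng.uniform(0, 0.12))},
                depth=depth,
                alt_reads=int(rng.integers(0, depth + 1)),
            )
        )
    passing, report = functional_filter(records)
    assert passing == [r for r in records if brute_functional_pass(r)]
    assert report.is_conserved


# ---------------------------------------------------------------------------
# segregation filter


@pytest.fixture
def seg_record(make_record, template_ped):
    samples = template_ped.sample_ids

    def _make(carriers, missing=(), pos=1):
        return make_record(
            carriers=carriers, samples=samples, missing=missing, pos=pos
        )

    return _make


def test_segregation_keeps_fully_cosegregating_variant(seg_record, template_ped):
    rec = seg_record(REQUIRED)
    passing, report = segregation_filter([rec], template_ped)
    assert passing == [rec]
    assert report.substage_counts == {"sharing": 1, "marry_in_exclusion": 1}


def test_segregation_two_step_rejection(seg_record, template_ped):
    in_marry_in = seg_record(REQUIRED | {"A09"})
    not_shared = seg_record(REQUIRED - {"A21"})
    passing, report = segregation_filter([in_marry_in, not_shared], template_ped)
    assert passing == []
    assert report.rejections == {
        "carried_by_marry_in": 1,
        "not_shared_by_required_carriers": 1,
    }
    assert report.substage_counts == {"sharing": 1, "marry_in_exclusion": 0}


def test_segregation_missing_call_policy(seg_record, template_ped):
    # missing call on a required carrier fails the sharing rule...
    rec = seg_record(REQUIRED - {"A17"}, missing={"A17"})
    passing, _ = segregation_filter([rec], template_ped)
    assert passing == []
    # ...unless missing genotypes are declared compatible
    passing, _ = segregation_filter([rec], template_ped, missing_as_compatible=True)
    assert passing == [rec]
    # a missing call on a marry-in never counts as a carrier
    rec2 = seg_record(REQUIRED, missing={"A09"})
    passing, _ = segregation_filter([rec2], template_ped)
    assert passing == [rec2]


def test_segregation_unaffected_carriers_do_not_reject(seg_record, template_ped):
    rec = seg_record(REQUIRED | {"A16", "A20"})  # extra unaffected blood carriers
    passing, _ = segregation_filter([rec], template_ped)
    assert passing == [rec]  # penalized in scoring, not filtered


def test_segregation_matches_bruteforce(seg_record, template_ped):
    rng = np.random.default_rng(23)
    samples = template_ped.sample_ids
    records = []
    for i in range(150):
        carriers = {s for s in samples if rng.random() < 0.7}
        missing = {s for s in set(samples) - carriers if rng.random() < 0.05}
        records.append(seg_record(carriers, missing=missing, pos=i + 1))
    passing, report = segregation_filter(records, template_ped)
    expected = [
        r for r in records
        if brute_segregation_pass(r, REQUIRED, TEMPLATE_MARRY_INS)
    ]
    assert passing == expected
    assert report.is_conserved


# ---------------------------------------------------------------------------
# cascade algebra


def test_stages_are_idempotent(make_record, template_ped):
    rng = np.random.default_rng(3)
    records = [
        make_record(
            pos=i + 1,
            mq=float(rng.uniform(20, 70)),
            qual=float(rng.uniform(30, 900)),
            carriers=["S1"],
            samples=["S1", "S2"],
            freqs={"1000G": float(rng.uniform(0, 0.1))},
        )
        for i in range(60)
    ]
    for stage in (qc_filter, functional_filter):
        once, _ = stage(records)
        twice, report = stage(once)
        assert twice == once
        assert report.rejections == {}


def test_qc_and_functional_commute(make_record):
    rng = np.random.default_rng(9)
    records = [
        make_record(
            pos=i + 1,
            mq=float(rng.uniform(25, 40)),
            carriers=["S1"] if rng.random() < 0.8 else [],
            samples=["S1"],
            consequence=str(rng.choice(["synonymous", "nonsynonymous"])),
        )
        for i in range(80)
    ]
    ab = functional_filter(qc_filter(records)[0])[0]
    ba = qc_filter(functional_filter(records)[0])[0]
    assert ab == ba


def test_vacuous_thresholds_are_identity(make_record):
    inf = float("inf")
    records = [
        make_record(pos=i + 1, mq=1.0, mq0=99, dp=0, qual=0.0, fs=99.0,
                    carriers=["S1"], consequence="synonymous",
                    freqs={"1000G": 0.9}, depth=3, alt_reads=0)
        for i in range(10)
    ]
    qc_vac = QCThresholds(
        min_mapping_quality=-inf, max_mq0_reads=10**9, min_site_depth=0,
        min_qual=-inf, max_strand_bias_phred=inf, missing_field_passes=True,
    )
    fn_vac = FunctionalThresholds(
        max_db_frequency=1.0, min_carrier_depth=0.0, min_alt_fraction=0.0,
        drop_synonymous=False,
    )
    assert qc_filter(records, qc_vac)[0] == records
    assert functional_filter(records, fn_vac)[0] == records
    # segregation is the identity when no roles constrain it
    free_ped = parse_ped(io.StringIO("F S1 0 0 1 0\nF S2 0 0 2 0\n"))
    passing, _ = segregation_filter(records, free_ped)
    assert passing == records
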