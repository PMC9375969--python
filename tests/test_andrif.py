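"""Bootstrap aneuploidy calling: null, p-values, BH and patient events."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import driverstrength as ds
from driverstrength.andrif import DEFAULT_ARM_TO_CHROMOSOME


def brute_force_bh(pvalues: dict, fdr: float) -> set:
    """Reference BH: check every k explicitly."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    best_k = 0
    for k in range(1, m + 1):
        if items[k - 1][1] <= k * fdr / m:
            best_k = k
    return {e for e, _ in items[:best_k]}


def test_bootstrap_degenerate_distributions():
    all_zero = ds.bootstrap_null([0, 0, 0, 0], B=50, seed=1)
    assert (all_zero.replicate_means == 0).all() and all_zero.median == 0
    all_one = ds.bootstrap_null([1, 1, 1], B=50, seed=1)
    assert (all_one.replicate_means == 1).all() and all_one.median == 1


def test_bootstrap_matches_exhaustive_enumeration():
    # draws of size 3 from [1, 0, -1]: 27 equiprobable sequences
    statuses = [1, 0, -1]
    exact = {}
    for seq in product(statuses, repeat=3):
        mean = round(sum(seq) / 3, 6)
        exact[mean] = exact.get(mean, 0) + 1 / 27
    null = ds.bootstrap_null(statuses, B=30_000, seed=42)
    observed = pd.Series(np.round(null.replicate_means, 6)).value_counts(normalize=True)
    for mean, prob in exact.items():
        assert observed.get(mean, 0.0) == pytest.approx(prob, abs=0.02)


def test_bootstrap_empty_statuses_errors():
    with pytest.raises(ds.DataError, match="ACC"):
        ds.bootstrap_null([], B=10, seed=0, cancer_type="ACC")


def test_bootstrap_is_reproducible():
    a = ds.bootstrap_null([1, 0, -1, 0, 1], B=500, seed=9)
    b = ds.bootstrap_null([1, 0, -1, 0, 1], B=500, seed=9)
    assert (a.replicate_means == b.replicate_means).all()


def _null_with(means, B=10_000):
    means = np.asarray(means, dtype=float)
    return ds.BootstrapNull(
        cancer_type="T", replicate_means=means, median=float(np.median(means)), B=len(means),
        n_draw=10,
    )


def test_status_pvalue_tail_counting():
    # 120 of 10,000 replicates above 0.6 -> 120 / 5,000
    means = np.concatenate([np.full(9880, 0.0), np.full(120, 0.7)])
    assert ds.status_pvalue(0.6, _null_with(means)) == pytest.approx(0.024)
    # 40 of 10,000 below -0.5 -> 40 / 5,000
    means = np.concatenate([np.full(9960, 0.0), np.full(40, -0.6)])
    assert ds.status_pvalue(-0.5, _null_with(means)) == pytest.approx(0.008)


def test_status_pvalue_no_tail_cases():
    ones = _null_with(np.ones(100))
    assert ds.status_pvalue(1.0, ones) is None      # not beyond the median
    zeros = _null_with(np.zeros(100))
    assert ds.status_pvalue(0.0, zeros) is None     # zero mean never tested
    neg = _null_with(-np.ones(100))
    assert ds.status_pvalue(-0.2, neg) is None      # negative but above median


def test_status_pvalue_always_within_unit_interval():
    rng = np.random.default_rng(2)
    for _ in range(50):
        null = _null_with(rng.normal(0, 0.2, size=501))
        p = ds.status_pvalue(float(rng.normal(0, 0.3)), null)
        assert p is None or 0.0 <= p <= 1.0


@pytest.mark.parametrize(
    "pvalues, expected",
    [
        ({"a": 0.001, "b": 0.02, "c": 0.04, "d": 0.9}, {"a", "b"}),
        ({"a": 1.0, "b": 1.0}, set()),
        ({"a": 0.04}, {"a"}),
    ],
)
def test_bh_select_worked_examples(pvalues, expected):
    assert ds.bh_select(pvalues, fdr=0.05) == expected


def test_bh_select_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(300):
        m = int(rng.integers(1, 12))
        p = {f"e{k}": float(rng.uniform() ** 2) for k in range(m)}
        fdr = float(rng.choice([0.01, 0.05, 0.1]))
        assert ds.bh_select(p, fdr) == brute_force_bh(p, fdr)


def _calls(rows):
    return pd.DataFrame(
        rows,
        columns=["entity", "cancer_type", "level", "observed_mean", "p_value",
                 "q_passed", "label"],
    )


def test_patient_calls_sign_matching_and_override():
    patients = ["A", "B", "C"]
    cohorts = pd.Series("TST", index=patients)
    arm = pd.DataFrame(
        {"8p": [-1, 1, -1], "8q": [0, 0, -1], "17p": [0, 0, 0]}, index=patients
    )
    chrom = pd.DataFrame({"8": [0, 0, -1], "17": [0, 0, 0]}, index=patients)
    calls = _calls(
        [
            ("8p", "TST", "arm", -0.4, 0.001, True, "DAL"),
            ("8", "TST", "chromosome", -0.3, 0.002, True, "DCL"),
        ]
    )
    events = ds.patient_calls(arm, chrom, calls, cohorts)
    by_patient = events.groupby("barcode")["event_class"].apply(list).to_dict()
    # A: arm status matches the DAL call; B: opposite sign, no event
    assert by_patient["A"] == ["DAL"]
    assert "B" not in by_patient
    # C carries the chromosome loss, which suppresses the 8p arm event
    assert by_patient["C"] == ["DCL"]


def test_patient_calls_unknown_arm_errors():
    arm = pd.DataFrame({"99z": [1]}, index=["A"])
    chrom = pd.DataFrame({"8": [0]}, index=["A"])
    with pytest.raises(ds.ConfigurationError, match="99z"):
        ds.patient_calls(arm, chrom, _calls([]), pd.Series("T", index=["A"]))


def test_at_most_one_event_per_chromosome_per_patient():
    patients = [f"P{k}" for k in range(8)]
    cohorts = pd.Series("TST", index=patients)
    arm = pd.DataFrame({"7p": 1, "7q": 1}, index=patients)
    chrom = pd.DataFrame({"7": [1] * 8}, index=patients)
    calls = _calls(
        [
            ("7p", "TST", "arm", 1.0, 0.0, True, "DAG"),
            ("7q", "TST", "arm", 1.0, 0.0, True, "DAG"),
            ("7", "TST", "chromosome", 1.0, 0.0, True, "DCG"),
        ]
    )
    events = ds.patient_calls(arm, chrom, calls, cohorts)
    per_patient = events.groupby("barcode").size()
    assert (per_patient == 1).all()
    assert set(events["event_class"]) == {"DCG"}


def test_cohort_calls_reproducible_and_labels_signed():
    rng = np.random.default_rng(17)
    patients = [f"P{k:03d}" for k in range(60)]
    arm = pd.DataFrame(
        rng.choice([-1, 0, 1], size=(60, 6)),
        index=patients,
        columns=["1p", "1q", "2p", "2q", "3p", "3q"],
    )
    arm["1q"] = 1  # decisive planted gain
    cohorts = pd.Series("TST", index=patients)
    first = ds.cohort_calls(arm, cohorts, "arm", B=2000, fdr=0.05, seed=3)
    second = ds.cohort_calls(arm, cohorts, "arm", B=2000, fdr=0.05, seed=3)
    pd.testing.assert_frame_equal(first, second)
    row = first.set_index("entity").loc["1q"]
    assert row["label"] == "DAG" and row["q_passed"]
    labelled = first.loc[first["label"] != ""]
    assert (np.sign(labelled["observed_mean"]) == labelled["label"].map(
        {"DAG": 1, "DAL": -1}
    )).all()


def test_default_arm_map_covers_acrocentrics():
    assert DEFAULT_ARM_TO_CHROMOSOME["8p"] == "8"
    assert "13p" not in DEFAULT_ARM_TO_CHROMOSOME
    assert DEFAULT_ARM_TO_CHROMOSOME["13q"] == "13"
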