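"""Driver-event classification, DSI/NDSI and the ranking filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import driverstrength as ds
from driverstrength.paldric import (
    DRIVER_CLASSES, LOW_PROBABILITY, PASSENGER, index_table, top_events,
)
from conftest import oracle_indices, random_event_cohort


@pytest.mark.parametrize(
    "n_nonsyn, n_inact, hisr, cna, expected_class, expected_count",
    [
        (2, 0, 7.0, 0, "SNA_oncogene", 1),
        (0, 0, 7.0, 2, "CNA_oncogene", 1),
        (1, 0, 7.0, 1, "mixed_oncogene", 1),
        (1, 0, 3.0, 0, "SNA_suppressor", 1),
        (2, 2, 3.0, 0, "SNA_suppressor", 1),   # inactivating SNAs allowed
        (0, 0, 3.0, -2, "CNA_suppressor", 1),
        (1, 1, 3.0, -1, "mixed_suppressor", 1),
        (0, 0, 9.0, 0, PASSENGER, 0),
        (0, 0, None, 0, PASSENGER, 0),          # no HISR, no evidence
        (1, 0, 7.0, -1, LOW_PROBABILITY, 0),    # oncogene spectrum + deletion
        (1, 1, 7.0, 0, LOW_PROBABILITY, 0),     # inactivating SNA in oncogene
        (0, 0, 7.0, -2, LOW_PROBABILITY, 0),
        (1, 0, None, 0, LOW_PROBABILITY, 0),    # evidence but no HISR
        (0, 0, None, 2, LOW_PROBABILITY, 0),
        (1, 0, 5.0, 1, LOW_PROBABILITY, 0),     # suppressor spectrum + gain
    ],
)
def test_classify_event_rules(n_nonsyn, n_inact, hisr, cna, expected_class, expected_count):
    cls, count = ds.classify_event(n_nonsyn, n_inact, hisr, cna)
    assert (cls, count) == (expected_class, expected_count)


@settings(deadline=None, max_examples=300)
@given(
    n_hyper=st.integers(0, 4),
    n_inact=st.integers(0, 4),
    hisr=st.one_of(st.none(), st.floats(0.01, 20)),
    cna=st.integers(-2, 2),
)
def test_classification_is_exhaustive_and_unit_counted(n_hyper, n_inact, hisr, cna):
    cls, count = ds.classify_event(n_hyper + n_inact, n_inact, hisr, cna)
    assert cls in DRIVER_CLASSES + (PASSENGER, LOW_PROBABILITY)
    assert count == (1 if cls in DRIVER_CLASSES else 0)


def test_classify_event_rejects_bad_cna():
    with pytest.raises(ds.DataError):
        ds.classify_event(0, 0, 1.0, 3)


@pytest.mark.parametrize(
    "p_A, p, expected",
    [
        ({1: 3, 2: 2}, {1: 10, 2: 20}, 0.35),
        ({}, {1: 10}, 0.0),
        ({1: 10}, {1: 10}, 1.0),
    ],
)
def test_dsi_examples(p_A, p, expected):
    assert ds.dsi(p_A, p) == pytest.approx(expected, abs=1e-15)


def test_dsi_rejects_inconsistent_profiles():
    with pytest.raises(ds.DataError):
        ds.dsi({1: 5}, {1: 3})


def test_ndsi_examples():
    assert ds.ndsi({1: 3, 2: 2}, {1: 10, 2: 20}) == pytest.approx(0.875, abs=1e-15)
    assert ds.ndsi({4: 6}, {4: 9}) == pytest.approx(0.25, abs=0)  # single stratum
    assert ds.ndsi({}, {1: 5}) is None


def test_total_events_counts_and_exclusions():
    gene = pd.DataFrame(
        {
            "barcode": ["A", "A", "B", "C"] + ["D"] * 101,
            "entity": [1, 2, 1, 3] + list(range(1000, 1101)),
            "event_class": "SNA_oncogene",
        }
    )
    aneu = pd.DataFrame(
        {"barcode": ["A", "A"], "entity": ["8q", "7"], "event_class": ["DAL", "DCG"]}
    )
    p_i, totals = ds.total_events(gene, aneu)
    assert totals["A"] == 4           # 2 gene + 1 arm + 1 chromosome events
    assert totals["B"] == 1
    assert "D" not in totals.index    # 101 events: beyond the i <= 100 window
    assert p_i[4] == 1 and p_i[1] == 2 and p_i.sum() == 3


def test_total_events_rejects_duplicates():
    gene = pd.DataFrame(
        {"barcode": ["A", "A"], "entity": [1, 1], "event_class": "SNA_oncogene"}
    )
    aneu = gene.iloc[:0]
    with pytest.raises(ds.DataError):
        ds.total_events(gene, aneu)


def test_grouped_indices_match_per_patient_oracle():
    rng = np.random.default_rng(123)
    for _ in range(30):
        by_patient, gene_events, aneu = random_event_cohort(rng)
        result = index_table(gene_events, aneu)
        expected = oracle_indices(by_patient)
        merged = result.merge(expected, on="entity", suffixes=("", "_oracle"))
        assert len(merged) == len(expected)
        assert np.allclose(merged["dsi"], merged["dsi_oracle"], atol=1e-12, rtol=0)
        assert np.allclose(merged["ndsi"], merged["ndsi_oracle"], atol=1e-12, rtol=0)
        assert (merged["n_patients"] == merged["n_patients_oracle"]).all()


def test_ndsi_replication_invariance_and_dsi_consistency():
    rng = np.random.default_rng(7)
    by_patient, gene_events, aneu = random_event_cohort(rng, n_patients=15)
    base = index_table(gene_events, aneu).set_index(["entity", "event_class"])
    for c in (2, 3):
        rep = pd.concat(
            [
                gene_events.assign(barcode=gene_events["barcode"] + f"_r{r}")
                for r in range(c)
            ],
            ignore_index=True,
        )
        scaled = index_table(rep, aneu).set_index(["entity", "event_class"])
        joined = base.join(scaled, lsuffix="_1", rsuffix="_c")
        assert np.allclose(joined["ndsi_1"], joined["ndsi_c"], atol=1e-12, rtol=0)
        assert np.allclose(joined["dsi_1"], joined["dsi_c"], atol=1e-12, rtol=0)
        assert (joined["n_patients_c"] == c * joined["n_patients_1"]).all()


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["entity", "entity_type", "event_class", "n_patients", "dsi", "ndsi"],
    )


def test_rank_and_filter_rules():
    records = _records(
        [
            (101, "gene", "SNA_oncogene", 30, 0.9, 0.30),
            (101, "gene", "mixed_oncogene", 15, 0.5, 0.20),  # duplicate, lower
            (102, "gene", "SNA_suppressor", 9, 2.0, 0.90),   # < 10 patients
            (103, "gene", "CNA_oncogene", 12, 0.4, 0.04),    # below NDSI floor
            ("8q", "aneuploidy", "DAG", 40, 0.6, 0.10),
        ]
    )
    ranked = ds.rank_and_filter(records, "ndsi")
    assert list(ranked["entity"]) == [101, "8q"]
    assert ranked.iloc[0]["event_class"] == "SNA_oncogene"

    by_dsi = ds.rank_and_filter(records, "dsi")
    assert list(by_dsi["entity"]) == [101, "8q", 103]

    genes_only = ds.rank_and_filter(records, "ndsi", genes_only=True)
    assert list(genes_only["entity"]) == [101]


def test_rank_ties_break_deterministically():
    records = _records(
        [
            (5, "gene", "SNA_oncogene", 12, 0.5, 0.2),
            (3, "gene", "SNA_oncogene", 12, 0.5, 0.2),
            (4, "gene", "SNA_oncogene", 20, 0.5, 0.2),
        ]
    )
    ranked = ds.rank_and_filter(records, "ndsi")
    # higher patient count first, then ascending identifier
    assert list(ranked["entity"]) == [4, 3, 5]


def test_stratified_counts_partition_by_sex(worked, worked_result):
    bundle, _ = worked
    res = worked_result
    events = pd.concat([res.gene_events, res.aneuploidy_events], ignore_index=True)
    overall = ds.stratified_counts(events, res.patients, "cancer_type")
    by_sex = ds.stratified_counts(events, res.patients, "sex")
    assert by_sex["n_events"].sum() == overall["n_events"].sum()
    key = ["event_class", "entity"]
    merged = (
        by_sex.groupby(key)["n_events"].sum().rename("by_sex").reset_index()
        .merge(overall.groupby(key)["n_events"].sum().rename("all").reset_index())
    )
    assert (merged["by_sex"] == merged["all"]).all()


def test_count_and_index_rankings_can_disagree():
    # a rare gene confined to driver-sparse patients outranks a frequent
    # one by NDSI but not by raw count
    by_patient = {}
    for k in range(4):            # rare gene: patients with 1 event
        by_patient[f"S{k}"] = {111}
    for k in range(12):           # frequent gene: patients with 4 events
        by_patient[f"W{k}"] = {222, 333, 444, 555}
    rows = [
        {"barcode": p, "entity": e, "event_class": "SNA_oncogene"}
        for p, entities in by_patient.items()
        for e in entities
    ]
    gene_events = pd.DataFrame(rows)
    aneu = gene_events.iloc[:0]
    table = index_table(gene_events, aneu)
    by_ndsi = table.sort_values("ndsi", ascending=False)["entity"].tolist()
    counts = table.sort_values("n_patients", ascending=False)["entity"].tolist()
    assert by_ndsi[0] == 111 and counts[0] != 111


def test_top_events_returns_head_per_group():
    counts = pd.DataFrame(
        {
            "group": ["G"] * 4,
            "event_class": ["SNA_oncogene"] * 4,
            "entity": [1, 2, 3, 4],
            "n_events": [5, 9, 2, 7],
        }
    )
    top = top_events(counts, top_n=2)
    assert list(top["entity"]) == [2, 4]


def test_unknown_grouping_errors(worked_result):
    res = worked_result
    with pytest.raises(ds.ConfigurationError, match="ploidy"):
        ds.stratified_counts(res.gene_events, res.patients, "ploidy")
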