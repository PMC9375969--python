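"""Shared fixtures and the independent brute-force index oracle.

The oracle computes DSI/NDSI by direct per-patient iteration over event
lists — no grouped counts, no shared code with the package — so tests can
check the grouped implementation against it.
"""

from collections import Counter, defaultdict

import numpy as np
import pandas as pd
import pytest

import driverstrength as ds


def oracle_indices(events_by_patient: dict, i_max: int = 100) -> pd.DataFrame:
    """DSI/NDSI by direct per-patient summation over {patient: set(entity)}."""
    totals = {
        p: len(entities)
        for p, entities in events_by_patient.items()
        if 1 <= len(entities) <= i_max
    }
    p_i = Counter(totals.values())
    num = defaultdict(float)
    den = defaultdict(float)
    n_pat = Counter()
    for patient, i in totals.items():
        for entity in events_by_patient[patient]:
            num[entity] += 1.0 / (i * p_i[i])
            den[entity] += 1.0 / p_i[i]
            n_pat[entity] += 1
    rows = [
        {
            "entity": e,
            "n_patients": n_pat[e],
            "dsi": num[e],
            "ndsi": num[e] / den[e],
        }
        for e in num
    ]
    return pd.DataFrame(rows, columns=["entity", "n_patients", "dsi", "ndsi"])


def random_event_cohort(rng: np.random.Generator, n_patients: int = 20,
                        n_entities: int = 10, max_i: int = 8):
    """A random per-patient event structure plus its frame representation.

    Returns ``(events_by_patient, gene_events, aneuploidy_events)`` where
    the frames feed the package and the dict feeds the oracle.
    """
    entities = [1000 + k for k in range(n_entities)]
    events_by_patient = {}
    rows = []
    for p in range(n_patients):
        barcode = f"R{p:03d}"
        i = int(rng.integers(0, max_i + 1))
        chosen = rng.choice(entities, size=min(i, n_entities), replace=False)
        events_by_patient[barcode] = set(int(e) for e in chosen)
        for e in chosen:
            rows.append({"barcode": barcode, "entity": int(e), "event_class": "SNA_oncogene"})
    gene_events = pd.DataFrame(rows, columns=["barcode", "entity", "event_class"])
    aneuploidy = pd.DataFrame(columns=["barcode", "entity", "event_class"])
    return events_by_patient, gene_events, aneuploidy


@pytest.fixture(scope="session")
def worked():
    return ds.worked_example()


@pytest.fixture(scope="session")
def worked_result(worked):
    bundle, _ = worked
    return ds.run_pipeline(bundle, params=ds.PipelineParams(B=1000), seed=7)
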