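"""Driver-event classification, counting and the (N)DSI indices (PALDRIC GENE).

Each consensus patient-gene pair is classified into one of eight driver
event classes from its patient-level SNA counts, the gene-level HISR and
the validated CNA status:

    ======================  ========  =======  ======  ==========  =====
    class                   n_nonsyn  n_inact  HISR    CNA status  count
    ======================  ========  =======  ======  ==========  =====
    SNA-based oncogene      >=1       0        >5      0           1
    CNA-based oncogene      0         0        >5      +1 or +2    1
    mixed oncogene          >=1       0        >5      +1 or +2    1
    SNA-based suppressor    >=1       any      <=5     0           1
    CNA-based suppressor    0         0        <=5     -1 or -2    1
    mixed suppressor        >=1       any      <=5     -1 or -2    1
    passenger               0         0        any     0           0
    low-probability driver  all the rest                           0
    ======================  ========  =======  ======  ==========  =====

Driver events in genes are pooled with per-patient aneuploidy events
(DAG/DAL/DCG/DCL); the per-patient total event count *i* (capped at 100)
stratifies the cohort.  With p_i the number of patients carrying exactly
*i* driver events and p_Ai the number of those also carrying an event in
entity A, the Driver Strength Index and its frequency-normalised form are

    DSI_A  = sum_i p_Ai / (i * p_i)
    NDSI_A = DSI_A / sum_i (p_Ai / p_i)

NDSI weights events found in driver-sparse patients more heavily and is
invariant to how often the entity is altered overall; it lies in
[1/100, 1] whenever defined.
"""

from __future__ import annotations

import json
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .core import ConfigurationError, DataError

SNA_ONCOGENE = "SNA_oncogene"
CNA_ONCOGENE = "CNA_oncogene"
MIXED_ONCOGENE = "mixed_oncogene"
SNA_SUPPRESSOR = "SNA_suppressor"
CNA_SUPPRESSOR = "CNA_suppressor"
MIXED_SUPPRESSOR = "mixed_suppressor"
PASSENGER = "passenger"
LOW_PROBABILITY = "low_probability"

DRIVER_CLASSES = (
    SNA_ONCOGENE, CNA_ONCOGENE, MIXED_ONCOGENE,
    SNA_SUPPRESSOR, CNA_SUPPRESSOR, MIXED_SUPPRESSOR,
)
ANEUPLOIDY_CLASSES = ("DAG", "DAL", "DCG", "DCL")

HISR_CUTOFF = 5.0
I_MAX = 100


def build_states(
    pairs: pd.DataFrame,
    patient_counts: pd.DataFrame,
    gene_summary: pd.DataFrame,
    cna_validated: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per patient-gene evidence for every consensus pair.

    Missing SNA counts become zeros, a missing gene-level HISR stays
    missing (NaN), and a missing CNA status becomes zero, mirroring how
    unmatched records are treated throughout.  Returns columns
    ``barcode, entrez, n_hyper, n_inact, n_nonsyn, hisr, cna``.
    """
    states = pairs[["barcode", "entrez"]].merge(
        patient_counts, on=["barcode", "entrez"], how="left"
    )
    states[["n_hyper", "n_inact"]] = (
        states[["n_hyper", "n_inact"]].fillna(0).astype(int)
    )
    states["n_nonsyn"] = states["n_hyper"] + states["n_inact"]
    states["hisr"] = states["entrez"].map(gene_summary.set_index("entrez")["hisr"])

    cna_lookup = cna_validated.stack()
    idx = pd.MultiIndex.from_arrays([states["entrez"], states["barcode"]])
    states["cna"] = cna_lookup.reindex(idx).fillna(0).astype(int).to_numpy()
    return states


def classify_event(n_nonsyn: int, n_inact: int, hisr: float | None, cna: int):
    """Classify one patient-gene state; returns (event_class, count)."""
    frame = pd.DataFrame(
        {"n_nonsyn": [n_nonsyn], "n_inact": [n_inact], "hisr": [hisr], "cna": [cna]}
    )
    out = classify_events(frame)
    return out["event_class"].iloc[0], int(out["count"].iloc[0])


def classify_events(states: pd.DataFrame) -> pd.DataFrame:
    """Vectorised driver-event classification (rules in the module docstring).

    A missing HISR fails both the ``>5`` and ``<=5`` comparisons, so a
    gene never summarised by the SNA stage can only be a passenger (all
    evidence zero) or a low-probability driver.
    """
    if not states["cna"].isin((-2, -1, 0, 1, 2)).all():
        raise DataError("validated CNA status outside {-2..2}")
    n_nonsyn = states["n_nonsyn"].to_numpy()
    n_inact = states["n_inact"].to_numpy()
    hisr = states["hisr"].to_numpy(dtype=float)
    cna = states["cna"].to_numpy()

    onco = hisr > HISR_CUTOFF
    supp = hisr <= HISR_CUTOFF
    gain = (cna == 1) | (cna == 2)
    loss = (cna == -1) | (cna == -2)
    no_sna = (n_nonsyn == 0) & (n_inact == 0)

    conditions = [
        (n_nonsyn >= 1) & (n_inact == 0) & onco & (cna == 0),
        no_sna & onco & gain,
        (n_nonsyn >= 1) & (n_inact == 0) & onco & gain,
        (n_nonsyn >= 1) & supp & (cna == 0),
        no_sna & supp & loss,
        (n_nonsyn >= 1) & supp & loss,
        no_sna & (cna == 0),
    ]
    choices = list(DRIVER_CLASSES) + [PASSENGER]
    event_class = np.select(conditions, choices, default=LOW_PROBABILITY)
    out = states.copy()
    out["event_class"] = event_class
    out["count"] = np.isin(event_class, DRIVER_CLASSES).astype(int)
    return out


def gene_events(classified: pd.DataFrame) -> pd.DataFrame:
    """Unit gene-level driver events: columns ``barcode, entity, event_class``."""
    hits = classified.loc[classified["count"] == 1]
    return pd.DataFrame(
        {
            "barcode": hits["barcode"].to_numpy(),
            "entity": hits["entrez"].to_numpy(),
            "event_class": hits["event_class"].to_numpy(),
        }
    )


def total_events(
    gene_events: pd.DataFrame,
    aneuploidy_events: pd.DataFrame,
    i_max: int = I_MAX,
) -> tuple[pd.Series, pd.Series]:
    """Per-patient driver-event totals and the cohort profile p_i.

    Events must already be unit counts, de-duplicated per (patient,
    entity).  Returns ``(p_i, totals)``: ``p_i`` indexed 1..i_max counts
    patients with exactly *i* events; ``totals`` maps each event-bearing
    patient (0 < i <= i_max) to their total.  Patients above ``i_max``
    are excluded from both.
    """
    events = pd.concat(
        [gene_events[["barcode", "entity"]], aneuploidy_events[["barcode", "entity"]]],
        ignore_index=True,
    )
    if events.duplicated().any():
        raise DataError("driver events are not de-duplicated per (patient, entity)")
    totals = events.groupby("barcode").size()
    totals = totals[(totals >= 1) & (totals <= i_max)]
    p_i = totals.value_counts().reindex(range(1, i_max + 1), fill_value=0)
    p_i.index.name = "i"
    return p_i, totals


def dsi(p_A: Mapping[int, int], p: Mapping[int, int], i_max: int = I_MAX) -> float:
    """Driver Strength Index: sum over i of p_Ai / (i * p_i)."""
    total = 0.0
    for i in range(1, i_max + 1):
        a = int(p_A.get(i, 0) or 0)
        n = int(p.get(i, 0) or 0)
        if a > n:
            raise DataError(f"p_A({i}) = {a} exceeds p({i}) = {n}")
        if a:
            total += a / (i * n)
    return total


def ndsi(p_A: Mapping[int, int], p: Mapping[int, int], i_max: int = I_MAX) -> float | None:
    """Normalised DSI, or ``None`` when the entity carries no events."""
    numerator = dsi(p_A, p, i_max=i_max)
    denominator = 0.0
    for i in range(1, i_max + 1):
        a = int(p_A.get(i, 0) or 0)
        if a:
            denominator += a / int(p[i])
    if denominator == 0.0:
        return None
    return numerator / denominator


def index_table(
    gene_events: pd.DataFrame,
    aneuploidy_events: pd.DataFrame,
    i_max: int = I_MAX,
) -> pd.DataFrame:
    """Per entity x class index records over the pooled driver events.

    Returns columns ``entity, entity_type, event_class, n_patients, dsi,
    ndsi, p_profile`` where ``p_profile`` is the sparse p_Ai mapping as a
    JSON string.  Entities are genes (Entrez IDs) and arm/chromosome
    labels; patients beyond ``i_max`` total events contribute nothing.
    """
    p_i, totals = total_events(gene_events, aneuploidy_events, i_max=i_max)
    gene = gene_events.assign(entity_type="gene")
    aneu = aneuploidy_events.assign(entity_type="aneuploidy")
    events = pd.concat([gene, aneu], ignore_index=True)
    events["i"] = events["barcode"].map(totals)
    events = events.dropna(subset=["i"])
    events["i"] = events["i"].astype(int)

    p = p_i.to_dict()
    rows = []
    for (entity, entity_type, event_class), grp in events.groupby(
        ["entity", "entity_type", "event_class"], sort=False
    ):
        p_A = grp["i"].value_counts().to_dict()
        rows.append(
            {
                "entity": entity,
                "entity_type": entity_type,
                "event_class": event_class,
                "n_patients": int(sum(p_A.values())),
                "dsi": dsi(p_A, p, i_max=i_max),
                "ndsi": ndsi(p_A, p, i_max=i_max),
                "p_profile": json.dumps({int(k): int(v) for k, v in sorted(p_A.items())}),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["entity", "entity_type", "event_class", "n_patients", "dsi", "ndsi", "p_profile"],
    )
    out["_key"] = out["entity"].astype(str)
    out = out.sort_values(["event_class", "_key"], kind="mergesort", ignore_index=True)
    return out.drop(columns="_key")


def rank_and_filter(
    records: pd.DataFrame,
    index: str = "ndsi",
    min_patients: int = 10,
    ndsi_floor: float = 0.05,
    top_n: int = 50,
    genes_only: bool = False,
) -> pd.DataFrame:
    """Rank entities by DSI or NDSI with the standard pruning steps.

    Per entity x class records with fewer than ``min_patients`` patients
    are dropped; entities appearing in several classes keep only their
    highest-index record; for NDSI rankings records below ``ndsi_floor``
    are additionally dropped.  Ties break by higher patient count, then
    ascending entity identifier.  ``genes_only`` removes arm/chromosome
    entities (for downstream tools that only accept genes).
    """
    if index not in ("dsi", "ndsi"):
        raise ConfigurationError(f"ranking index must be 'dsi' or 'ndsi', got {index!r}")
    kept = records.loc[records["n_patients"] >= min_patients].copy()
    kept = kept.dropna(subset=[index])
    kept["_entity_key"] = kept["entity"].astype(str)
    kept = kept.sort_values(
        [index, "n_patients", "_entity_key"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    kept = kept.drop_duplicates("entity", keep="first")
    if index == "ndsi":
        kept = kept.loc[kept["ndsi"] >= ndsi_floor]
    if genes_only:
        kept = kept.loc[kept["entity_type"] == "gene"]
    kept = kept.drop(columns="_entity_key").head(top_n).reset_index(drop=True)
    kept.insert(0, "rank", np.arange(1, len(kept) + 1))
    return kept


DEFAULT_AGE_BINS = list(range(0, 101, 10)) + [200]


def stratified_counts(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    grouping: str,
    totals: pd.Series | None = None,
    age_bins: list[int] | None = None,
) -> pd.DataFrame:
    """Per-group, per-class driver-event counts for one stratification.

    ``grouping`` is one of ``cancer_type, stage, age_group, sex,
    total_events``; ``events`` pools gene and aneuploidy unit events
    (columns ``barcode, entity, event_class``).  Returns tidy counts
    ``group, event_class, entity, n_events``.
    """
    clinical = patients.set_index("barcode")
    if grouping == "age_group":
        bins = DEFAULT_AGE_BINS if age_bins is None else age_bins
        group = pd.cut(clinical["age"], bins=bins, right=False).astype(str)
    elif grouping == "total_events":
        if totals is None:
            raise ConfigurationError("grouping by total_events requires the totals series")
        group = totals
    elif grouping in clinical.columns:
        group = clinical[grouping]
    else:
        raise ConfigurationError(f"unknown grouping key {grouping!r}")

    work = events.copy()
    work["group"] = work["barcode"].map(group)
    work = work.dropna(subset=["group"])
    counts = (
        work.groupby(["group", "event_class", "entity"])
        .size()
        .rename("n_events")
        .reset_index()
    )
    return counts


def top_events(
    counts: pd.DataFrame,
    by: str = "n_events",
    per_class: bool = True,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top-N entities per (group, class) — the histogram-style summaries."""
    keys = ["group", "event_class"] if per_class else ["group"]
    ordered = counts.sort_values(
        keys + [by, "entity"],
        ascending=[True] * len(keys) + [False, True],
        key=lambda s: s.astype(str) if s.name == "entity" else s,
        kind="mergesort",
    )
    return ordered.groupby(keys, sort=False).head(top_n).reset_index(drop=True)


def stratified_report(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    totals: pd.Series,
    groupings=("cancer_type", "stage", "age_group", "sex", "total_events"),
    top_n: int = 10,
) -> dict[str, pd.DataFrame]:
    """Counts for every grouping, overall and per sex (where annotated)."""
    out: dict[str, pd.DataFrame] = {}
    populations = {"all": patients}
    if "sex" in patients.columns:
        for sex, block in patients.dropna(subset=["sex"]).groupby("sex"):
            populations[f"sex={sex}"] = block
    for pop_name, pop in populations.items():
        barcodes = set(pop["barcode"])
        pop_events = events.loc[events["barcode"].isin(barcodes)]
        for grouping in groupings:
            if grouping == "sex" and pop_name != "all":
                continue
            counts = stratified_counts(pop_events, pop, grouping, totals=totals)
            out[f"{pop_name}/{grouping}"] = top_events(counts, top_n=top_n)
    return out


def plot_top_events(counts: pd.DataFrame, path, title: str = "") -> None:
    """Bar chart of a top-events table (one panel per event class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = counts["event_class"].unique()
    fig, axes = plt.subplots(
        len(classes), 1, figsize=(8, 2.5 * max(len(classes), 1)), squeeze=False
    )
    for ax, cls in zip(axes.ravel(), classes):
        block = counts.loc[counts["event_class"] == cls]
        ax.bar(block["entity"].astype(str), block["n_events"])
        ax.set_ylabel("events")
        ax.set_title(str(cls))
        ax.tick_params(axis="x", rotation=45)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
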