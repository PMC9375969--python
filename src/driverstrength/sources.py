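"""Ingestion of cohort-level driver predictions and the consensus filter.

Third-party driver-prediction algorithms publish *cohort-level* lists:
either driver genes (Entrez ID + cancer type, usually with a q-value) or
driver mutations (transcript + substitution + cancer type).  These are
converted to *patient-level* patient-gene pairs by matching against the
cohort's own somatic data, and only pairs supported by at least two
independent source lists survive.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import ConfigurationError, require_columns

logger = logging.getLogger("driverstrength")

GENE_LEVEL = "gene"
MUTATION_LEVEL = "mutation"

GENE_COLUMNS = ("entrez", "cancer_type")
MUTATION_COLUMNS = ("entrez", "transcript", "substitution", "cancer_type")


class CohortDriverList:
    """One source's cohort-level driver predictions, q-value filtered.

    ``kind`` is ``"gene"`` (entries keyed by Entrez ID + cancer type) or
    ``"mutation"`` (keyed by Ensembl transcript + substitution + cancer
    type, with the Entrez ID carried along for CNA matching).
    """

    def __init__(self, name: str, kind: str, entries: pd.DataFrame):
        if kind not in (GENE_LEVEL, MUTATION_LEVEL):
            raise ConfigurationError(f"unknown driver-list kind {kind!r}")
        required = GENE_COLUMNS if kind == GENE_LEVEL else MUTATION_COLUMNS
        require_columns(entries, required, f"driver list {name!r}")
        if "q_value" in entries.columns:
            q = entries["q_value"].dropna()
            if ((q < 0) | (q > 1)).any():
                raise ConfigurationError(f"driver list {name!r} has q-values outside [0, 1]")
        self.name = name
        self.kind = kind
        self.entries = entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)


def load_source(
    source,
    kind: str,
    name: str,
    q_max: float = 0.05,
    cancer_type_map: dict[str, str] | None = None,
) -> CohortDriverList:
    """Load one driver list (path or DataFrame) and apply the q-value filter.

    Entries with ``q_value > q_max`` are dropped; entries without a
    q-value (curated lists such as the Cancer Gene Census) are retained.
    ``cancer_type_map`` optionally renames source cancer-type labels to
    the cohort codes used throughout (e.g. CGC tumour names -> TCGA
    codes); unmapped labels pass through unchanged.
    """
    if isinstance(source, pd.DataFrame):
        entries = source.copy()
    else:
        try:
            entries = pd.read_csv(source, sep="\t")
        except (pd.errors.ParserError, ValueError) as exc:
            raise ConfigurationError(f"driver list {name!r}: {exc}") from exc
    if cancer_type_map:
        entries["cancer_type"] = entries["cancer_type"].map(
            lambda c: cancer_type_map.get(c, c)
        )
    if "q_value" in entries.columns:
        before = len(entries)
        entries = entries.loc[~(entries["q_value"] > q_max)]
        logger.info(
            "source %s: dropped %d of %d entries with q > %g",
            name, before - len(entries), before, q_max,
        )
    return CohortDriverList(name=name, kind=kind, entries=entries)


def to_patient_level(
    source: CohortDriverList,
    snas: pd.DataFrame,
    cna_validated: pd.DataFrame,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Convert one cohort-level list to patient-gene pairs.

    Gene-level entries match any QC-passing patient of the entry's cancer
    type bearing at least one SNA in the gene (SNA route) or a nonzero
    validated CNA status in it (CNA route).  Mutation-level entries match
    through transcript + substitution + cancer type on the SNA route and
    through Entrez ID + cancer type on the CNA route.  SNA- and
    CNA-derived pairs are unioned and de-duplicated.  Returns columns
    ``barcode, entrez, source``.
    """
    cohort_of = patients.set_index("barcode")["cancer_type"]
    keep = snas["barcode"].isin(cohort_of.index)
    snas = snas.loc[keep].copy()
    snas["cancer_type"] = snas["barcode"].map(cohort_of)

    entries = source.entries
    if source.kind == GENE_LEVEL:
        sna_pairs = snas.merge(
            entries[["entrez", "cancer_type"]].drop_duplicates(),
            on=["entrez", "cancer_type"],
        )[["barcode", "entrez"]]
    else:
        sna_pairs = snas.merge(
            entries[["entrez", "transcript", "substitution", "cancer_type"]].drop_duplicates(),
            on=["transcript", "substitution", "cancer_type"],
            suffixes=("_patient", ""),
        )[["barcode", "entrez"]]

    # CNA route: Entrez + cancer type against nonzero validated statuses.
    cna_cols = [b for b in cna_validated.columns if b in cohort_of.index]
    cna_long = (
        cna_validated[cna_cols]
        .stack()
        .rename("status")
        .reset_index()
        .set_axis(["entrez", "barcode", "status"], axis=1)
    )
    cna_long = cna_long.loc[cna_long["status"] != 0]
    cna_long["cancer_type"] = cna_long["barcode"].map(cohort_of)
    cna_pairs = cna_long.merge(
        entries[["entrez", "cancer_type"]].drop_duplicates(),
        on=["entrez", "cancer_type"],
    )[["barcode", "entrez"]]

    pairs = (
        pd.concat([sna_pairs, cna_pairs], ignore_index=True)
        .drop_duplicates()
        .reset_index(drop=True)
    )
    pairs["source"] = source.name
    matched_genes = set(pairs["entrez"])
    n_unmatched = int((~entries["entrez"].isin(matched_genes)).sum())
    if n_unmatched:
        logger.info("source %s: %d entries matched no patient", source.name, n_unmatched)
    return pairs


def consensus_filter(pairs: pd.DataFrame, min_sources: int = 2) -> pd.DataFrame:
    """Keep patient-gene pairs supported by >= ``min_sources`` distinct lists.

    ``pairs`` concatenates the per-source outputs of
    :func:`to_patient_level`.  Returns one row per surviving pair with a
    pipe-joined ``sources`` column.
    """
    if pairs.empty:
        return pd.DataFrame(columns=["barcode", "entrez", "sources"])
    grouped = (
        pairs.drop_duplicates(["barcode", "entrez", "source"])
        .groupby(["barcode", "entrez"])["source"]
        .agg(["nunique", lambda s: "|".join(sorted(s))])
        .set_axis(["n_sources", "sources"], axis=1)
        .reset_index()
    )
    out = grouped.loc[grouped["n_sources"] >= min_sources, ["barcode", "entrez", "sources"]]
    return out.reset_index(drop=True)
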