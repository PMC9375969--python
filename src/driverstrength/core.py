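"""Shared identifiers, clinical/QC table handling and the sample-filtering gate.

The analysis population is defined once, up front: primary malignant
samples of adequate quality and purity that carry all three data types
(somatic point mutations, copy-number calls and arm-level aneuploidy
calls).  Every downstream stage restricts its inputs to the barcodes that
survive :func:`filter_samples`.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger("driverstrength")


class ConfigurationError(Exception):
    """A problem with configuration or input schema, not with the data values."""


class DataError(Exception):
    """Input values outside their documented domain."""


#: Histology labels accepted as "primary malignant"; file dialects differ.
DEFAULT_PRIMARY_LABELS = frozenset({"Primary Tumor", "primary malignant neoplasm"})

#: Columns the clinical/QC table must provide (after column-name mapping).
REQUIRED_CLINICAL_COLUMNS = (
    "barcode",
    "cancer_type",
    "histology",
    "low_quality",
    "cancer_dna_fraction",
    "subclonal_fraction",
    "has_sna",
    "has_cna",
    "has_aneuploidy",
)

#: Optional clinical columns used only for stratified reporting.
OPTIONAL_CLINICAL_COLUMNS = ("sex", "age", "stage")


def require_columns(table: pd.DataFrame, columns, what: str = "table") -> None:
    """Raise :class:`ConfigurationError` naming the first missing column."""
    for col in columns:
        if col not in table.columns:
            raise ConfigurationError(f"{what} is missing required column {col!r}")


def load_clinical(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical/QC TSV, renaming file columns to the canonical schema.

    ``column_map`` maps canonical names (see ``REQUIRED_CLINICAL_COLUMNS``)
    to the column headers actually present in the file.
    """
    table = pd.read_csv(path, sep="\t")
    if column_map:
        table = table.rename(columns={v: k for k, v in column_map.items()})
    require_columns(table, REQUIRED_CLINICAL_COLUMNS, "clinical table")
    frac = table[["cancer_dna_fraction", "subclonal_fraction"]]
    bad = ((frac < 0) | (frac > 1)).any(axis=None)
    if bad:
        raise DataError("cancer_dna_fraction/subclonal_fraction outside [0, 1]")
    return table


def filter_samples(
    patients: pd.DataFrame,
    accepted_histology=DEFAULT_PRIMARY_LABELS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the sample QC gate and return (retained records, removal report).

    A record is retained iff its histology is in ``accepted_histology``, it
    is not flagged low quality, cancer DNA fraction >= 0.5, subclonal genome
    fraction <= 0.5, and all three data types (SNA, CNA, aneuploidy) are
    present.  Records with a missing fraction cannot certify the purity
    criteria and are removed (counted under ``missing_fraction``).  Input
    order is preserved; the report counts, per criterion, how many records
    violate it (a record may violate several).
    """
    require_columns(patients, REQUIRED_CLINICAL_COLUMNS, "clinical table")

    histology_ok = patients["histology"].isin(accepted_histology)
    quality_ok = ~patients["low_quality"].astype(bool)
    dna = pd.to_numeric(patients["cancer_dna_fraction"], errors="coerce")
    sub = pd.to_numeric(patients["subclonal_fraction"], errors="coerce")
    fraction_present = dna.notna() & sub.notna()
    dna_ok = dna >= 0.5
    sub_ok = sub <= 0.5
    data_ok = (
        patients["has_sna"].astype(bool)
        & patients["has_cna"].astype(bool)
        & patients["has_aneuploidy"].astype(bool)
    )

    keep = histology_ok & quality_ok & fraction_present & dna_ok.fillna(False) & sub_ok.fillna(False) & data_ok
    report = {
        "histology": int((~histology_ok).sum()),
        "low_quality": int((~quality_ok).sum()),
        "cancer_dna_fraction": int((fraction_present & ~dna_ok).sum()),
        "subclonal_fraction": int((fraction_present & ~sub_ok).sum()),
        "missing_fraction": int((~fraction_present).sum()),
        "missing_data_type": int((~data_ok).sum()),
        "retained": int(keep.sum()),
        "removed": int((~keep).sum()),
    }
    for criterion, n in report.items():
        if criterion not in ("retained", "removed"):
            logger.info("sample filter: %s removed %d record(s)", criterion, n)
    logger.info(
        "sample filter: retained %d of %d records", report["retained"], len(patients)
    )
    return patients.loc[keep].copy(), report
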