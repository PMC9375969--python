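"""Functional classification of somatic point mutations (SNADRIF).

Each variant class is mapped to one of four functional categories:
potentially *hyperactivating* (missense, in-frame indels, de novo start
in frame), potentially *inactivating* (frameshifts, nonsense, nonstop,
translation start site), *passenger* (silent, de novo start out of
frame), or *unclear* (everything else, e.g. non-coding annotations).
Per gene, the Hyperactivating-to-Inactivating SNA Ratio

    HISR = (n_hyper + 1) / (n_inact + 1)

summarises whether the mutation spectrum looks oncogene-like (HISR > 5)
or tumour-suppressor-like (HISR <= 5).  Genes with only unclear SNAs, or
with fewer than 10 classified (hyper + inact + passenger) SNAs, are
removed — too few observations to estimate HISR.
"""

from __future__ import annotations

import pandas as pd

HYPERACTIVATING = "hyperactivating"
INACTIVATING = "inactivating"
PASSENGER = "passenger"
UNCLEAR = "unclear"

CATEGORIES = (HYPERACTIVATING, INACTIVATING, PASSENGER, UNCLEAR)

#: Default mapping from MAF variant-classification labels to categories.
#: Ships as data so users can extend it for local file dialects (e.g. the
#: "de novo start" labels, which have no universal MAF spelling).
DEFAULT_VARIANT_CATEGORIES: dict[str, str] = {
    "Frame_Shift_Del": INACTIVATING,
    "Frame_Shift_Ins": INACTIVATING,
    "Nonsense_Mutation": INACTIVATING,
    "Nonstop_Mutation": INACTIVATING,
    "Translation_Start_Site": INACTIVATING,
    "In_Frame_Del": HYPERACTIVATING,
    "In_Frame_Ins": HYPERACTIVATING,
    "Missense_Mutation": HYPERACTIVATING,
    "De_novo_Start_InFrame": HYPERACTIVATING,
    "De_novo_Start_OutOfFrame": PASSENGER,
    "Silent": PASSENGER,
}

SNA_COLUMNS = ("barcode", "entrez", "symbol", "transcript", "variant_class",
               "substitution", "cancer_type")


def classify_sna(variant_class: str, mapping: dict[str, str] | None = None) -> str:
    """Category for one variant-classification label; unknown labels are unclear."""
    table = DEFAULT_VARIANT_CATEGORIES if mapping is None else mapping
    return table.get(variant_class, UNCLEAR)


def hisr(n_hyper: int, n_inact: int) -> float:
    """Hyperactivating-to-Inactivating SNA Ratio: (n_hyper + 1) / (n_inact + 1)."""
    if n_hyper < 0 or n_inact < 0:
        raise ValueError("SNA counts must be non-negative")
    return (n_hyper + 1) / (n_inact + 1)


def _categorise(snas: pd.DataFrame, mapping: dict[str, str] | None) -> pd.Series:
    table = DEFAULT_VARIANT_CATEGORIES if mapping is None else mapping
    return snas["variant_class"].map(table).fillna(UNCLEAR)


def summarize_and_filter(
    snas: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    min_classified: int = 10,
) -> pd.DataFrame:
    """Per-gene category counts and HISR, with the gene-level filters applied.

    Input rows must already be restricted to QC-passing patients.  Returns
    one row per surviving gene with columns ``entrez, symbol, n_hyper,
    n_inact, n_passenger, n_unclear, hisr``.  Genes whose SNAs are all
    unclear, or with fewer than ``min_classified`` classified SNAs
    (hyper + inact + passenger), are dropped; exactly ``min_classified``
    is retained.
    """
    columns = ["entrez", "symbol", "n_hyper", "n_inact", "n_passenger", "n_unclear", "hisr"]
    if snas.empty:
        return pd.DataFrame(columns=columns)
    work = snas[["entrez", "symbol"]].copy()
    work["category"] = _categorise(snas, mapping)
    counts = pd.crosstab(work["entrez"], work["category"]).reindex(
        columns=list(CATEGORIES), fill_value=0
    )
    counts.columns = ["n_hyper", "n_inact", "n_passenger", "n_unclear"]
    symbols = work.drop_duplicates("entrez").set_index("entrez")["symbol"]

    classified = counts["n_hyper"] + counts["n_inact"] + counts["n_passenger"]
    keep = (classified > 0) & (classified >= min_classified)
    out = counts.loc[keep].copy()
    out["hisr"] = (out["n_hyper"] + 1) / (out["n_inact"] + 1)
    out.insert(0, "symbol", symbols.reindex(out.index))
    return out.reset_index()[columns]


def patient_gene_counts(
    snas: pd.DataFrame, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per (barcode, entrez) hyperactivating/inactivating SNA counts.

    This is the patient-level companion of :func:`summarize_and_filter`
    consumed by the driver-event classifier; passenger and unclear SNAs do
    not contribute.
    """
    if snas.empty:
        return pd.DataFrame(columns=["barcode", "entrez", "n_hyper", "n_inact"])
    work = snas[["barcode", "entrez"]].copy()
    category = _categorise(snas, mapping)
    work["n_hyper"] = (category == HYPERACTIVATING).astype(int)
    work["n_inact"] = (category == INACTIVATING).astype(int)
    out = work.groupby(["barcode", "entrez"], as_index=False)[["n_hyper", "n_inact"]].sum()
    return out


def read_maf(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a MAF-like TSV into the canonical SNA schema.

    ``column_map`` maps canonical names (``barcode``, ``entrez``, ...) to the
    headers present in the file; omitted entries are assumed canonical.
    """
    table = pd.read_csv(path, sep="\t")
    if column_map:
        table = table.rename(columns={v: k for k, v in column_map.items()})
    from .core import require_columns

    require_columns(table, SNA_COLUMNS, "SNA (MAF) table")
    return table[list(SNA_COLUMNS)]
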