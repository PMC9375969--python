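"""Bootstrap detection of recurrent arm/chromosome gains and losses (ANDRIF).

Per cancer type, the observed mean alteration status of each chromosome
arm (or whole chromosome) is compared against a bootstrap null built by
resampling statuses, with replacement, from the cohort's full status
table.  One-tailed exceedance counts divided by B/2 give p-values, which
are screened per cancer type with Benjamini-Hochberg at FDR 5%.  Cohort
calls are then instantiated per patient: a patient carries a driver
arm/chromosome event only when their own status matches the sign of the
cohort call.  Chromosome calls override arm calls so the same aneuploidy
is never counted twice (or three times) for one patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError, DataError

ARM_LABELS = {1: "DAG", -1: "DAL"}
CHROMOSOME_LABELS = {1: "DCG", -1: "DCL"}

#: Arms per chromosome; acrocentric chromosomes (13, 14, 15, 21, 22) have
#: no p-arm calls in standard arm-level aneuploidy tables.
DEFAULT_ARM_TO_CHROMOSOME: dict[str, str] = {
    f"{c}{arm}": str(c)
    for c in list(range(1, 23)) + ["X"]
    for arm in ("p", "q")
    if not (c in (13, 14, 15, 21, 22) and arm == "p")
}


@dataclass
class BootstrapNull:
    """Bootstrap distribution of mean alteration status for one cohort."""

    cancer_type: str
    replicate_means: np.ndarray
    median: float
    B: int
    n_draw: int

    def __post_init__(self) -> None:
        self.replicate_means = np.asarray(self.replicate_means, dtype=float)
        if len(self.replicate_means) != self.B:
            raise DataError("replicate_means length does not match B")


def bootstrap_null(
    statuses,
    B: int = 10_000,
    seed=None,
    n_draw: int | None = None,
    cancer_type: str = "",
) -> BootstrapNull:
    """Bootstrap the mean of ``statuses``.

    Each of the ``B`` replicates draws ``n_draw`` values (default: all of
    them) with replacement from ``statuses`` and records their mean.
    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    values = np.asarray(statuses, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise DataError(f"no statuses to bootstrap for cohort {cancer_type!r}")
    if B < 1:
        raise DataError("B must be >= 1")
    if not np.isin(values, (-1, 0, 1)).all():
        raise DataError("arm/chromosome statuses must be in {-1, 0, 1}")
    n = len(values) if n_draw is None else int(n_draw)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(values, size=(B, n), replace=True)
    means = draws.mean(axis=1)
    return BootstrapNull(
        cancer_type=cancer_type,
        replicate_means=means,
        median=float(np.median(means)),
        B=B,
        n_draw=n,
    )


def status_pvalue(observed_mean: float, null: BootstrapNull) -> float | None:
    """One-tailed bootstrap p-value, or ``None`` when no tail applies.

    Positive means above the null median are tested against the upper
    tail, negative means below it against the lower tail; the exceedance
    count is divided by B/2 and capped at 1.  Any other configuration
    (zero mean, or a mean not beyond the median) yields ``None`` — the
    cell is left empty rather than scored.
    """
    if observed_mean > 0 and observed_mean > null.median:
        count = int((null.replicate_means > observed_mean).sum())
    elif observed_mean < 0 and observed_mean < null.median:
        count = int((null.replicate_means < observed_mean).sum())
    else:
        return None
    return min(count / (null.B / 2), 1.0)


def bh_select(pvalues: dict[str, float], fdr: float = 0.05) -> set[str]:
    """Entities passing Benjamini-Hochberg step-up at the given FDR."""
    if not 0 < fdr < 1:
        raise DataError("fdr must lie in (0, 1)")
    if not pvalues:
        return set()
    entities = list(pvalues)
    p = np.asarray([pvalues[e] for e in entities], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return {e for e, r in zip(entities, reject) if r}


def cohort_calls(
    status_table: pd.DataFrame,
    patient_cohorts: pd.Series,
    level: str = "arm",
    B: int = 10_000,
    fdr: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cohort-level aneuploidy driver calls for one status table.

    ``status_table`` is patients x entities with entries in {-1, 0, 1} or
    missing; ``patient_cohorts`` maps barcode -> cancer-type code.  Per
    cancer type one bootstrap null is built from the pooled statuses of
    all entities, drawing n_patients values per replicate.  Returns one
    row per (cancer_type, entity) with the observed mean, the p-value
    (NaN where no tail applied) and the DAG/DAL (or DCG/DCL) label for
    BH-passing entities.
    """
    labels = ARM_LABELS if level == "arm" else CHROMOSOME_LABELS
    values = status_table.to_numpy(dtype=float)
    known = values[~np.isnan(values)]
    if not np.isin(known, (-1, 0, 1)).all():
        raise DataError(f"{level} status table contains entries outside {{-1, 0, 1}}")

    cohorts = patient_cohorts.reindex(status_table.index)
    rows = []
    root = np.random.SeedSequence(seed)
    cohort_codes = sorted(cohorts.dropna().unique())
    children = root.spawn(len(cohort_codes))
    for code, child in zip(cohort_codes, children):
        block = status_table.loc[cohorts == code]
        pooled = block.to_numpy(dtype=float).ravel()
        pooled = pooled[~np.isnan(pooled)]
        null = bootstrap_null(
            pooled,
            B=B,
            seed=np.random.default_rng(child),
            n_draw=len(block),
            cancer_type=code,
        )
        pvals: dict[str, float] = {}
        means: dict[str, float] = {}
        for entity in block.columns:
            col = block[entity].dropna()
            if col.empty:
                continue
            mean = float(col.mean())
            means[entity] = mean
            p = status_pvalue(mean, null)
            if p is not None:
                pvals[entity] = p
        selected = bh_select(pvals, fdr=fdr)
        for entity, mean in means.items():
            p = pvals.get(entity, np.nan)
            passed = entity in selected
            rows.append(
                {
                    "entity": entity,
                    "cancer_type": code,
                    "level": level,
                    "observed_mean": mean,
                    "p_value": p,
                    "q_passed": passed,
                    "label": labels[int(np.sign(mean))] if passed else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["entity", "cancer_type", "level", "observed_mean", "p_value", "q_passed", "label"],
    )


def patient_calls(
    arm_table: pd.DataFrame,
    chromosome_table: pd.DataFrame,
    calls: pd.DataFrame,
    patient_cohorts: pd.Series,
    arm_to_chromosome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Instantiate cohort calls per patient, chromosome overriding arms.

    A patient gains a DAL event on arm *a* iff their status on *a* is -1
    and *a* is cohort-labelled DAL for their cancer type (symmetrically
    for gains and for whole chromosomes).  When a patient carries a DCL
    or DCG on a chromosome, no arm events on that chromosome's arms are
    emitted for that patient, preventing double/triple counting of the
    same aneuploidy.  Returns columns ``barcode, entity, event_class``.
    """
    mapping = DEFAULT_ARM_TO_CHROMOSOME if arm_to_chromosome is None else arm_to_chromosome
    for arm in arm_table.columns:
        if arm not in mapping:
            raise ConfigurationError(f"arm {arm!r} missing from the arm->chromosome map")

    events: list[pd.DataFrame] = []
    labelled = calls.loc[calls["label"] != ""]
    for (level, table) in (("chromosome", chromosome_table), ("arm", arm_table)):
        sub = labelled.loc[labelled["level"] == level]
        for row in sub.itertuples():
            sign = 1 if row.label in ("DAG", "DCG") else -1
            if row.entity not in table.columns:
                continue
            col = table[row.entity]
            cohort_ok = patient_cohorts.reindex(table.index) == row.cancer_type
            hit = (col == sign) & cohort_ok
            if hit.any():
                events.append(
                    pd.DataFrame(
                        {
                            "barcode": table.index[hit],
                            "entity": row.entity,
                            "event_class": row.label,
                        }
                    )
                )
    if not events:
        return pd.DataFrame(columns=["barcode", "entity", "event_class"])
    out = pd.concat(events, ignore_index=True)

    chrom_events = out.loc[out["event_class"].isin(("DCG", "DCL"))]
    overridden = set(zip(chrom_events["barcode"], chrom_events["entity"]))
    if overridden:
        arm_rows = out["event_class"].isin(("DAG", "DAL"))
        arm_chrom = out["entity"].map(mapping)
        on_called_chrom = np.fromiter(
            ((b, c) in overridden for b, c in zip(out["barcode"], arm_chrom)),
            dtype=bool,
            count=len(out),
        )
        drop = arm_rows.to_numpy() & on_called_chrom
        out = out.loc[~drop]
    return out.reset_index(drop=True)
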