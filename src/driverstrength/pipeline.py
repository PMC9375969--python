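"""End-to-end orchestration: QC -> CNA validation -> SNA summary ->
aneuploidy calls -> source conversion -> consensus -> event classification
-> DSI/NDSI ranking, with input validation, a run manifest and a content
hash cache for the bootstrap stage (the only stage whose runtime is not
trivially small)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, DataError, filter_samples, load_clinical
from .gecnav import STATUS_LEVELS, expression_status_matrix, validate_cna_matrix
from .snadrif import patient_gene_counts, read_maf, summarize_and_filter
from .andrif import cohort_calls, patient_calls
from .sources import consensus_filter, load_source, to_patient_level
from . import paldric

logger = logging.getLogger("driverstrength")


@dataclass
class PipelineParams:
    """Analysis thresholds, defaulting to the published study settings."""

    min_snas: int = 10        # classified SNAs needed for a gene-level HISR
    min_patients: int = 10    # entity x class records below this are pruned
    ndsi_floor: float = 0.05  # NDSI rankings drop entries below this
    i_max: int = 100          # per-patient driver totals considered
    q_max: float = 0.05       # q-value cutoff for source driver lists
    fdr: float = 0.05         # Benjamini-Hochberg FDR for aneuploidy calls
    B: int = 10_000           # bootstrap replicates
    top_n: int = 50

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")


@dataclass
class PipelineResult:
    """Every intermediate and final table of one run."""

    patients: pd.DataFrame
    filter_report: dict
    cna_validated: pd.DataFrame
    gene_summary: pd.DataFrame
    patient_counts: pd.DataFrame
    aneuploidy_calls: pd.DataFrame
    aneuploidy_events: pd.DataFrame
    consensus: pd.DataFrame
    classified: pd.DataFrame
    gene_events: pd.DataFrame
    p_i: pd.Series
    totals: pd.Series
    index: pd.DataFrame
    top_dsi: pd.DataFrame
    top_ndsi: pd.DataFrame


def _table_digest(*frames) -> str:
    h = hashlib.sha256()
    for frame in frames:
        h.update(pd.util.hash_pandas_object(frame, index=True).to_numpy().tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def _bootstrap_stage(bundle, patients, params, seed, cache_dir):
    """Cohort-level aneuploidy calls, cached by content hash when possible."""
    qc = patients["barcode"]
    arm = bundle.arm_status.loc[bundle.arm_status.index.isin(qc)]
    chrom = bundle.chromosome_status.loc[bundle.chromosome_status.index.isin(qc)]
    cohorts = patients.set_index("barcode")["cancer_type"]

    cache_path = None
    if cache_dir is not None:
        key = _table_digest(arm, chrom)
        cache_path = Path(cache_dir) / f"andrif_{key}_B{params.B}_f{params.fdr}_s{seed}.tsv"
        if cache_path.exists():
            logger.info("andrif: reusing cached cohort calls (%s)", cache_path.name)
            calls = pd.read_csv(cache_path, sep="\t", dtype={"entity": str})
            calls["label"] = calls["label"].fillna("")
            return arm, chrom, cohorts, calls

    calls = pd.concat(
        [
            cohort_calls(arm, cohorts, "arm", B=params.B, fdr=params.fdr, seed=seed),
            cohort_calls(chrom, cohorts, "chromosome", B=params.B, fdr=params.fdr,
                         seed=seed + 1),
        ],
        ignore_index=True,
    )
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        calls.to_csv(cache_path, sep="\t", index=False)
    return arm, chrom, cohorts, calls


def run_pipeline(bundle, params: PipelineParams | None = None, seed: int = 0,
                 cache_dir=None) -> PipelineResult:
    """Run every stage on an in-memory bundle and return all tables.

    Deterministic given (bundle, params, seed): the bootstrap stage derives
    independent generators per cancer type from ``seed``.
    """
    params = params or PipelineParams()

    patients, report = filter_samples(bundle.clinical)
    qc = set(patients["barcode"])

    maf = bundle.maf.loc[bundle.maf["barcode"].isin(qc)].reset_index(drop=True)
    expr_cols = [c for c in bundle.expression.columns if c in qc]
    expr_status = expression_status_matrix(bundle.expression[expr_cols])
    cna = bundle.cna[[c for c in bundle.cna.columns if c in qc]]
    cna_validated = validate_cna_matrix(cna, expr_status)

    gene_summary = summarize_and_filter(maf, min_classified=params.min_snas)
    patient_counts = patient_gene_counts(maf)

    arm, chrom, cohorts, calls = _bootstrap_stage(bundle, patients, params, seed, cache_dir)
    aneu_events = patient_calls(arm, chrom, calls, cohorts)

    pair_frames = [
        to_patient_level(src, maf, cna_validated, patients)
        for src in bundle.source_lists
    ]
    pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame(
        columns=["barcode", "entrez", "source"]
    )
    consensus = consensus_filter(pairs)

    states = paldric.build_states(consensus, patient_counts, gene_summary, cna_validated)
    classified = paldric.classify_events(states)
    g_events = paldric.gene_events(classified)
    p_i, totals = paldric.total_events(g_events, aneu_events, i_max=params.i_max)
    index = paldric.index_table(g_events, aneu_events, i_max=params.i_max)
    top_dsi = paldric.rank_and_filter(
        index, "dsi", min_patients=params.min_patients, top_n=params.top_n
    )
    top_ndsi = paldric.rank_and_filter(
        index, "ndsi", min_patients=params.min_patients,
        ndsi_floor=params.ndsi_floor, top_n=params.top_n,
    )
    for stage, frame in (
        ("qc", patients), ("snadrif", gene_summary), ("andrif", aneu_events),
        ("consensus", consensus), ("events", g_events), ("index", index),
    ):
        logger.info("stage %s: %d records", stage, len(frame))
    return PipelineResult(
        patients=patients,
        filter_report=report,
        cna_validated=cna_validated,
        gene_summary=gene_summary,
        patient_counts=patient_counts,
        aneuploidy_calls=calls,
        aneuploidy_events=aneu_events,
        consensus=consensus,
        classified=classified,
        gene_events=g_events,
        p_i=p_i,
        totals=totals,
        index=index,
        top_dsi=top_dsi,
        top_ndsi=top_ndsi,
    )


def validate_inputs(bundle) -> dict[str, list[str]]:
    """Schema and cross-file consistency checks.

    Hard violations (values outside their domain, missing columns) raise;
    soft inconsistencies (IDs present in some files only) are returned as
    warnings.  A fully consistent bundle yields an empty warning list.
    """
    import numpy as np

    warnings: list[str] = []
    from .core import REQUIRED_CLINICAL_COLUMNS, require_columns
    from .snadrif import SNA_COLUMNS

    require_columns(bundle.clinical, REQUIRED_CLINICAL_COLUMNS, "clinical table")
    require_columns(bundle.maf, SNA_COLUMNS, "SNA (MAF) table")
    if bundle.clinical["barcode"].duplicated().any():
        raise DataError("duplicate barcodes in the clinical table")

    if not np.isin(bundle.cna.to_numpy(), STATUS_LEVELS).all():
        raise DataError("CNA matrix contains entries outside {-2..2}")
    if (bundle.expression.to_numpy() < 0).any():
        raise DataError("expression matrix contains negative values")
    for name, table in (("arm", bundle.arm_status), ("chromosome", bundle.chromosome_status)):
        values = table.to_numpy(dtype=float)
        known = values[~np.isnan(values)]
        if not np.isin(known, (-1, 0, 1)).all():
            raise DataError(f"{name} status table contains entries outside {{-1, 0, 1}}")

    clinical_barcodes = set(bundle.clinical["barcode"])
    stray = set(bundle.maf["barcode"]) - clinical_barcodes
    if stray:
        warnings.append(
            f"{len(stray)} SNA-table patient(s) absent from the clinical table "
            "(excluded from the analysis)"
        )
    for name, cols in (
        ("CNA", bundle.cna.columns),
        ("expression", bundle.expression.columns),
        ("arm-status", bundle.arm_status.index),
        ("chromosome-status", bundle.chromosome_status.index),
    ):
        missing = set(cols) - clinical_barcodes
        if missing:
            warnings.append(
                f"{len(missing)} {name} patient(s) absent from the clinical table"
            )
    no_expr = set(bundle.cna.index) - set(bundle.expression.index)
    if no_expr:
        warnings.append(
            f"{len(no_expr)} CNA gene(s) lack expression; their statuses pass through unvalidated"
        )
    for warning in warnings:
        logger.warning("validate: %s", warning)
    return {"warnings": warnings}


# ---------------------------------------------------------------------------
# File-based orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths, source registry and thresholds for a file-based run."""

    clinical: str
    maf: str
    cna: str
    expression: str
    arm_status: str
    chromosome_status: str
    sources: list[dict] = field(default_factory=list)  # {name, path, kind}
    cancer_type_map: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0
    outdir: str = "driverstrength_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate_paths(self) -> None:
        for name in ("clinical", "maf", "cna", "expression", "arm_status",
                     "chromosome_status"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigurationError(f"input {name!r} not found: {path}")
        for src in self.sources:
            if not Path(src["path"]).exists():
                raise ConfigurationError(
                    f"source list {src.get('name', '?')!r} not found: {src['path']}"
                )


def read_bundle(config: RunConfig):
    """Load all input files of a run into an in-memory bundle."""
    from .simulate import Bundle

    config.validate_paths()
    ct_map = None
    if config.cancer_type_map:
        mapping = pd.read_csv(config.cancer_type_map, sep="\t", header=None)
        ct_map = dict(zip(mapping[0], mapping[1]))
    source_lists = [
        load_source(src["path"], kind=src["kind"], name=src["name"],
                    q_max=config.params.q_max, cancer_type_map=ct_map)
        for src in config.sources
    ]
    return Bundle(
        clinical=load_clinical(config.clinical),
        maf=read_maf(config.maf),
        cna=pd.read_csv(config.cna, sep="\t", index_col="entrez"),
        expression=pd.read_csv(config.expression, sep="\t", index_col="entrez"),
        arm_status=pd.read_csv(config.arm_status, sep="\t", index_col="barcode"),
        chromosome_status=pd.read_csv(
            config.chromosome_status, sep="\t", index_col="barcode"
        ),
        source_lists=source_lists,
    )


def run_all(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline from files and persist every table.

    Writes all intermediates, the final index tables, the top-50 DSI and
    NDSI lists, stratified summaries and a JSON manifest into
    ``config.outdir``.  Rerunning with identical inputs, thresholds and
    seed reproduces all outputs bit for bit (the bootstrap stage is
    additionally content-cached under ``outdir/cache``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = read_bundle(config)
    validate_inputs(bundle)
    result = run_pipeline(
        bundle, params=config.params, seed=config.seed, cache_dir=out / "cache"
    )

    tables = {
        "patients_filtered": result.patients,
        "cna_validated": result.cna_validated.reset_index(names="entrez"),
        "gene_summary": result.gene_summary,
        "patient_gene_counts": result.patient_counts,
        "aneuploidy_calls": result.aneuploidy_calls,
        "aneuploidy_events": result.aneuploidy_events,
        "consensus_pairs": result.consensus,
        "classified_events": result.classified,
        "cohort_event_counts": result.p_i.rename("n_patients").reset_index(),
        "index_records": result.index,
        "top_dsi": result.top_dsi,
        "top_ndsi": result.top_ndsi,
    }
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(result.filter_report, fh, indent=2)

    strata_dir = out / "stratified"
    strata_dir.mkdir(exist_ok=True)
    events = pd.concat(
        [result.gene_events, result.aneuploidy_events.rename(columns={})],
        ignore_index=True,
    )
    for key, frame in paldric.stratified_report(
        events, result.patients, result.totals
    ).items():
        frame.to_csv(strata_dir / (key.replace("/", "_") + ".tsv"), sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "params": asdict(config.params),
        "stage_records": {name: int(len(frame)) for name, frame in tables.items()},
        "filter_report": result.filter_report,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result

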