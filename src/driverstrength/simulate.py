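"""Seeded generator of TCGA-like input bundles with plantable driver structure.

The generator builds a cohort *backwards* from the per-patient driver
burden: every QC-passing patient is first assigned a target total event
count *i* (drawn from configurable strata), and events are then placed to
realise those totals exactly — planted drivers into their configured
stratum, filler genes into the remaining slots.  This makes index
recovery tests sharp: a "strong" planted driver lives only in
driver-sparse patients (small *i*), a "weak" one only in driver-rich
patients, at identical frequency.

Every planted or filler event is materialised so the full pipeline
reproduces it: enough classified SNAs per gene to clear the 10-SNA
summary filter (topped up with silent mutations on existing carriers,
which create no new events), expression shifted multiplicatively past the
1.25x/0.75x thresholds wherever a CNA must validate, and two mock
gene-level driver-source lists containing every event gene so the
two-source consensus filter passes.  Aneuploidy structure is planted as
arm/chromosome statuses whose cohort mean equals the configured effect
size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError
from .sources import CohortDriverList

DEFAULT_ARMS = tuple(
    f"{c}{arm}"
    for c in range(1, 23)
    for arm in ("p", "q")
    if not (c in (13, 14, 15, 21, 22) and arm == "p")
)
DEFAULT_CHROMOSOMES = tuple(str(c) for c in range(1, 23))

#: role -> default target stratum of total driver events per carrier
ROLE_STRATA = {"strong": (1, 3), "weak": (20, 10**9), "any": (1, 10**9)}

MECHANISMS = (
    "sna_oncogene", "sna_suppressor",
    "cna_oncogene", "cna_suppressor",
    "mixed_oncogene", "mixed_suppressor",
)


@dataclass
class PlantedDriver:
    """A driver gene planted with a known mechanism and burden stratum."""

    entrez: int
    role: str = "any"
    mechanism: str = "sna_oncogene"
    n_carriers: int = 10
    stratum: tuple[int, int] | None = None

    def target_stratum(self) -> tuple[int, int]:
        if self.stratum is not None:
            return self.stratum
        return ROLE_STRATA[self.role]


@dataclass
class AneuploidyPlant:
    """A recurrent arm/chromosome gain or loss with a fixed cohort mean."""

    entity: str
    cancer_type: str
    direction: int = 1  # +1 gain, -1 loss
    effect_size: float = 0.4  # mean status == fraction of patients altered
    level: str = "arm"


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort bundle."""

    seed: int
    cohorts: dict[str, int] = field(default_factory=lambda: {"SIMA": 100})
    n_filler_genes: int = 60
    planted: list[PlantedDriver] = field(default_factory=list)
    aneuploidy_plants: list[AneuploidyPlant] = field(default_factory=list)
    #: (low, high, fraction) strata for per-patient total driver events
    strata: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1, 3, 0.3), (4, 12, 0.4), (13, 25, 0.3)]
    )
    qc_fail_fraction: float = 0.05
    n_decoy_genes: int = 10
    background_silent_rate: float = 0.2   # expected silent decoy SNAs per patient
    background_cna_rate: float = 0.01     # decoy gene-patient cells with a raw CNA
    expression_noise_sd: float = 0.1
    arm_noise: float = 0.0                # P(nonzero status) on non-planted arms
    arms: tuple[str, ...] = DEFAULT_ARMS
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES

    def __post_init__(self) -> None:
        for lo, hi, frac in self.strata:
            if lo < 1 or hi < lo or not 0 <= frac <= 1:
                raise ConfigurationError(f"invalid stratum ({lo}, {hi}, {frac})")
        for rate in (self.qc_fail_fraction, self.background_cna_rate, self.arm_noise):
            if not 0 <= rate <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")
        for plant in self.planted:
            if plant.mechanism not in MECHANISMS:
                raise ConfigurationError(f"unknown mechanism {plant.mechanism!r}")


@dataclass
class SimTruth:
    """What the generator intended, for assertions against pipeline output."""

    patient_totals: pd.Series          # barcode -> intended total driver events
    gene_truth: pd.DataFrame           # entrez, role, mechanism, stratum_lo, stratum_hi
    aneuploidy_truth: pd.DataFrame     # entity, level, cancer_type, label


@dataclass
class Bundle:
    """A complete input bundle in the formats the pipeline reads."""

    clinical: pd.DataFrame
    maf: pd.DataFrame
    cna: pd.DataFrame                  # genes x patients, raw statuses
    expression: pd.DataFrame           # genes x patients
    arm_status: pd.DataFrame           # patients x arms
    chromosome_status: pd.DataFrame    # patients x chromosomes
    source_lists: list[CohortDriverList]
    truth: SimTruth | None = None


def _maf_row(barcode, entrez, cancer_type, variant_class, k):
    return {
        "barcode": barcode,
        "entrez": entrez,
        "symbol": f"G{entrez}",
        "transcript": f"ENST{entrez:011d}",
        "variant_class": variant_class,
        "substitution": f"c.{100 + k}A>G",
        "cancer_type": cancer_type,
    }


def generate_cohort(config: SimConfig) -> Bundle:
    """Generate a full input bundle plus ground truth, deterministic in seed."""
    rng = np.random.default_rng(config.seed)

    # --- patients ------------------------------------------------------
    barcodes, cohort_of, qc_fail = [], {}, []
    for code, n in config.cohorts.items():
        n_fail = int(round(config.qc_fail_fraction * n))
        for k in range(n):
            bc = f"SIM-{code}-{k:04d}"
            barcodes.append(bc)
            cohort_of[bc] = code
            if k >= n - n_fail:
                qc_fail.append(bc)
    qc_pass = [b for b in barcodes if b not in set(qc_fail)]

    # --- intended per-patient totals ----------------------------------
    weights = np.array([frac for *_, frac in config.strata], dtype=float)
    if weights.sum() <= 0:
        raise ConfigurationError("stratum fractions must sum to a positive value")
    weights = weights / weights.sum()
    totals: dict[str, int] = {}
    for code in config.cohorts:
        members = [b for b in qc_pass if cohort_of[b] == code]
        counts = np.floor(weights * len(members)).astype(int)
        counts[0] += len(members) - counts.sum()
        pos = 0
        for (lo, hi, _), cnt in zip(config.strata, counts):
            for b in members[pos:pos + cnt]:
                totals[b] = int(rng.integers(lo, hi + 1))
            pos += cnt
    remaining = dict(totals)

    maf_rows: list[dict] = []
    cna_cells: dict[tuple[int, str], int] = {}      # (entrez, barcode) -> raw status
    expr_shift: dict[tuple[int, str], float] = {}   # (entrez, barcode) -> multiplier
    arm_cells: dict[tuple[str, str], int] = {}      # (barcode, entity) -> status
    chrom_cells: dict[tuple[str, str], int] = {}
    gene_sna_carriers: dict[int, list[str]] = {}

    def add_sna(barcode, entrez, variant_class):
        maf_rows.append(
            _maf_row(barcode, entrez, cohort_of[barcode], variant_class, len(maf_rows))
        )
        gene_sna_carriers.setdefault(entrez, []).append(barcode)

    # --- aneuploidy plants (consume one slot per carrier) --------------
    aneu_truth_rows = []
    for plant in config.aneuploidy_plants:
        members = [b for b in qc_pass if cohort_of[b] == plant.cancer_type]
        if not members:
            raise ConfigurationError(f"no patients in cohort {plant.cancer_type!r}")
        n_carriers = int(round(plant.effect_size * len(members)))
        eligible = sorted(members, key=lambda b: -remaining[b])
        carriers = [b for b in eligible if remaining[b] >= 1][:n_carriers]
        if len(carriers) < n_carriers:
            raise ConfigurationError(
                f"aneuploidy plant on {plant.entity} needs {n_carriers} carriers, "
                f"only {len(carriers)} patients have a free event slot"
            )
        cells = arm_cells if plant.level == "arm" else chrom_cells
        for b in carriers:
            cells[(b, plant.entity)] = plant.direction
            remaining[b] -= 1
        labels = {("arm", 1): "DAG", ("arm", -1): "DAL",
                  ("chromosome", 1): "DCG", ("chromosome", -1): "DCL"}
        aneu_truth_rows.append(
            {
                "entity": plant.entity,
                "level": plant.level,
                "cancer_type": plant.cancer_type,
                "label": labels[(plant.level, plant.direction)],
                "n_carriers": len(carriers),
            }
        )

    # --- planted driver genes ------------------------------------------
    gene_truth_rows = []
    for plant in config.planted:
        lo, hi = plant.target_stratum()
        eligible = [b for b in qc_pass if lo <= totals[b] <= hi and remaining[b] >= 1]
        if len(eligible) < plant.n_carriers:
            raise ConfigurationError(
                f"planted driver {plant.entrez} needs {plant.n_carriers} carriers in "
                f"stratum [{lo}, {hi}], only {len(eligible)} slots available"
            )
        carriers = list(rng.choice(eligible, size=plant.n_carriers, replace=False))
        mech = plant.mechanism
        if mech in ("sna_oncogene", "sna_suppressor"):
            variant = "Missense_Mutation" if mech == "sna_oncogene" else "Nonsense_Mutation"
            for b in carriers:
                add_sna(b, plant.entrez, variant)
        elif mech in ("mixed_oncogene", "mixed_suppressor"):
            gain = mech == "mixed_oncogene"
            variant = "Missense_Mutation" if gain else "Nonsense_Mutation"
            for b in carriers:
                add_sna(b, plant.entrez, variant)
                cna_cells[(plant.entrez, b)] = 2 if gain else -2
                expr_shift[(plant.entrez, b)] = 1.5 if gain else 0.1
        else:  # pure CNA mechanism: half the carriers supply the HISR evidence
            gain = mech == "cna_oncogene"
            variant = "Missense_Mutation" if gain else "Nonsense_Mutation"
            n_sna = max(1, math.ceil(plant.n_carriers / 2))
            for b in carriers[:n_sna]:
                add_sna(b, plant.entrez, variant)
            for b in carriers[n_sna:]:
                cna_cells[(plant.entrez, b)] = 2 if gain else -2
                expr_shift[(plant.entrez, b)] = 1.5 if gain else 0.1
        for b in carriers:
            remaining[b] -= 1
        gene_truth_rows.append(
            {
                "entrez": plant.entrez,
                "role": plant.role,
                "mechanism": mech,
                "stratum_lo": lo,
                "stratum_hi": hi,
                "n_carriers": plant.n_carriers,
            }
        )

    # --- filler events realise the remaining per-patient budget --------
    filler_pool = [200000 + g for g in range(config.n_filler_genes)]
    planted_ids = {p.entrez for p in config.planted}
    if set(filler_pool) & planted_ids:
        raise ConfigurationError("planted Entrez IDs collide with the filler pool")
    filler_variant = {
        g: ("Missense_Mutation" if k % 2 == 0 else "Nonsense_Mutation")
        for k, g in enumerate(filler_pool)
    }
    usage = {g: 0 for g in filler_pool}
    for b in qc_pass:
        need = remaining[b]
        if need > len(filler_pool):
            raise ConfigurationError(
                f"patient {b} needs {need} filler events but the pool has "
                f"{len(filler_pool)} genes; enlarge n_filler_genes"
            )
        chosen = sorted(filler_pool, key=lambda g: (usage[g], g))[:need]
        for g in chosen:
            add_sna(b, g, filler_variant[g])
            usage[g] += 1
        remaining[b] = 0

    # --- top up genes below the 10-classified-SNA summary filter -------
    for g, carriers in list(gene_sna_carriers.items()):
        short = 10 - len(carriers)
        for k in range(max(short, 0)):
            add_sna(carriers[k % len(carriers)], g, "Silent")
    for (g, _b) in list(cna_cells):
        if g not in gene_sna_carriers:
            raise ConfigurationError(f"gene {g} has CNA events but no HISR support")

    # --- decoy background (not in any source list) ---------------------
    decoys = [900000 + g for g in range(config.n_decoy_genes)]
    if decoys:
        for b in qc_pass:
            for _ in range(rng.poisson(config.background_silent_rate)):
                add_sna(b, int(rng.choice(decoys)), "Silent")
        n_bg = rng.binomial(len(decoys) * len(barcodes), config.background_cna_rate)
        for _ in range(int(n_bg)):
            g = int(rng.choice(decoys))
            b = barcodes[int(rng.integers(len(barcodes)))]
            cna_cells.setdefault((g, b), int(rng.choice((-1, 1))))

    # QC-failing patients still carry data (the gate must remove them).
    event_genes = sorted(set(gene_sna_carriers) - set(decoys))
    for b in qc_fail:
        add_sna(b, event_genes[0] if event_genes else decoys[0], "Missense_Mutation")

    # --- matrices -------------------------------------------------------
    genes = sorted(set(event_genes) | set(decoys) | {g for g, _ in cna_cells})
    cna = pd.DataFrame(0, index=genes, columns=barcodes, dtype=int)
    for (g, b), status in cna_cells.items():
        cna.loc[g, b] = status

    baseline = pd.Series(rng.uniform(50.0, 150.0, size=len(genes)), index=genes)
    noise = np.exp(rng.normal(0.0, config.expression_noise_sd, size=(len(genes), len(barcodes))))
    expression = pd.DataFrame(
        baseline.to_numpy()[:, None] * noise, index=genes, columns=barcodes
    )
    for (g, b), mult in expr_shift.items():
        expression.loc[g, b] = baseline[g] * mult

    arm_status = pd.DataFrame(0, index=barcodes, columns=list(config.arms), dtype=int)
    chrom_status = pd.DataFrame(
        0, index=barcodes, columns=list(config.chromosomes), dtype=int
    )
    if config.arm_noise > 0:
        planted_arms = {p.entity for p in config.aneuploidy_plants if p.level == "arm"}
        planted_chroms = {
            p.entity for p in config.aneuploidy_plants if p.level == "chromosome"
        }
        for table, planted_cols in ((arm_status, planted_arms), (chrom_status, planted_chroms)):
            free = [c for c in table.columns if c not in planted_cols]
            draws = rng.choice(
                (-1, 0, 1),
                size=(len(barcodes), len(free)),
                p=(config.arm_noise / 2, 1 - config.arm_noise, config.arm_noise / 2),
            )
            table.loc[:, free] = draws
    for (b, e), status in arm_cells.items():
        arm_status.loc[b, e] = status
    for (b, e), status in chrom_cells.items():
        chrom_status.loc[b, e] = status

    # --- clinical -------------------------------------------------------
    clinical = pd.DataFrame(
        {
            "barcode": barcodes,
            "cancer_type": [cohort_of[b] for b in barcodes],
            "histology": "Primary Tumor",
            "low_quality": [b in set(qc_fail) for b in barcodes],
            "cancer_dna_fraction": 0.9,
            "subclonal_fraction": 0.05,
            "sex": rng.choice(("female", "male"), size=len(barcodes)),
            "age": rng.integers(30, 85, size=len(barcodes)),
            "stage": rng.choice(("I", "II", "III", "IV"), size=len(barcodes)),
            "has_sna": True,
            "has_cna": True,
            "has_aneuploidy": True,
        }
    )

    # --- mock driver-source lists --------------------------------------
    def source_frame(gene_ids):
        rows = [
            {"entrez": g, "cancer_type": code, "q_value": 0.001}
            for g in gene_ids
            for code in config.cohorts
        ]
        return pd.DataFrame(rows, columns=["entrez", "cancer_type", "q_value"])

    source_a = CohortDriverList(
        "mock_consensus_a", "gene", source_frame(event_genes + decoys)
    )
    source_b = CohortDriverList("mock_consensus_b", "gene", source_frame(event_genes))

    truth = SimTruth(
        patient_totals=pd.Series(totals, name="intended_total"),
        gene_truth=pd.DataFrame(
            gene_truth_rows,
            columns=["entrez", "role", "mechanism", "stratum_lo", "stratum_hi", "n_carriers"],
        ),
        aneuploidy_truth=pd.DataFrame(
            aneu_truth_rows, columns=["entity", "level", "cancer_type", "label", "n_carriers"]
        ),
    )
    maf = pd.DataFrame(
        maf_rows,
        columns=["barcode", "entrez", "symbol", "transcript", "variant_class",
                 "substitution", "cancer_type"],
    )
    return Bundle(
        clinical=clinical,
        maf=maf,
        cna=cna,
        expression=expression,
        arm_status=arm_status,
        chromosome_status=chrom_status,
        source_lists=[source_a, source_b],
        truth=truth,
    )


def null_cohort(
    seed: int,
    n_patients: int = 100,
    cohort: str = "NULL",
    arms: tuple[str, ...] = DEFAULT_ARMS,
    chromosomes: tuple[str, ...] = DEFAULT_CHROMOSOMES,
) -> Bundle:
    """A bundle with no planted structure: arm statuses i.i.d. uniform.

    Used for aneuploidy-caller calibration; carries no driver events, so
    the end-to-end index table is empty.
    """
    config = SimConfig(
        seed=seed,
        cohorts={cohort: n_patients},
        n_decoy_genes=5,
        arm_noise=2.0 / 3.0,  # uniform over {-1, 0, 1}
        arms=arms,
        chromosomes=chromosomes,
    )
    return _null_bundle(config)


def _null_bundle(config: SimConfig) -> Bundle:
    """generate_cohort minus event placement: pure background."""
    inner = SimConfig(
        seed=config.seed,
        cohorts=config.cohorts,
        planted=[],
        aneuploidy_plants=[],
        strata=[(1, 1, 1.0)],
        n_filler_genes=1,
        n_decoy_genes=config.n_decoy_genes,
        qc_fail_fraction=0.0,
        arm_noise=config.arm_noise,
        arms=config.arms,
        chromosomes=config.chromosomes,
    )
    bundle = generate_cohort(inner)
    # strip the single filler gene's events: a null cohort plants nothing
    filler = 200000
    bundle.maf = bundle.maf.loc[bundle.maf["entrez"] != filler].reset_index(drop=True)
    keep = [g for g in bundle.cna.index if g != filler]
    bundle.cna = bundle.cna.loc[keep]
    bundle.expression = bundle.expression.loc[keep]
    empty = pd.DataFrame(columns=["entrez", "cancer_type", "q_value"])
    bundle.source_lists = [
        CohortDriverList("mock_consensus_a", "gene", empty),
        CohortDriverList("mock_consensus_b", "gene", empty),
    ]
    bundle.truth = SimTruth(
        patient_totals=pd.Series(dtype=int),
        gene_truth=pd.DataFrame(
            columns=["entrez", "role", "mechanism", "stratum_lo", "stratum_hi", "n_carriers"]
        ),
        aneuploidy_truth=pd.DataFrame(
            columns=["entity", "level", "cancer_type", "label", "n_carriers"]
        ),
    )
    return bundle


# ---------------------------------------------------------------------------
# Worked example: a hand-sized fixture with frozen expected index values.
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_GENES = {
    1001: "ONC1",   # oncogene, missense in P01..P10
    1002: "TSG1",   # suppressor, nonsense in P01..P10
    1003: "AMP1",   # missense in P01..P10 plus validated amplification in P11, P12
    1004: "DEL1",   # nonsense in P01..P10 plus validated deletion in P01, P11, P12
    1005: "PASS1",  # silent only: consensus pairs that classify as passengers
}


def worked_example() -> tuple[Bundle, pd.DataFrame]:
    """A fixed 12-patient, 5-gene, one-arm-driver bundle with expected indices.

    The expected per entity x class table (DSI/NDSI as exact fractions)
    was computed by direct summation of the index definitions over the
    per-patient event lists, independently of the pipeline implementation.
    """
    cohort = "TST"
    patients = [f"P{k:02d}" for k in range(1, 13)]
    qc_fail = ["P13"]  # low-quality patient the QC gate must remove
    all_patients = patients + qc_fail

    maf_rows = []
    k = 0

    def sna(barcode, entrez, variant):
        nonlocal k
        maf_rows.append(_maf_row(barcode, entrez, cohort, variant, k))
        k += 1

    for b in patients[:10]:
        sna(b, 1001, "Missense_Mutation")
        sna(b, 1002, "Nonsense_Mutation")
        sna(b, 1003, "Missense_Mutation")
        sna(b, 1004, "Nonsense_Mutation")
        sna(b, 1005, "Silent")
    sna("P13", 1001, "Missense_Mutation")  # must not reach the HISR counts

    genes = sorted(WORKED_EXAMPLE_GENES)
    cna = pd.DataFrame(0, index=genes, columns=all_patients, dtype=int)
    cna.loc[1003, ["P11", "P12"]] = 2
    cna.loc[1004, ["P01", "P11", "P12"]] = -2

    expression = pd.DataFrame(100.0, index=genes, columns=all_patients)
    expression.loc[1003, ["P11", "P12"]] = 150.0      # 1.5x median -> status +1
    expression.loc[1004, ["P01", "P11", "P12"]] = 10.0  # 0.1x median -> status -1

    arms = ["8p", "8q", "17p"]
    arm_status = pd.DataFrame(0, index=all_patients, columns=arms, dtype=int)
    arm_status.loc[patients[:8], "8q"] = 1  # decisive planted arm gain
    chrom_status = pd.DataFrame(0, index=all_patients, columns=["8", "17"], dtype=int)

    clinical = pd.DataFrame(
        {
            "barcode": all_patients,
            "cancer_type": cohort,
            "histology": "Primary Tumor",
            "low_quality": [b in qc_fail for b in all_patients],
            "cancer_dna_fraction": 0.9,
            "subclonal_fraction": 0.05,
            "sex": ["female" if int(b[1:]) % 2 else "male" for b in all_patients],
            "age": [40 + 2 * int(b[1:]) for b in all_patients],
            "stage": "II",
            "has_sna": True,
            "has_cna": True,
            "has_aneuploidy": True,
        }
    )

    entries = pd.DataFrame(
        [{"entrez": g, "cancer_type": cohort, "q_value": 0.001} for g in genes]
    )
    source_lists = [
        CohortDriverList("mock_consensus_a", "gene", entries),
        CohortDriverList("mock_consensus_b", "gene", entries.copy()),
    ]

    totals = pd.Series(
        {b: 5 for b in patients[:8]} | {b: 4 for b in patients[8:10]}
        | {b: 2 for b in patients[10:]},
        name="intended_total",
    )
    truth = SimTruth(
        patient_totals=totals,
        gene_truth=pd.DataFrame(
            [
                {"entrez": 1001, "role": "any", "mechanism": "sna_oncogene",
                 "stratum_lo": 4, "stratum_hi": 5, "n_carriers": 10},
                {"entrez": 1002, "role": "any", "mechanism": "sna_suppressor",
                 "stratum_lo": 4, "stratum_hi": 5, "n_carriers": 10},
            ]
        ),
        aneuploidy_truth=pd.DataFrame(
            [{"entity": "8q", "level": "arm", "cancer_type": cohort,
              "label": "DAG", "n_carriers": 8}]
        ),
    )

    bundle = Bundle(
        clinical=clinical,
        maf=pd.DataFrame(maf_rows),
        cna=cna,
        expression=expression,
        arm_status=arm_status,
        chromosome_status=chrom_status,
        source_lists=source_lists,
        truth=truth,
    )

    # Cohort profile: p = {2: 2, 4: 2, 5: 8}; exact fractions below.
    expected = pd.DataFrame(
        [
            (1001, "gene", "SNA_oncogene", 10, 0.45, 0.225),
            (1003, "gene", "SNA_oncogene", 10, 0.45, 0.225),
            (1003, "gene", "CNA_oncogene", 2, 0.5, 0.5),
            (1002, "gene", "SNA_suppressor", 10, 0.45, 0.225),
            (1004, "gene", "SNA_suppressor", 9, 0.425, 17.0 / 75.0),
            (1004, "gene", "mixed_suppressor", 1, 0.025, 0.2),
            (1004, "gene", "CNA_suppressor", 2, 0.5, 0.5),
            ("8q", "aneuploidy", "DAG", 8, 0.2, 0.2),
        ],
        columns=["entity", "entity_type", "event_class", "n_patients", "dsi", "ndsi"],
    )
    return bundle, expected


def write_bundle(bundle: Bundle, outdir) -> dict[str, str]:
    """Write a bundle as TSVs (plus source lists) into ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, frame, **kw):
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", **kw)
        paths[name] = str(p)

    save("clinical", bundle.clinical, index=False)
    save("maf", bundle.maf, index=False)
    save("cna", bundle.cna, index_label="entrez")
    save("expression", bundle.expression, index_label="entrez")
    save("arm_status", bundle.arm_status, index_label="barcode")
    save("chromosome_status", bundle.chromosome_status, index_label="barcode")
    for lst in bundle.source_lists:
        save(f"source_{lst.name}", lst.entries, index=False)
    return paths
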