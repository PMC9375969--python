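# Methods

This note records the model, the numerical conventions, the synthetic
data design and the open design choices behind `driverstrength`.

## Driver events and the indices

The unit of analysis is the *driver event*: one (patient, entity) pair
where the entity is a gene, a chromosome arm or a whole chromosome.
Gene-level events come from classifying consensus patient–gene pairs
against four pieces of evidence — the patient's hyperactivating and
inactivating SNA counts in the gene, the gene's cohort-wide HISR, and
the expression-validated CNA status. The classification table (module
docstring of `paldric`) is exhaustive: exactly one class fires for any
state, with `passenger` (no evidence at all) and `low_probability`
(evidence inconsistent with a coherent oncogene or suppressor pattern,
or evidence without a defined HISR) counting zero events, and the six
coherent classes counting one each. Aneuploidy events (DAG/DAL/DCG/DCL)
are added per patient, with chromosome calls overriding their arms so a
single aneuploidy never contributes twice.

Per patient, the total `i` is the number of unit events; patients with
`i = 0` carry no information for the indices and patients with `i > 100`
are excluded (the cap keeps the stratification well-populated; genuinely
hypermutated outliers would otherwise contribute near-zero weights
anyway). With `p_i` patients at total `i` and `p_Ai` of them carrying
entity `A`:

- `DSI_A = Σ p_Ai/(i·p_i)` — each carrier contributes `1/(i·p_i)`, so
  carriers in driver-sparse patients weigh more;
- `NDSI_A = DSI_A / Σ (p_Ai/p_i)` — the denominator is the
  frequency-style sum, so NDSI depends only on *where* the events sit,
  not how many there are. Uniform replication of every event-bearing
  patient scales `p_Ai` and `p_i` together and leaves **both** indices
  unchanged; what distinguishes DSI is that it grows with the entity's
  frequency at fixed cohort structure (double `p_Ai` at fixed `p_i` and
  DSI doubles while NDSI is unchanged). When defined, `1/100 ≤ NDSI ≤ 1`,
  with equality at 1 iff every carrier has `i = 1`.

Both indices are computed from grouped counts; the test suite checks the
grouped computation against a direct per-patient summation oracle at
1e-12 on hundreds of random cohorts.

## Thresholds and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `min_snas` | 10 | classified SNAs (hyper+inact+passenger) a gene needs for a HISR |
| HISR cutoff | 5 | `> 5` oncogene-like, `≤ 5` suppressor-like |
| `q_max` | 0.05 | q-value filter on source driver lists (strictly `>` removed) |
| consensus | 2 | distinct source lists a patient–gene pair needs |
| `B` | 10,000 | bootstrap replicates per cancer type |
| `fdr` | 0.05 | Benjamini–Hochberg level for aneuploidy calls |
| `i_max` | 100 | largest per-patient total considered |
| `min_patients` | 10 | carriers an entity × class needs to be ranked |
| `ndsi_floor` | 0.05 | minimum NDSI kept in NDSI rankings |
| `top_n` | 50 | length of the ranked driver lists |

Sample QC keeps records with cancer DNA fraction ≥ 0.5 and subclonal
fraction ≤ 0.5 (boundaries inclusive — the removal criteria are strict
inequalities); records with a missing fraction cannot certify either
criterion and are removed, counted separately in the filter report.

## Numerical conventions

- **Expression bands.** The four thresholds (0.05×, 0.75×, 1.25×, 1.75×
  the per-gene median) need a closure convention; we use half-open bands
  with −2 strictly below 0.05×, +2 strictly above 1.75×, and −1/+1
  taking their inner boundaries. For continuous expression the boundary
  mass is negligible. A gene with median 0 yields status +2 for any
  positive value and 0 at zero — the general rule already implies this.
  The median is computed pan-cancer across the post-QC population.
- **Bootstrap p-values.** Per cancer type one null is built by pooling
  all arm (or chromosome) statuses and drawing `n_patients` values per
  replicate; the one-tailed exceedance count is divided by `B/2` exactly
  as defined, and capped at 1 before BH (the cap is defensive: a mean
  beyond the null median cannot produce more than `B/2` exceedances).
  Cells whose mean is zero or not beyond the null median get no p-value.
  Replicate streams are spawned per (cancer type, level) from the run
  seed via `numpy.random.SeedSequence`, making the stage bit-reproducible.
- **BH selection** delegates to `statsmodels` (`fdr_bh`); an explicit
  all-`k` step-up search serves as the independent oracle in tests.
- **Tie-breaking.** Ranked lists order by index, then larger carrier
  count, then ascending entity identifier (stringified), so outputs are
  byte-stable across reruns.
- **Missing data.** A gene absent from the SNA summary has no HISR; with
  any nonzero evidence the pair is `low_probability`, with none it is a
  passenger. Missing arm statuses produce no events. Genes absent from
  the expression matrix pass their CNA statuses through unvalidated.

## Synthetic cohorts

The generator works backwards from the per-patient burden: patients are
assigned target totals `i` from configurable strata (defaults
`(1–3, 30%)`, `(4–12, 40%)`, `(13–25, 30%)` — centred on the
low-to-intermediate burdens where the indices are most informative),
then events are placed to realise the totals exactly. Planted drivers
draw their carriers from the configured stratum ("strong" = 1–3,
"weak" = ≥ 20); aneuploidy plants mark `round(effect_size · n)` patients
with the planted sign, each consuming one event slot; filler genes
absorb the remaining slots with usage balancing so they clear the
10-SNA summary filter (genes still short are topped up with silent
mutations on existing carriers, which create no new events). Pure-CNA
planted mechanisms split carriers between CNA-only events and
supporting missense/nonsense SNAs, because a gene with no SNAs has no
HISR and could not be classified; each carrier still consumes exactly
one slot. Expression is log-normal noise (σ = 0.1) around a per-gene
baseline, with planted CNA cells set deterministically to 1.5× (gains)
or 0.1× (losses) of baseline so validation is guaranteed. Two mock
gene-level source lists carry every event gene (one also carries decoy
genes, which the consensus filter must remove).

What the generator does **not** emulate: mutational signatures and
hotspot structure, clonal architecture, correlated CNA segments,
realistic cohort sizes or cancer-type heterogeneity. Passing tests
therefore demonstrate the correctness and calibration of the
*algorithms*, not biological validity on real cohorts.

The bundled worked example (12 patients, 5 genes, one planted 8q gain)
is fully deterministic; its expected index table was computed by direct
summation of the index definitions over the per-patient event lists and
is frozen in `simulate.worked_example`. The planted arm effect (8 of 12
patients) is large enough that the bootstrap call is stable from
B = 1,000 upwards.

## Problem sizes in the tests and acceptance script

Index-level checks run on thousands of small random cohorts (≤ 20
patients) where the brute-force oracle is exact and instantaneous.
Recovery and calibration studies use 100 seeded cohorts of 100–200
patients with `B = 200` (recovery; the aneuploidy stage is inert there)
or `B = 2,000` (calibration/power), sizes at which the planted effect
(0.4 mean arm status over ~95 patients, z ≈ 5 against the pooled null)
is decisively detectable while the whole suite stays fast.

## Orchestration

`run_all` executes the stages in dependency order, writes every
intermediate table as TSV plus a JSON manifest (version, seed,
thresholds, per-stage record counts), and caches the bootstrap stage
under a content hash of the status tables and its parameters — the
bootstrap dominates runtime, while every other stage is sub-second at
the scales involved, so a run-level manifest plus a single-stage cache
gives bit-identical, cheap reruns without a full content-addressed
store. Stage errors abort with the stage name; input validation
distinguishes hard schema violations (raised) from join-coverage
warnings (logged and reported).

## Known limitations

- Mutation-level source matching is exact-string on transcript ID and
  substitution; HGVS dialect differences are not normalised.
- Chromosome-level statuses are taken from the input file; derivation
  from arm statuses is not attempted.
- The "de novo start" variant labels have no universal MAF spelling;
  the shipped variant-class mapping is a plain dict users can extend.
- Stratified summaries use decade age bins and the clinical table's
  stage labels as-is; both are configuration, not biology.
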