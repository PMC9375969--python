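# driverstrength

Patient-level integration of somatic cancer driver events and ranking of
driver genes, chromosome arms and chromosomes by the **Driver Strength
Index (DSI)** and its frequency-normalised variant (**NDSI**).

## The problem

Most driver-gene catalogues rank genes by how *often* they are altered
across a cohort. Alteration frequency, however, conflates how common a
driver is with how *strong* it is: a gene that, when hit, suffices on its
own (or with one or two partners) to sustain a tumour is a stronger
driver than one that only appears alongside dozens of other events, even
if the latter is mutated more often. `driverstrength` integrates three
kinds of somatic alteration per patient — single-nucleotide alterations
(SNAs), expression-validated gene-level copy-number alterations (CNAs)
and arm/chromosome-level aneuploidy — counts unit *driver events* per
patient, and scores each driver by the company it keeps.

With `p_i` the number of patients carrying exactly `i` driver events in
total (`i = 1..100`) and `p_Ai` the number of those also carrying an
event in entity `A`:

```
DSI_A  = Σ_i  p_Ai / (i · p_i)
NDSI_A = DSI_A / Σ_i (p_Ai / p_i)
```

A driver found mostly in patients with few total events gets a high
NDSI (upper bound 1, attained when every carrier has `i = 1`); one that
only ever appears in heavily altered genomes tends to 1/100. NDSI is
invariant to the overall alteration frequency of the entity; DSI is not.

## Pipeline stages

1. **Sample QC** — keep primary malignant, non-low-quality samples with
   cancer DNA fraction ≥ 50%, subclonal genome fraction ≤ 50%, and all
   three data types present.
2. **Expression validation of CNAs (GECNAV)** — discretise expression
   relative to the per-gene median (−2 below 0.05×, −1 below 0.75×, +1
   above 1.25×, +2 above 1.75×); a CNA keeps only sign-concordant
   expression support, otherwise it is zeroed.
3. **SNA classification (SNADRIF)** — map variant classes to
   hyperactivating / inactivating / passenger / unclear; per gene compute
   the Hyperactivating-to-Inactivating SNA Ratio
   `HISR = (n_hyper + 1)/(n_inact + 1)` over genes with ≥ 10 classified
   SNAs.
4. **Aneuploidy drivers (ANDRIF)** — per cancer type, bootstrap pooled
   arm (and chromosome) statuses (10,000 replicates), one-tailed
   p-values against the resampled mean, Benjamini–Hochberg at FDR 5%;
   cohort calls are instantiated per patient with matching status sign,
   chromosome calls overriding arm calls.
5. **Driver sources** — ingest cohort-level driver-gene and
   driver-mutation lists (q ≤ 0.05), convert them to patient–gene pairs
   through the cohort's own SNA/CNA data, and keep pairs supported by
   ≥ 2 independent lists.
6. **Event classification and ranking (PALDRIC)** — classify each pair
   into SNA/CNA/mixed oncogene or tumour-suppressor classes (or
   passenger / low-probability, which count 0), pool gene and aneuploidy
   events per patient, and compute DSI/NDSI with the ranking filters
   (≥ 10 patients per entity × class, best class per entity,
   NDSI ≥ 0.05 for NDSI rankings, top 50).

A seeded synthetic-cohort generator (`driverstrength.simulate`) emits
all six input kinds with plantable driver-strength structure, so every
stage is testable without any downloads.

## Worked example

```python
import driverstrength as ds

bundle, expected = ds.worked_example()          # 12 patients, 5 genes, 1 arm driver
result = ds.run_pipeline(bundle, params=ds.PipelineParams(B=1000), seed=1)
print(result.index[["entity", "event_class", "n_patients", "dsi", "ndsi"]])
```

```
  entity       event_class  n_patients    dsi      ndsi
0   1003      CNA_oncogene           2  0.500  0.500000
1   1004    CNA_suppressor           2  0.500  0.500000
2     8q               DAG           8  0.200  0.200000
3   1001      SNA_oncogene          10  0.450  0.225000
4   1003      SNA_oncogene          10  0.450  0.225000
5   1002    SNA_suppressor          10  0.450  0.225000
6   1004    SNA_suppressor           9  0.425  0.226667
7   1004  mixed_suppressor           1  0.025  0.200000
```

The cohort has `p = {2: 2, 4: 2, 5: 8}`. Gene 1001, altered in the ten
patients with 4–5 total events, scores `DSI = 2/(4·2) + 8/(5·8) = 0.45`
and `NDSI = 0.45 / (2/2 + 8/8) = 0.225`. The amplification events of
gene 1003 live in the two 2-event patients, hence `NDSI = 0.5` — a
stronger per-event signal — but with only 2 carriers that class is
pruned by the ≥ 10-patient filter, so the ranked NDSI list keeps the
three 10-patient genes (`result.top_ndsi`). The planted 8q gain is
called DAG in the eight carriers.

The same run is available from the shell:

```bash
driverstrength run --config config.yaml   # paths, sources, thresholds, seed
```

with subcommands `gecnav`, `snadrif`, `andrif`, `sources`, `paldric`,
`simulate` and `validate` for individual stages.

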