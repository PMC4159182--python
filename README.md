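# cohortfusion

A translational-informatics core for chronic-inflammation cohort research:
a **pseudonymized multi-source cohort store** over clinical-registry,
biobank, genotype, serology and metabolic data, with cross-source Boolean
querying, waterfall cohort stratification, time-window biomarker sample
selection, and an XML service contract for pushing ACPA results to a
clinical decision support system (CDSS).

It is written for translational researchers and research engineers who need
to answer questions like *"which cryopreserved cell samples come from HLA-DR
\*04 carriers with the rs2064476 risk genotype?"* or *"which serum samples
fall inside the DAS28 follow-up window of an anti-TNF treatment episode?"*
across data sources that normally live in disconnected systems — without
ever moving a direct patient identifier.

## What it does

All sources are plain delimited tables joined on a **coded patient
identifier** (the virtual join attribute produced by the pseudonymization
layer):

| table | content |
|---|---|
| `patients` | roster: coded id, cohort (RA / psoriasis), study label |
| `visits` | registry visits: DAS28 and its components (joint counts, ESR, CRP, HAQ, global scores) |
| `treatments` | treatment episodes (opaque codes A/B/C, DMARD/cortisone/NSAID co-medication) |
| `samples` | biobank specimens: type (serum, PBMC, SFMC, …), date, cell count (×10⁶), freezer `box:cell` position, volume, status |
| `genotypes` | HLA-DR string plus one column per risk SNP (65-SNP packaged reference with major/minor/risk alleles) |
| `serology` | ACPA panel: CCP serum and Cit-C1 / Cit-Eno / Cit-Fib IgG titres |
| `psoriasis` | PASI, BMI, LDL, HDL, triglycerides at onset and 10-year follow-up |

On top of the store:

* **query** — Boolean trees of criteria (`eq/ne/gt/ge/lt/le/in_set/between`)
  over any source, evaluated at patient granularity (exists-semantics: a
  patient matches a sample criterion if ≥ 1 of their samples matches) or
  sample granularity; lossless CSV/TSV/JSON/XML export with per-column
  provenance.
* **stratify** — waterfall filtering with per-stage survivor counts,
  including the built-in RA anti-TNF response preset
  (CCP⁺ → anti-TNF start → baseline DAS28 → follow-up in the 2–3-month
  window → ΔDAS28 threshold); psoriasis metabolic condition tables; the
  four-specificity ACPA titre matrix; PASI change over 10 years.
* **windows** — the serum-sample selection algorithm: samples collected at
  most 30 days before / 40 days after a DAS start date (inclusive), and 75
  before / 152 after the DAS end date, summarized per treatment.
* **deid** — coding keys (identifier → token bijection), keyholder-gated
  re-identification with an append-only audit log, and a brute-force
  leakage scanner asserted over every export path.
* **interop** — schema-validated `GetACPAresultResponse` documents carrying
  exactly the four ACPA parameters, plus an in-process notification relay
  emulating the exchange index.
* **synth** — a seeded generator emulating the study cohorts (2001 RA / 747
  psoriasis patients by default; Hardy–Weinberg genotypes from the packaged
  allele table), plus fixtures with planted, exactly-known answers.

## Worked example

Stratify a synthetic RA cohort for anti-TNF response:

```python
from cohortfusion import (SynthConfig, generate,
                          ra_treatment_response_steps, run_waterfall)

store = generate(SynthConfig(ra_n=300, psoriasis_n=10, seed=7))
steps = ra_treatment_response_steps(delta_threshold=-1.2,
                                    anti_tnf_codes=("A",), ccp_cutoff=25.0)
report = run_waterfall(store, steps)
for label, n in report.stages:
    print(f"{label:>20}: {n}")
```

prints

```
        ccp_positive: 163
      anti_tnf_start: 123
      baseline_das28: 123
  followup_in_window: 52
         delta_das28: 52
        delta_filter: 2
```

Reading: of 300 RA patients, 163 are anti-CCP positive (titre > 25), 123 of
those start treatment A, all 123 have a DAS28 measured at treatment start,
52 also have a follow-up DAS28 in the 60–92-day window, and 2 improved by
at least 1.2 DAS28 units — the stratified responder cohort. Counts can only
shrink down the list.

The same engines are scriptable from the shell (`cohortfusion synth`,
`query`, `waterfall`, `metabolic`, `windows`, `acpa-export`,
`acpa-validate`); see `examples/` for one narrative script per capability.

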