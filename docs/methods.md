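# Methods

This note documents the data model, algorithms, defaults and design choices
behind `cohortfusion`, and what the synthetic cohorts do and do not show
about real registry data.

## The fused store

Every source is a flat table keyed by a coded patient identifier; the store
is the set of those tables plus the packaged risk-SNP reference. Referential
integrity (every child `coded_id` resolves to the patients roster) is
enforced at load time and re-checkable at any point; validation also flags
negative quantities, malformed HLA strings, out-of-pattern freezer
coordinates and unknown freezer statuses, as a report rather than an
exception, so a curator can fix a dirty export incrementally.

Conventions that matter in practice:

* **Decimal dialects.** Swedish registry exports mix decimal-comma
  (`13,5` million cells) and decimal-point conventions. The reader takes an
  explicit dialect — default point (comma-separated), `CsvDialect.comma()`
  for semicolon-separated/decimal-comma — with an opt-in sniffing mode.
  Both dialects load to identical values by construction.
* **CRP sentinel.** Registry CRP columns repeat an identical boundary value
  (default 9.99 mg/L) meaning "below detection". The raw value is preserved
  in the table; `FusedStore.crp_effective()` masks the sentinel to missing.
  The sentinel is configurable and can be disabled.
* **Dates** are ISO-8601 in files; all window arithmetic is in whole days.
* **HLA-DR normalization.** `"*15/*04"` ≡ `"*04/*15"`: alleles are split on
  `/`, stripped and sorted. The allele universe follows modern registry
  typing, in which the DR2/DR5/DR6 serogroups are reported as their split
  families (*15/*16, *11/*12, *13/*14), so *02/*05/*06 never occur; over
  that universe the enumerated 14-element *04 inclusion set used in
  queries is exactly the set of *04 carriers, which the test suite proves
  by enumeration.
* **Genotype calls are unordered**: `"GA"` ≡ `"AG"`, stored with bases
  sorted. Cell counts are stored in millions, so the classic
  "> 50,000,000 cells" criterion is written `n_cells_millions > 50`.
* The packaged reference lists 65 RA-risk SNPs with locus and
  major/minor/risk alleles; one entry (rs6682654, CD244) carries no allele
  assignments and is represented with nulls.

## Pseudonymization

`code_records` replaces direct-identifier columns with tokens
(`P` + zero-padded integer, drawn without replacement from a seeded stream
— sortable, collision-free, visibly non-identifying). The mapping is a
bijection held in a `CodingKey` that is persisted separately from any store
export; multiple identifier columns form one compound identifier.
Re-identification requires keyholder status in the access policy and every
attempt — granted or denied — appends to a JSON-lines audit log.
`scan_for_leakage` is deliberately a brute-force substring scan of every
cell (and, for exports, of the serialized text): slow and exhaustive is the
right trade-off for a privacy postcondition. The authorization model is a
flat per-user privilege set standing in for PI-granted credentials;
network authentication, encryption at rest and firewall topology are
deployment concerns outside this library. Coding is global per store by
default; a namespace field supports per-study keys.

## Query semantics

A query is a tree of AND/OR/NOT over criteria `(source, field, op, value)`.
Granularity decides the result unit:

* *patient*: a patient satisfies a leaf if **at least one** of their rows in
  the leaf's source matches (exists-semantics). This matches how cohort
  discovery questions are phrased ("patients with a sample such that …").
* *sample*: a sample-table leaf must hold on the sample row itself; leaves
  on other sources are evaluated at the patient level.

Missing data: by default a comparison on a missing value is false, hence
NOT over missing is true — the pragmatic reading for sparse registry
extracts. A strict mode implements Kleene three-valued logic (missing →
unknown; unknown propagates through the connectives; unknown rows are
excluded from results). `ne` never matches missing in either mode.

Results carry per-column provenance (which source table each column came
from), are sorted by `coded_id` then `sample_date` for reproducible
exports, and round-trip losslessly through CSV/TSV (provenance in `#`
header lines), JSON and XML (validated against a packaged result schema).
Structural identities — AND-idempotence, AND/OR monotonicity, De Morgan,
patient-count ≤ distinct-patient sample count — are property-tested against
an independent row-scan interpreter.

## Waterfall stratification

A waterfall is an ordered list of labelled steps, each mapping the current
cohort state (a per-patient frame that may carry derived columns) to the
surviving state; survivor counts are recorded per stage and are
non-increasing by construction for filtering steps. The RA anti-TNF
response preset:

1. anti-CCP positive — any serum CCP titre above the cutoff
   (default 25 units; assays differ, so this is a parameter);
2. an anti-TNF treatment start exists (treatment codes are opaque; which
   codes count as anti-TNF is a parameter, default `{"A"}`);
3. baseline DAS28: the DAS28 visit nearest the treatment start within a
   ±30-day tolerance;
4. follow-up DAS28 in the two-to-three-month window, implemented as
   [60, 92] days after baseline, inclusive (calendar months vary; the day
   values are configurable). With several in-window visits the earliest is
   used (alternatives: nearest-midpoint, or all visits with the patient
   surviving if any passes);
5. ΔDAS28 = follow-up − baseline (no filtering);
6. threshold on ΔDAS28. The threshold X is study-specific and deliberately
   a required parameter; the default comparator is ≤ (improvement).

EULAR response classification is intentionally not implemented; the preset
stratifies on raw DAS28 change only.

## Metabolic presets, ACPA matrix, PASI change

The psoriasis presets emit one row per condition and conjunction, mirroring
the standard risk-profile breakdown: high-risk (BMI>29 kg/m², LDL>4.3
mmol/L, TG>2.6 mmol/L; 6 rows) and low-risk (BMI<25, TG<2, LDL<4; 7 rows),
counting distinct patients at one timepoint (default onset). The ACPA
matrix is fixed to the four specificities (CCP serum, Cit-C1, Cit-Eno,
Cit-Fib IgG) with one column per patient — latest serum measurement by
default, or a (patient, date) column axis for longitudinal inspection;
missing titres stay missing, never zero. PASI change is
`pasi_year10 − pasi_onset`, with incomplete patients listed rather than
dropped.

## Window selection

Episodes are derived per treatment record: the episode spans from the
treatment start to the day before the patient's next treatment start;
`das_start_date`/`das_end_date` are the first/last DAS28 visits in that
span. Registry practice gives no single authoritative definition of episode
boundaries, so the builder is strategy-pluggable; `registry` is the default
and only built-in. Window membership is inclusive at both ends ("at most N
days before, up to M days after"), with defaults 30/40 (start) and 75/152
(end). Eligibility predicates (serum type, minimum volume, freezer-status
whitelist) are applied first; the per-treatment summary echoes the global
eligible count on every row, counts a sample once per window per treatment
(it may legitimately sit in both windows), and counts patients per
treatment — a patient treated sequentially with A then C contributes to
both rows, so per-treatment totals may exceed the distinct-patient count.
An optional flag deduplicates samples claimed by overlapping episodes.

## Synthetic cohorts

Defaults are the study-cohort conditions: 2001 RA and 747 psoriasis
patients, a 225/747 ten-year follow-up fraction, treatment mix from the
A/B/C patient counts (1276/95/251 of 1622 treated), and a 0.6 anti-CCP
positive fraction. Genotypes are drawn per SNP under Hardy–Weinberg
equilibrium using the packaged major/minor identities; the reference table
prints allele identities but no numeric frequencies, so a single default
minor-allele frequency (0.3, overridable per SNP) is used. Distributions
the registries do not pin down are simple parametric choices made for
testability, not epidemiology: Poisson visit and sample counts, 30–120-day
visit gaps, an AR(1) DAS28 trajectory drifting toward 3.2 with φ = 0.8,
log-normal titres separated by serostatus, normal BMI/LDL/HDL and
log-normal triglycerides around ordinary Northern-European adult values,
and a 15% CRP-sentinel rate. Everything derives from one
`numpy.random.default_rng(seed)`, so a fixed seed reproduces the store
byte for byte.

Consequently, passing tests demonstrate *engine correctness* — selection,
counting, windowing and round-trip behaviour on data with the right
structure — not that real-cohort summary counts are reproduced; headline
biobank figures depend on the actual populations and are out of scope. The
generator also omits real-data pathologies such as free-text noise,
duplicated visits, inconsistent units and mid-study assay changes.

`plant_truth` builds fixtures whose expected answers are known exactly:
seven planted *04-carrier/AG samples (with the worked example's cell
counts, freezer positions and CCP titres) among ≥ 50 decoys forced to fail
a criterion; serum samples at day offsets −31/−30/0/+40/+41 and
−76/−75/0/+152/+153 around a DAS episode's anchors; and a ten-patient
waterfall demo with five full-pathway responders and five decoys each
failing exactly one stage.

## Service contract

The exchange with the CDSS is reduced to its contract: a packaged XSD for
`GetACPAresultResponse` documents (exactly the four ACPA parameters per
result, `xsi:nil` for unmeasured titres, a required message id and schema
version), a JSON descriptor pairing request and response operations, and an
in-process notification relay replacing the county-council exchange index.
The SOAP/WSDL transport and certificate infrastructure are deliberately out
of scope; the schema is versioned so a site-specific XSD can be dropped in.
Titres are serialized as exact exponent-free decimal expansions of the
float value, which makes build → parse bit-lossless. Message ids are a
deterministic digest of patient and result date, which gives duplicate
submissions idempotent notification behaviour for free.

## Numerical and degenerate-input choices

* Window and follow-up day bounds are inclusive at both ends throughout.
* Ties for the baseline visit (equidistant before/after the start date)
  resolve to the earlier visit via stable sorting; follow-up ties resolve
  by the configured policy (earliest by default).
* Empty inputs are non-errors wherever a report is the output: empty child
  tables load as valid empty stores, an empty cohort yields a (4 × 0) ACPA
  matrix, a treatment with no patients yields a zero summary row, an
  unknown patient in an ACPA request yields a valid empty document.
* Missing episode anchor dates produce empty selections with a logged
  warning, not an exception.
* Sizes in the default test run are scaled to keep the suite fast: the
  oracle sweep uses a 100-patient store and 220 expressions; the
  Hardy–Weinberg check uses 10,000 genotype-only patients; waterfall
  soundness sweeps seeds 1–20 at 40 patients.

## Known limitations

* Episode construction is heuristic; real registries have richer
  start/stop/switch semantics than "next treatment start ends the episode".
* The strict three-valued query mode treats a patient absent from a source
  as unknown for every leaf on that source, which is conservative.
* The leakage scanner is substring-based: it will not catch transformed
  identifiers (reversed digits, checksummed variants).
* The packaged ACPA schema is a faithful reconstruction of the described
  message content, not a copy of a production site schema; deployments
  should drop in their own XSD under a new schema version.
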