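# Methods

## The data model

`cdwquery` stores every fact as one row of a single relational value
table (an entity–attribute–value schema) with four grouping levels:

```
patient  >  encounter  >  document  >  group
```

A row always carries a patient identifier and may additionally carry an
encounter, a document, and a group identifier. A concept dictionary
(id, name, value kind, domain, unit) types every row; value kinds are
`numeric`, `text`, `code`, and `date`. Absent levels are SQL `NULL`,
never the empty string, so identifier equality can never join two rows
on `""`. Identifiers compare as exact, case-sensitive strings: DICOM
UIDs and accession numbers are opaque keys.

Two irregular shapes are first-class:

* **patient-only values** (demographics such as `Sex`, `BirthYear`);
* **orphan imaging documents**: a document (and groups) with a *null*
  encounter, produced when a DICOM study has no accession number that
  resolves to a local radiology report.

A group always nests inside a document (the store rejects a group id
without a document id); under the DICOM mapping a series can never
belong to two documents, and no other data source produces bare groups.

### Entity counting

`distinct_count(level, records)` counts distinct scope prefixes of the
given depth among records anchored *at least that deep*. A null slot
forms its own key within its parent — `(P, ∅)` is one encounter-level
key, distinct from every real encounter of `P` — but a record whose
anchoring simply stops above the level (e.g. a patient-only row at the
encounter level) contributes no key there. Statistics can therefore
report orphan pseudo-encounters separately instead of silently counting
them as hospitalizations.

## Clinical and DICOM ingestion

A radiology report becomes one row per non-empty narrative field
(order identifier, short finding, finding, assessment), all sharing the
report's (patient, encounter, document) prefix; empty fields produce no
rows so value counts reflect facts. The report batch is indexed by
accession number.

Each DICOM series (series granularity only; per-image rows add bulk
without query power) is linked as follows:

* accession number found in the report index → the series **adopts the
  report's patient, encounter and document identifiers**, and its
  Series Instance UID becomes the group id — the DICOM hierarchy is
  preserved inside the warehouse;
* no or unknown accession → **orphan fallback**: DICOM patient id, null
  encounter, document id `"STUDY:" + StudyInstanceUID`. An unknown
  accession degrades to this fallback with a warning rather than an
  error, because externally transmitted studies routinely reference
  order numbers that do not exist locally.

Modality, both UIDs, the series description and any extra header tags
are stored group-scoped (one row per header value); the study
description is stored document-scoped, once per (document, study) pair.
Extra tags keep their DICOM keyword spelling as concept ids, so concept
naming needs no mapping file; study-level tags other than
StudyDescription default to group scope. Imaging rows are unique on
(scope, concept, value), which makes re-ingestion of identical input a
no-op.

## The query language and the cascade

A query holds an optional admission-date window and up to four boolean
condition trees, one per level (`AND`/`OR`, parentheses; operators
`contains`, `matches`, `==`, `!=`, `>`, `>=`, `<`, `<=`, `exists`).
Evaluation cascades from patient to group; each level filters the
*children* of the previous selection, and a level without conditions
passes all children through.

Key semantic choices:

* **Existential conditions.** A condition is true in a scope iff *some*
  record in the scope satisfies it; AND-ed conditions may be witnessed
  by different records. Same-record co-occurrence (two markers in one
  laboratory report) is expressed by lowering the level to the
  document, not by a same-row operator — that is precisely what the
  fourth level is for.
* **Orphan flow.** Orphan documents pass the encounter level only when
  that level has neither conditions nor a date window: an encounter
  constraint cannot be satisfied by a document without an encounter.
* **Admission window.** The window is an encounter property: it filters
  encounters by admission date (closed interval, whole days). At the
  patient level it only requires that the patient has an encounter at
  all. A `[*, *]` window is normalised away and is exactly a no-op.
* **Text matching.** `contains` is case-insensitive substring;
  `matches` is an unanchored case-sensitive regular expression (the
  stand-in for a full-text index; patterns may opt into `(?i)`).
* **Determinism.** All selections are sets; exports sort
  lexicographically by identifier tuple so repeated exports are
  byte-identical. Negation (`NOT`) is deliberately excluded: its
  interaction with null-slot scopes has no obvious right answer, so it
  is left out rather than guessed.

Per-level statistics report, for each *queried* level, the five
Tables-style counts (#patients, #encounters, #documents, #groups,
#values) computed by `distinct_count` **over that level's witness
records**, plus per-attribute record counts and (for text/code
attributes) unique-value counts. Counting over witnesses keeps the row
an exact description of what matched; a production display may instead
show downstream child counts per row, which here is available from the
cascade result itself (`children` of the selection).

## Single-level joins and inflation

To simulate a system without document/group levels, every condition of
the query — from all four levels — is evaluated existentially within
each entity at one join level, and **all** series hanging off the
passing entities are returned, with no group-level re-filtering.

Visibility at a join entity is its root-to-leaf path: all records below
the entity plus records anchored above it at their own depth (a
flattened row carries its ancestors' attributes). With conditions
placed at their concepts' native level — how these queries are written
in practice — this definition makes the containment chain

```
groups(multilevel) ⊆ groups(document join) ⊆ groups(encounter join) ⊆ groups(patient join)
```

provable, and it is property-tested on random instances. The inflation
report gives `100 × (n_single − n_multilevel) / n_multilevel`, rounded
half-away-from-zero to an integer for presentation (raw counts are
always included), plus the modality distribution of the excess groups.
The mean series per study is reported as `n_series / n_studies` rounded
to one decimal.

## The synthetic hospital

No real extract can ship, so a seeded generator emulates the structure
the queries exploit, at a scale of **200 patients** by default (roughly
400 encounters, 280 reports/studies, 1,400 series — two orders of
magnitude below a real two-year departmental extract, but large enough
that every query archetype selects hundreds of series while the whole
suite stays fast).

Defaults and rationale:

| parameter | default | why |
| --- | --- | --- |
| `encounters_per_patient` | 2.0 (1 + Poisson) | matches the ~2 encounters/patient of a two-year internal-medicine extract |
| `reports_per_encounter` | 0.7 (Poisson) | roughly half of encounters have imaging; some have several reports, which is what makes document-level joins differ from encounter-level ones |
| `series_per_study` | 5.0 (1 + Poisson) | typical multi-sequence study size |
| `p_orphan_series` | 0.15 | a visible minority of externally transmitted series, decided per series so the linkage rate is exactly binomial and testable |
| `modality_mix` | MR .50, PR .20, XA .12, CT .10, US .08 | MR-dominated with the contaminant modalities that coarse joins sweep up |
| `p_cardiac_report` | 0.3 | the cardiac-MR sub-population targeted by the radiology archetype |
| `p_cardiac_pr` | 0.25 | presentation states planted alongside MR acquisitions in cardiac studies — the document-join excess |
| `p_heart_failure` | 0.2 | heart-failure phenotype prevalence among encounters |

Cardiac studies draw their series from {MR, PR} (first series always
MR); generic studies draw i.i.d. from `modality_mix`. The
law-of-large-numbers calibration test therefore sets
`p_cardiac_report = 0` to isolate the mix mechanism. Heart-failure
encounters always carry the full bundle: a fixed regex-discoverable
letter phrase, LVEF in 20–40 %, an ICD code from {I11, I13, I50}, and
NT-proBNP above 1000 pg/ml.

UIDs use a fixed private root with sequential suffixes and accession
numbers are zero-padded sequences, so equal configs produce
byte-identical files. The generator writes the C-FIND-style CSV
dialect by default; an optional mode emits minimal DICOM Part-10 files
(header only) to exercise the file reader end-to-end.

**What passing tests do and do not show.** The generator reproduces the
*structural* features — hierarchy, linkage, orphans, planted
contaminants, phenotype bundles — not realistic clinical prose,
realistic DICOM tag inventories, coding practice, or the absolute scale
of a production warehouse. Green tests demonstrate that the mapping and
query semantics are correct and that the inflation effect has the
published qualitative shape (document-join inflation positive,
encounter-join inflation larger, excess dominated by PR); the absolute
synthetic counts and percentages are not comparable to the published
ones, which derive from a proprietary hospital dataset.

## Numerical and degenerate-input choices

* Dates compare as whole days; windows are closed on both ends.
* Percentages round half-away-from-zero (`floor(x + 0.5)`), matching
  how the published integers fall out of their raw counts.
* Inflation over an empty multilevel result is an error, not 0 or ∞.
* An empty store evaluates to empty selections at every level; an empty
  scope makes every condition false; an empty export is a header-only
  file.
* Numeric values coerce to float on insert; a non-numeric value for a
  numeric concept is rejected at insert time, not at query time.
* CSV dumps mark nulls with a literal `\N` so a null identifier can
  never be confused with an empty string.

## Known limitations

* Single-writer, single-process store; no schema migration or
  pseudonymization (out of scope by design).
* Free-text search is regular-expression based; there is no inverted
  index, so letter searches scan linearly.
* No `NOT`; no same-row operator (by design — lower the level instead).
* Instance-level (per-image) metadata is not modeled.
* The heart-failure query reproduces only the *shape* of a published
  detection algorithm (letter regex + LVEF threshold + ICD codes); no
  claim about its clinical validity is made or tested.
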