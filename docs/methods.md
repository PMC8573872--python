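# Methods note

This note records the semantics implemented by the package, the parameter
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the open design decisions. It makes no empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Data model

A patient is an immutable record (`events.PatientRecord`) of a birth date and
seven typed event collections: diagnoses, laboratory results, procedures,
medication orders, imaging findings, vaccinations and exam findings. Every
event carries a calendar date; dates are the only temporal granularity. All
coded fields (concepts, specialties, organisms, specimens, drug classes,
imaging observations) are validated against a closed vocabulary at
construction time, so rule evaluation never meets an unknown term. Events are
stored sorted by date; verdicts are invariant to input order (tested by
shuffling). Diagnoses flagged `uncertain` (rule-out, "possible") are excluded
from every rule.

## Rule semantics

Each of the 19 definitions is a logic tree over lettered criteria with three
combinators: `AND` (all children), `OR` (at least one), and `AND/OR`
(inclusive disjunction — one or both). `AND/OR` is truth-functionally
identical to `OR`; it is kept as a distinct node kind because the source
definitions distinguish it typographically, and `display()` renders it
faithfully. The tree shapes ship in `data/aim_rules.yaml` alongside all
numeric parameters, and `load_registry` accepts per-definition overrides
(unknown parameter names are rejected).

A definition is **met** when its tree evaluates true over the per-criterion
verdicts. `earliest_met_date` is the smallest date *t* such that the tree is
satisfied using only each criterion's first-documented date ≤ *t*; it is
present exactly when the definition is met and is never before birth.

### Criterion primitives

| Primitive | Default | Rationale |
|---|---|---|
| Episode gap | 30 days | Diagnoses ≤ 30 days apart (transitively) are one illness episode, so re-documentation of a single infection is not double-counted. |
| Counting window | 365 days | "Per year" thresholds (≥ 3 strep episodes, ≥ 4 sinusitis episodes) use the maximum count of episode *starts* in any closed 365-day window, anchored at episode starts — verified against an exhaustive day-scan oracle. |
| Diagnosis ↔ lab linkage | ± 14 days | A confirmatory lab within two weeks of the diagnosis supports the same illness. |
| Sinusitis diagnosis ↔ antibiotic | − 1 / + 3 days | Antibiotic orders follow the visit closely; a same-episode order may be entered the day before the coded diagnosis. |
| Urine culture ↔ urinalysis | ± 1 day | Both specimens come from the same clinical encounter. |
| Recurrent documentation | ≥ 2 diagnoses, span ≥ 183 days, ≥ 1 specialist | Chronic conditions (definitions 15–19) require persistence (≈ half a year) and specialist corroboration, not a single coded visit. |
| Fever | ≥ 100.5 °F | Pneumonia exam criterion (with cough and rales). |
| Breakthrough varicella | ≥ 42 days post-vaccination | Applies to both the diagnosis and PCR paths; unvaccinated patients never qualify for *breakthrough* disease. |
| Urine culture CFU | suprapubic: any growth; catheter ≥ 50,000; clean catch ≥ 100,000 CFU/mL | Specimen-specific contamination risk. Pyuria: ≥ 10 WBC/µL unspun or ≥ 5 WBC/hpf centrifuged. |
| Celiac TTG | strictly > 10 × ULN | See "Open design decisions". |
| Tympanostomy surrogate | CPT {69433, 69436} | Tube placement as evidence of recurrent/persistent otitis media. |

All windows and thresholds are configurable per definition via YAML overrides;
the defaults above are the reference conditions exercised by the tests.

### Boundary behaviour

All comparisons at printed thresholds are inclusive of the threshold value
(≥ / ≤), with one deliberate exception (TTG, strictly >). Ten boundary
fixtures pin this: for each printed threshold a patient exactly at the value
passes and a patient one resolution step away fails.

### Monotonicity

Adding events never un-meets a definition, with one principled carve-out:
for episode-counted rules (2 and 5), adding a diagnosis *between* two existing
episodes can merge them and lower the episode count. This is intended
semantics — the new diagnosis reveals that what looked like two illnesses was
one continuous illness — and is pinned by a dedicated test. The monotonicity
test therefore adds only events in disjoint date ranges (duplicates, benign
noise, and a full second condition), under which all verdicts are preserved.

## Delphi arithmetic

Percent agreement is computed in exact integer arithmetic,
`(200·yes + n) // (2·n)`, which equals half-up rounding of `100·yes/n`
(7 of 8 → 88, not 87). Half-up was chosen because it reproduces the
percentages in the shipped agreement table; a brute-force `Decimal` oracle over all panel sizes ≤ 13 confirms
the identity. Consensus levels: < 60 none, 60–79 moderate, ≥ 80 strong;
definitions below 60 % after a round enter the revision queue for the next
round, and round indices per panel and definition must be contiguous from 1.
The packaged final agreement table yields: 18 of 19 definitions strong in
both panels; external histogram {80 %: 7, 100 %: 12}; internal histogram
{75 %: 1, 88 %: 9, 100 %: 9}.

## Synthetic cohort generator

The generator produces a cohort with an exhaustive gold label for every
patient × definition pair: `positive` (a designed case), `near_miss` (a
designed case failing exactly one criterion, drawn from a per-definition
catalogue — e.g. catheter culture at 49,999 CFU/mL, varicella at day 41,
urinalysis outside the ± 1-day window), or `unrelated`. Defaults: 500-patient
problem sizes in the acceptance script, prevalence 0.2 per definition,
near-miss rate 0.5 among negatives, Poisson(3) benign noise events per
patient. All randomness flows through one seeded `numpy` generator, so the
same seed yields byte-identical bundles.

**Cross-talk control.** Each definition's evidence occupies a dedicated
per-definition date slot (345-day pitch, 45-day guard gap exceeding every
linkage window), so evidence planted for one definition can never
accidentally satisfy or link into another. Two clinically entangled pairs
need extra care: zoster positives in vaccinated patients use the antiviral
path rather than VZV PCR (which would otherwise satisfy breakthrough
varicella), and the breakthrough-varicella PCR path is suppressed when the
patient carries a zoster near-miss design. The tests verify purity directly:
every near-miss variant in isolation meets **no** definition, and every
positive builder meets **exactly** its own.

**What it does and does not emulate.** The generator emulates the *logical*
structure of EHR evidence — linked labs, episode spacing, specialist
documentation, contaminated cultures, afebrile exams, rule-out codes — well
enough to exercise every criterion and its failure modes. It does not emulate
realistic marginal frequencies, code co-occurrence, visit cadence,
missingness, free text, or inter-condition correlation; labels are
per-definition independent by design so that sensitivity and specificity are
attributable to single rules.

## Open design decisions

- **TTG threshold strictness.** The source material states the 10× ULN
  threshold both inclusively and strictly in different places. The package
  implements strictly greater (10.1 × passes, 10.0 × fails), following the
  prose "greater than 10-fold"; the boundary fixture pins this choice and a
  single parameter (`ttg_uln_multiple`) plus one comparison would flip it.
- **`AND/OR` as inclusive disjunction.** Interpreted as "one or both"; an
  exclusive reading would make the pneumonia rule fail patients with *both*
  exam and imaging evidence, which is clinically indefensible.
- **Episode merging vs. monotonicity** (above): merging wins.
- **No fitted-model API.** The package is a deterministic rule engine with no
  estimation step, so it exposes definitions/evaluators/reports directly
  rather than a model–fit–results triple.

## Numerical choices

Agreement percentages use exact integer arithmetic (no floating point).
Episode grouping, window counting and linkage operate on `datetime.date` and
integer day arithmetic. CSV serialization formats floats by writing integral
values as integers and others via `repr`, so round-trips are byte-identical
(e.g. 1,000,000 is never written as `1e+06`). Temperatures are stored in
Fahrenheit; the loader can convert from Celsius (`F = C·9/5 + 32`).

## Limitations

- The closed vocabulary is a miniature stand-in for real terminologies
  (ICD/SNOMED/LOINC/RxNorm); deploying on real data requires mapping layers.
- Date-only granularity cannot express same-day ordering (e.g. culture drawn
  before antibiotics).
- Perfect sensitivity/specificity on the synthetic cohort shows the engine
  matches its own specification, not that the definitions are accurate
  against chart review.
- The Delphi module tabulates ballots; it does not model panelist behaviour
  or comment-driven revision content.
- `earliest_met_date` uses each criterion's first-documented date and may be
  conservative for criteria that are met, lost, and met again.
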