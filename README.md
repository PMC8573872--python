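# aimphenotype

Rule-based computable phenotyping of **19 asthma-associated infectious and
inflammatory multimorbidities (AIMs)** from structured electronic-health-record
(EHR) event tables, together with the modified-Delphi consensus arithmetic used
to ratify the definitions and a gold-labeled synthetic cohort generator for
validating the rule engine.

## Scientific problem

Asthma frequently co-occurs with a set of infectious and inflammatory
conditions, but studying those associations at scale requires *operational*
definitions — rules precise enough that a program can decide, from coded EHR
data alone, whether a patient meets each condition. Diagnosis codes alone are
unreliable (rule-out codes, contaminated cultures, unconfirmed clinical
impressions), so each definition combines diagnosis events with confirmatory
laboratory, imaging, medication, procedure, vaccination and exam evidence.

The package implements 19 such definitions — 11 infectious and 8
inflammatory:

| # | Definition | # | Definition |
|---|---|---|---|
| 1 | Invasive bacterial infection | 11 | Viral infection confirmed by lab |
| 2 | Frequent *S. pyogenes* upper respiratory infection | 12 | Celiac disease |
| 3 | Pneumonia | 13 | Kawasaki disease |
| 4 | Recurrent/persistent otitis media | 14 | Appendicitis |
| 5 | Recurrent/persistent infectious sinusitis | 15 | Autoimmune thyroiditis |
| 6 | *Bordetella pertussis* | 16 | Diabetes type 1 |
| 7 | Breakthrough varicella infection | 17 | Diabetes type 2 |
| 8 | Zoster (shingles) | 18 | Inflammatory bowel disease |
| 9 | Urinary tract infection | 19 | JRA/JIA/RA |
| 10 | Skin fungal infection | | |

Each definition is a small logic tree over lettered criteria. The grammar has
three combinators — `AND` (all), `OR` (exactly the usual disjunction) and
`AND/OR` (inclusive disjunction: one or both) — e.g. pneumonia is
`A AND (B AND/OR C)`: a pneumonia diagnosis, plus a qualifying exam (fever
≥ 100.5 °F and cough and rales) and/or chest imaging with infiltrates or
consolidation. Criteria are built from reusable primitives:

- **episode grouping** — diagnoses ≤ 30 days apart merge transitively into one
  illness episode, so three strep diagnoses in one month count once;
- **rolling-window counting** — e.g. ≥ 3 distinct confirmed strep episodes
  within any 365-day window;
- **event linkage** — a diagnosis only counts when a confirmatory lab falls in
  a window around it (± 14 days by default; − 1/+ 3 days for
  sinusitis-antibiotics; ± 1 day for urine culture ↔ urinalysis);
- **quantitative thresholds** — e.g. urine culture ≥ 50,000 CFU/mL (catheter)
  or ≥ 100,000 CFU/mL (clean catch), pyuria ≥ 10 WBC/µL (unspun) or ≥ 5
  WBC/hpf (centrifuged), tissue transglutaminase IgA strictly > 10× the upper
  limit of normal;
- **recurrent documentation** — chronic conditions (definitions 15–19) require
  ≥ 2 diagnoses spanning ≥ 183 days with at least one from a relevant
  specialist.

The definitions were ratified by a modified-Delphi process: anonymous yes/no
voting by an internal expert panel (n = 8, three rounds) and an external panel
(n = 5, two rounds). Percent agreement is yes-votes over votes, rounded
half-up to an integer; < 60 % is no consensus (queued for revision), 60–79 %
moderate, ≥ 80 % strong. The package ships the final per-panel agreement
table and reproduces its summary: 18 of 19 definitions reached strong
consensus in both panels.

## Worked example

Generate a gold-labeled synthetic cohort, evaluate all 19 definitions, and
score the engine against the generator's labels:

```bash
$ aimphenotype generate --out cohort --n 200 --seed 7
wrote 200 patients to cohort

$ aimphenotype evaluate cohort --out results.csv
200 patients, 3800 verdicts, 762 met
  definition  1: 58 met
  definition  2: 44 met
  definition  3: 41 met
  ...
  definition 19: 36 met

$ aimphenotype validate cohort
sensitivity=1.0000 specificity=1.0000 (tp=762 fn=0 tn=3038 fp=0)

$ head -3 results.csv
patient_id,aim_id,name,met,earliest_met_date,evidence
P00000,1,Invasive bacterial infection,False,,A:1
P00000,2,Frequent Streptococcus pyogenes upper respiratory infection,False,,
```

Tabulate Delphi ballots (one row per panelist × round × definition):

```bash
$ aimphenotype delphi ballots.csv --out report.csv
internal round 1: queued for revision -> [13]
wrote 3 reports to report.csv

$ cat report.csv
panel,round_index,aim_id,n_votes,n_yes,agreement_pct,level
internal,1,13,8,4,50,none
internal,2,13,8,6,75,moderate
internal,3,13,8,7,88,strong
```

The same functionality is available as a library:

```python
>>> from aimphenotype.delphi import summarize_final
>>> s = summarize_final()
>>> s.strong_in_both, s.internal_histogram, s.external_histogram
(18, {75: 1, 88: 9, 100: 9}, {80: 7, 100: 12})
```

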