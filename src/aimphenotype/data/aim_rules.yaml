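# The 19 operational phenotype definitions: criterion trees and tunable
# parameters.  Trees use the combinator grammar of aimphenotype.primitives:
# a bare letter is a leaf criterion, {and|or|and_or: [...]} a combination.
# "and_or" is inclusive disjunction, displayed as "AND/OR".
#
# Every threshold and window here can be overridden at run time without code
# edits; the values below are the ratified defaults.  Linkage windows (in
# days) operationalize "related to" clauses the prose leaves implicit.

- aim_id: 1
  name: Invasive bacterial infection
  category: infectious
  tree: {and: [A, B]}
  parameters:
    culture_link_days: 14
    diagnosis_concepts: [sepsis, bacteremia, meningitis, encephalitis, mastoiditis,
                         brain_abscess, pneumonia, cellulitis, osteomyelitis,
                         septic_arthritis, pleuritis, pericarditis, pyelonephritis]

- aim_id: 2
  name: Frequent Streptococcus pyogenes upper respiratory infection
  category: infectious
  tree: {and: [A, B, C]}
  parameters:
    diagnosis_concepts: [sore_throat, pharyngitis, tonsillitis]
    test_link_days: 14
    episode_gap_days: 30
    window_days: 365
    min_episodes: 3

- aim_id: 3
  name: Pneumonia
  category: infectious
  tree: {and: [A, {and_or: [B, C]}]}
  parameters:
    exam_link_days: 14
    min_temperature_f: 100.5

- aim_id: 4
  name: Recurrent/persistent otitis media
  category: infectious
  tree: A
  parameters:
    # CPT codes for tympanostomy tube placement (with/without anesthesia)
    tympanostomy_cpt_codes: ["69433", "69436"]

- aim_id: 5
  name: Recurrent/persistent infectious sinusitis
  category: infectious
  tree: {and: [A, {and_or: [B, C]}]}
  parameters:
    antibiotic_days_before: 1
    antibiotic_days_after: 3
    episode_gap_days: 30
    window_days: 365
    min_episodes: 4

- aim_id: 6
  name: Bordetella pertussis
  category: infectious
  tree: A
  parameters: {}

- aim_id: 7
  name: Breakthrough varicella infection
  category: infectious
  tree: {and_or: [A, B]}
  parameters:
    min_days_after_vaccination: 42

- aim_id: 8
  name: Zoster (shingles)
  category: infectious
  tree: {and: [A, {and_or: [B, C]}]}
  parameters:
    antiviral_link_days: 14

- aim_id: 9
  name: Urinary tract infection
  category: infectious
  tree: {and: [A, B]}
  parameters:
    suprapubic_min_cfu: 0          # any recovery qualifies
    catheter_min_cfu: 50000
    clean_catch_min_cfu: 100000
    pyuria_min_wbc_per_ul: 10
    pyuria_min_wbc_per_hpf: 5
    urinalysis_link_days: 1

- aim_id: 10
  name: Skin fungal infection
  category: infectious
  tree: {and_or: [A, B]}
  parameters:
    antifungal_link_days: 14

- aim_id: 11
  name: Viral infection confirmed by lab
  category: infectious
  tree: {and: [A, B]}
  parameters:
    lab_link_days: 14

- aim_id: 12
  name: Celiac disease
  category: inflammatory
  tree: {and: [A, {and_or: [{and: [B, C]}, {and: [D, E]}]}]}
  parameters:
    # "more than 10x the upper limit of normal"; strict comparison
    ttg_fold_uln_threshold: 10

- aim_id: 13
  name: Kawasaki disease
  category: inflammatory
  tree: A
  parameters:
    specialist_set: [infectious_disease, cardiology, rheumatology]

- aim_id: 14
  name: Appendicitis
  category: inflammatory
  tree: {or: [A, {and: [B, C]}]}
  parameters: {}

- aim_id: 15
  name: Autoimmune thyroiditis
  category: inflammatory
  tree: A
  parameters:
    diagnosis_concepts: [autoimmune_thyroiditis]
    min_count: 2
    min_span_days: 183
    specialist_set: [endocrinology]
    specialist_min: 1

- aim_id: 16
  name: Diabetes type 1
  category: inflammatory
  tree: A
  parameters:
    diagnosis_concepts: [diabetes_type1]
    min_count: 2
    min_span_days: 183
    specialist_set: [endocrinology]
    specialist_min: 1

- aim_id: 17
  name: Diabetes type 2
  category: inflammatory
  tree: A
  parameters:
    diagnosis_concepts: [diabetes_type2]
    min_count: 2
    min_span_days: 183
    specialist_set: [endocrinology]
    specialist_min: 1

- aim_id: 18
  name: Inflammatory bowel disease
  category: inflammatory
  tree: A
  parameters:
    diagnosis_concepts: [ibd, crohns, ulcerative_colitis]
    min_count: 2
    min_span_days: 183
    specialist_set: [gastroenterology]
    specialist_min: 1

- aim_id: 19
  name: JRA/JIA/RA
  category: inflammatory
  tree: A
  parameters:
    diagnosis_concepts: [jra_jia_ra]
    min_count: 2
    min_span_days: 183
    specialist_set: [rheumatology]
    specialist_min: 1
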