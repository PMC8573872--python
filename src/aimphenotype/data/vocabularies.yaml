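# Controlled vocabularies for structured EHR events.
#
# These are the only terms the loader accepts for the open-ended fields
# (diagnosis concepts, provider specialties, lab organisms).  Keeping them in
# one packaged file guarantees the rule definitions and the cohort inputs
# cannot drift apart.

concepts:
  # infectious-disease concepts
  - pneumonia
  - sinusitis
  - sore_throat
  - pharyngitis
  - tonsillitis
  - sepsis
  - bacteremia
  - meningitis
  - encephalitis
  - mastoiditis
  - brain_abscess
  - cellulitis
  - osteomyelitis
  - septic_arthritis
  - pleuritis
  - pericarditis
  - pyelonephritis
  - uti
  - varicella
  - zoster
  - skin_fungal_infection
  - viral_infection_respiratory
  - viral_infection_gastrointestinal
  - appendicitis
  # dedicated negative concepts: an operative note describing a normal or
  # incidentally removed appendix must never count as an appendicitis finding
  - normal_appendix
  - incidental_appendectomy
  # inflammatory-disease concepts
  - celiac_disease
  - kawasaki_disease
  - autoimmune_thyroiditis
  - diabetes_type1
  - diabetes_type2
  - ibd
  - crohns
  - ulcerative_colitis
  - jra_jia_ra
  # benign concepts (background noise in synthetic cohorts; no rule uses them)
  - eczema
  - atopic_dermatitis
  - allergic_rhinitis
  - well_child_visit
  - ankle_sprain

specialties:
  - gastroenterology
  - endocrinology
  - rheumatology
  - infectious_disease
  - cardiology
  - surgery
  - primary_care
  - other

organisms:
  - streptococcus_pyogenes
  - bordetella_pertussis
  - vzv
  - any_pathogenic_bacteria
  - fungus
  - respiratory_virus
  - gi_virus
  - streptococcus_pneumoniae
  - staphylococcus_aureus
  - escherichia_coli
  - neisseria_meningitidis
  - haemophilus_influenzae
  # common culture contaminants (skin flora) — never "pathogenic bacteria"
  - staphylococcus_epidermidis
  - corynebacterium_spp
  - cutibacterium_acnes
  - bacillus_spp

# Organisms that satisfy "any pathogenic bacteria" in the invasive
# bacterial-infection rule.
pathogenic_bacteria:
  - any_pathogenic_bacteria
  - streptococcus_pneumoniae
  - streptococcus_pyogenes
  - staphylococcus_aureus
  - escherichia_coli
  - neisseria_meningitidis
  - haemophilus_influenzae

# Organisms treated as contamination of a culture, not true pathogens.
contaminants:
  - staphylococcus_epidermidis
  - corynebacterium_spp
  - cutibacterium_acnes
  - bacillus_spp

# Normally sterile body-fluid specimens.
sterile_specimens:
  - blood
  - csf
  - pleural_fluid
  - pericardial_fluid
  - peritoneal_fluid
  - synovial_fluid
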