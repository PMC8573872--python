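"""Seeded generator of gold-labeled synthetic pediatric cohorts.

Every phenotype rule must be testable without any data download, so the
generator constructs patients whose records are *designed* to satisfy a
definition (positives), to fail it by exactly one criterion or one boundary
(near-misses), or to be unrelated background noise.  The intent is recorded as
a :class:`GoldLabel` per (patient, definition), which makes the generator an
independent oracle: the engine is validated by demanding perfect sensitivity
and specificity against these labels.

Design notes:

* Each patient's events for definition *k* occupy a dedicated date slot
  (345-day pitch from birth, at most 300 days used per slot), so the 45-day
  inter-slot gap exceeds every linkage window and episode gap.  A near-miss
  engineered for one definition therefore cannot accidentally satisfy
  another, even in patients designed for many conditions at once.
* The near-miss catalog is enumerated per criterion, not sampled from a
  distribution, so coverage is auditable; which catalog entry a given
  near-miss patient receives is drawn from the seeded generator.
* Zoster positives in patients who carry a varicella vaccination are built on
  the antiviral-treatment path rather than the VZV-PCR path, because a
  free-floating positive VZV PCR after vaccination would satisfy the
  breakthrough-varicella rule as well.
* Background noise draws on concepts, drug classes and exam values that no
  rule references (benign diagnoses, afebrile exams, unrelated CPT codes).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .definitions import N_DEFINITIONS, default_registry, evaluate_aim
from .events import (
    DiagnosisEvent,
    DrugClass,
    ExamFinding,
    HistologyFinding,
    ImagingFinding,
    ImagingObservation,
    LabKind,
    LabResult,
    MedicationOrder,
    Modality,
    PatientRecord,
    ProcedureEvent,
    QuantityUnits,
    SourceSection,
    Specimen,
    VaccinationEvent,
    Vaccine,
)

SLOT_PITCH_DAYS = 345  # per-definition slot spacing from birth
SLOT_OFFSET_DAYS = 30
MAX_NOISE_DAY = 6569  # ~18 years of follow-up

Label = Literal["positive", "near_miss", "unrelated"]


class GoldLabel(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    aim_id: int = Field(ge=1, le=N_DEFINITIONS)
    label: Label
    variant: Optional[str] = None  # near-miss catalog entry, when applicable


class GeneratorConfig(BaseModel):
    """Generation settings for one synthetic cohort.

    ``prevalence`` is the per-definition probability that a patient is a
    designed positive (a scalar applies to all 19); among designed negatives,
    ``near_miss_rate`` is the probability of receiving a near-miss record for
    that definition rather than nothing.
    """

    n_patients: int = Field(ge=0)
    seed: int
    prevalence: float | dict[int, float] = 0.2
    near_miss_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    noise_events_per_patient: float = Field(default=3.0, ge=0.0)

    @field_validator("prevalence")
    @classmethod
    def _prob_range(cls, v):
        values = v.values() if isinstance(v, dict) else [v]
        if any(not 0.0 <= p <= 1.0 for p in values):
            raise ValueError("prevalence probabilities must lie in [0, 1]")
        return v

    def prevalence_for(self, aim_id: int) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence.get(aim_id, 0.0)
        return self.prevalence


# ---------------------------------------------------------------------------
# record sketch: accumulates events for one patient
# ---------------------------------------------------------------------------

@dataclass
class _Sketch:
    patient_id: str
    birth: dt.date
    rng: np.random.Generator
    has_vaccination: bool = False
    aim8_design: Optional[str] = None
    diagnoses: list = field(default_factory=list)
    labs: list = field(default_factory=list)
    procedures: list = field(default_factory=list)
    medications: list = field(default_factory=list)
    imaging: list = field(default_factory=list)
    vaccinations: list = field(default_factory=list)
    exams: list = field(default_factory=list)

    def date(self, offset: int) -> dt.date:
        return self.birth + dt.timedelta(days=int(offset))

    def dx(self, off, concept, specialty="primary_care", section=SourceSection.diagnosis,
           uncertain=False):
        self.diagnoses.append(
            DiagnosisEvent(
                date=self.date(off), concept=concept, provider_specialty=specialty,
                source_section=section, uncertain=uncertain,
            )
        )

    def lab(self, off, kind, **kw):
        self.labs.append(LabResult(date=self.date(off), kind=kind, **kw))

    def med(self, off, drug_class, name=None):
        self.medications.append(
            MedicationOrder(date=self.date(off), drug_class=drug_class, name=name)
        )

    def proc(self, off, cpt, description=None):
        self.procedures.append(
            ProcedureEvent(date=self.date(off), cpt_code=cpt, description=description)
        )

    def img(self, off, modality, findings=()):
        self.imaging.append(
            ImagingFinding(date=self.date(off), modality=modality, findings=tuple(findings))
        )

    def vacc(self, off, vaccine=Vaccine.varicella):
        self.vaccinations.append(VaccinationEvent(date=self.date(off), vaccine=vaccine))

    def exam(self, off, temperature_f=None, cough=False, rales=False):
        self.exams.append(
            ExamFinding(
                date=self.date(off), temperature_f=temperature_f, cough=cough,
                rale_crackle_crepitation=rales,
            )
        )

    def build(self) -> PatientRecord:
        return PatientRecord(
            patient_id=self.patient_id,
            birth_date=self.birth,
            diagnoses=tuple(self.diagnoses),
            labs=tuple(self.labs),
            procedures=tuple(self.procedures),
            medications=tuple(self.medications),
            imaging=tuple(self.imaging),
            vaccinations=tuple(self.vaccinations),
            exams=tuple(self.exams),
        )


def _slot(aim_id: int) -> int:
    return SLOT_OFFSET_DAYS + (aim_id - 1) * SLOT_PITCH_DAYS


def _choice(rng: np.random.Generator, options: Sequence):
    return options[int(rng.integers(len(options)))]


# ---------------------------------------------------------------------------
# designed-positive builders (one per definition)
# ---------------------------------------------------------------------------

_STERILE = ["blood", "csf", "pleural_fluid", "synovial_fluid"]
_PATHOGENS = [
    "streptococcus_pneumoniae", "staphylococcus_aureus", "escherichia_coli",
    "neisseria_meningitidis", "haemophilus_influenzae",
]
_INVASIVE_DX = ["sepsis", "bacteremia", "meningitis", "osteomyelitis", "cellulitis"]
_THROAT_DX = ["sore_throat", "pharyngitis", "tonsillitis"]


def _pos1(b: _Sketch, base: int) -> None:
    specimen = Specimen(_choice(b.rng, _STERILE))
    organism = _choice(b.rng, _PATHOGENS)
    b.lab(base, LabKind.culture, specimen=specimen, organism=organism, positive=True)
    b.dx(base + int(b.rng.integers(0, 8)), _choice(b.rng, _INVASIVE_DX),
         specialty="infectious_disease")


def _strep_episode(b: _Sketch, day: int, positive: bool = True) -> None:
    b.dx(day, _choice(b.rng, _THROAT_DX))
    kind = _choice(b.rng, [LabKind.radt, LabKind.culture, LabKind.pcr])
    b.lab(day, kind, specimen=Specimen.throat, organism="streptococcus_pyogenes",
          positive=positive)


def _pos2(b: _Sketch, base: int) -> None:
    for k in range(3):
        _strep_episode(b, base + k * 45)


def _pos3(b: _Sketch, base: int) -> None:
    b.dx(base, "pneumonia")
    path = int(b.rng.integers(3))
    if path in (0, 2):
        b.exam(base, temperature_f=100.5 + float(b.rng.integers(0, 30)) / 10,
               cough=True, rales=True)
    if path in (1, 2):
        b.img(base, Modality.chest_xray,
              [_choice(b.rng, list(ImagingObservation)[:3])])


def _pos4(b: _Sketch, base: int) -> None:
    b.proc(base, _choice(b.rng, ["69433", "69436"]), "tympanostomy tube placement")


def _sinusitis_episodes(b: _Sketch, base: int, n: int, abx: bool = True,
                        abx_offset: int = 1) -> None:
    for k in range(n):
        day = base + k * 40
        b.dx(day, "sinusitis")
        if abx:
            b.med(day + abx_offset, DrugClass.antibiotic, "amoxicillin")


def _pos5(b: _Sketch, base: int) -> None:
    _sinusitis_episodes(b, base, 4)
    if b.rng.random() < 0.5:
        b.img(base + 10, Modality.sinus_ct,
              [_choice(b.rng, [ImagingObservation.sinus_opacification,
                               ImagingObservation.air_fluid_level])])
    else:
        b.dx(base + 130, "sinusitis", specialty="surgery",
             section=SourceSection.operative_note)


def _pos6(b: _Sketch, base: int) -> None:
    b.lab(base, LabKind.pcr, specimen=Specimen.upper_respiratory,
          organism="bordetella_pertussis", positive=True)


def _pos7(b: _Sketch, base: int) -> None:
    b.vacc(base)
    day = base + 42 + int(b.rng.integers(0, 60))
    b.dx(day, "varicella")
    # PCR confirmation is safe to add unless this patient also carries a
    # zoster near-miss, whose rule must stay unmet
    if b.aim8_design != "near_miss" and b.rng.random() < 0.3:
        b.lab(day, LabKind.pcr, specimen=Specimen.skin, organism="vzv", positive=True)


def _pos8(b: _Sketch, base: int) -> None:
    b.dx(base, "zoster")
    if b.has_vaccination or b.rng.random() < 0.5:
        b.med(base + 1, DrugClass.antiviral_vzv, "acyclovir")
    else:
        b.lab(base, LabKind.pcr, specimen=Specimen.skin, organism="vzv", positive=True)


def _urine_culture(b: _Sketch, day: int, specimen: Specimen, cfu: Optional[float]) -> None:
    kw: dict = dict(specimen=specimen, organism="escherichia_coli", positive=True)
    if cfu is not None:
        kw.update(quantity=cfu, quantity_units=QuantityUnits.cfu_per_ml)
    b.lab(day, LabKind.culture, **kw)


def _pyuria(b: _Sketch, day: int, *, wbc_ul: Optional[float] = None,
            wbc_hpf: Optional[float] = None) -> None:
    if wbc_ul is not None:
        b.lab(day, LabKind.urinalysis, specimen=Specimen.urine_clean_catch,
              positive=True, quantity=wbc_ul, quantity_units=QuantityUnits.wbc_per_ul_unspun)
    else:
        b.lab(day, LabKind.urinalysis, specimen=Specimen.urine_clean_catch,
              positive=True, quantity=wbc_hpf,
              quantity_units=QuantityUnits.wbc_per_hpf_centrifuged)


def _pos9(b: _Sketch, base: int) -> None:
    variant = int(b.rng.integers(3))
    if variant == 0:
        _urine_culture(b, base, Specimen.urine_suprapubic, None)
    elif variant == 1:
        _urine_culture(b, base, Specimen.urine_catheter, 50000 + float(b.rng.integers(0, 50000)))
    else:
        _urine_culture(b, base, Specimen.urine_clean_catch, 100000 + float(b.rng.integers(0, 50000)))
    if b.rng.random() < 0.5:
        _pyuria(b, base, wbc_ul=10 + float(b.rng.integers(0, 90)))
    else:
        _pyuria(b, base, wbc_hpf=5 + float(b.rng.integers(0, 20)))


def _pos10(b: _Sketch, base: int) -> None:
    if b.rng.random() < 0.5:
        b.dx(base, "skin_fungal_infection")
        b.med(base, DrugClass.antifungal, "clotrimazole")
    else:
        kind = _choice(b.rng, [LabKind.culture, LabKind.fungal_smear])
        kw = dict(specimen=Specimen.skin, positive=True)
        if kind is LabKind.culture:
            kw["organism"] = "fungus"
        b.lab(base, kind, **kw)


def _pos11(b: _Sketch, base: int) -> None:
    if b.rng.random() < 0.5:
        b.dx(base, "viral_infection_respiratory")
        b.lab(base, _choice(b.rng, [LabKind.pcr, LabKind.culture]),
              specimen=Specimen.upper_respiratory, organism="respiratory_virus", positive=True)
    else:
        b.dx(base, "viral_infection_gastrointestinal")
        b.lab(base, LabKind.pcr, specimen=Specimen.other, organism="gi_virus", positive=True)


def _pos12(b: _Sketch, base: int) -> None:
    b.dx(base, "celiac_disease", specialty="gastroenterology")
    if b.rng.random() < 0.5:
        # serologic path: strongly elevated TTG IgA plus EMA/DGA positivity
        b.lab(base, LabKind.serology_ttg_iga, specimen=Specimen.blood, positive=True,
              quantity=11 + float(b.rng.integers(0, 10)), quantity_units=QuantityUnits.fold_uln)
        b.lab(base, _choice(b.rng, [LabKind.serology_ema, LabKind.serology_dga]),
              specimen=Specimen.blood, positive=True)
    else:
        # histologic path: positive TTG IgA plus duodenal-biopsy findings
        b.lab(base, LabKind.serology_ttg_iga, specimen=Specimen.blood, positive=True,
              quantity=3 + float(b.rng.integers(0, 6)), quantity_units=QuantityUnits.fold_uln)
        b.lab(base + 14, LabKind.histology, specimen=Specimen.duodenal_biopsy, positive=True,
              histology_findings=(_choice(b.rng, list(HistologyFinding)),))


def _pos13(b: _Sketch, base: int) -> None:
    b.dx(base, "kawasaki_disease",
         specialty=_choice(b.rng, ["infectious_disease", "cardiology", "rheumatology"]))


def _pos14(b: _Sketch, base: int) -> None:
    if b.rng.random() < 0.5:
        b.dx(base, "appendicitis", specialty="surgery", section=SourceSection.operative_note)
    else:
        b.dx(base, "appendicitis")
        b.img(base, _choice(b.rng, [Modality.abdominal_ct, Modality.ultrasound]),
              [ImagingObservation.appendicitis_suggestive])


def _make_recurrent_pos(concepts: Sequence[str], specialist: str):
    def build(b: _Sketch, base: int) -> None:
        concept = _choice(b.rng, list(concepts))
        gap = 183 + int(b.rng.integers(0, 60))
        b.dx(base, concept, specialty=specialist)
        b.dx(base + gap, concept, specialty="primary_care")
    return build


_POSITIVE_BUILDERS: dict[int, Callable[[_Sketch, int], None]] = {
    1: _pos1, 2: _pos2, 3: _pos3, 4: _pos4, 5: _pos5, 6: _pos6, 7: _pos7,
    8: _pos8, 9: _pos9, 10: _pos10, 11: _pos11, 12: _pos12, 13: _pos13, 14: _pos14,
    15: _make_recurrent_pos(["autoimmune_thyroiditis"], "endocrinology"),
    16: _make_recurrent_pos(["diabetes_type1"], "endocrinology"),
    17: _make_recurrent_pos(["diabetes_type2"], "endocrinology"),
    18: _make_recurrent_pos(["ibd", "crohns", "ulcerative_colitis"], "gastroenterology"),
    19: _make_recurrent_pos(["jra_jia_ra"], "rheumatology"),
}


# ---------------------------------------------------------------------------
# near-miss catalog: each entry violates exactly one criterion or boundary
# ---------------------------------------------------------------------------

def _nm1_contaminant(b, base):
    b.lab(base, LabKind.culture, specimen=Specimen.blood,
          organism="staphylococcus_epidermidis", positive=True)
    b.dx(base + 2, "bacteremia", specialty="infectious_disease")


def _nm1_nonsterile(b, base):
    b.lab(base, LabKind.culture, specimen=Specimen.other,
          organism="staphylococcus_aureus", positive=True)
    b.dx(base + 2, "cellulitis", specialty="infectious_disease")


def _nm1_no_dx(b, base):
    b.lab(base, LabKind.culture, specimen=Specimen.blood,
          organism="streptococcus_pneumoniae", positive=True)


def _nm1_dx_outside_window(b, base):
    b.lab(base, LabKind.culture, specimen=Specimen.blood,
          organism="streptococcus_pneumoniae", positive=True)
    b.dx(base + 20, "sepsis", specialty="infectious_disease")


def _nm2_two_episodes(b, base):
    for k in range(2):
        _strep_episode(b, base + k * 45)


def _nm2_negative_tests(b, base):
    for k in range(3):
        _strep_episode(b, base + k * 45, positive=False)


def _nm2_tests_without_dx(b, base):
    for k in range(3):
        b.lab(base + k * 45, LabKind.radt, specimen=Specimen.throat,
              organism="streptococcus_pyogenes", positive=True)


def _nm3_dx_only(b, base):
    b.dx(base, "pneumonia")


def _nm3_fever_below(b, base):
    b.dx(base, "pneumonia")
    b.exam(base, temperature_f=100.4, cough=True, rales=True)


def _nm3_no_cough(b, base):
    b.dx(base, "pneumonia")
    b.exam(base, temperature_f=101.2, cough=False, rales=True)


def _nm3_no_rales(b, base):
    b.dx(base, "pneumonia")
    b.exam(base, temperature_f=101.2, cough=True, rales=False)


def _nm3_exam_without_dx(b, base):
    b.exam(base, temperature_f=101.2, cough=True, rales=True)
    b.img(base, Modality.chest_xray, [ImagingObservation.consolidation])


def _nm3_exam_outside_window(b, base):
    b.dx(base, "pneumonia")
    b.exam(base + 20, temperature_f=101.2, cough=True, rales=True)


def _nm4_wrong_cpt(b, base):
    b.proc(base, "69210", "cerumen removal")


def _nm5_three_episodes(b, base):
    _sinusitis_episodes(b, base, 3)
    b.img(base + 10, Modality.sinus_ct, [ImagingObservation.sinus_opacification])


def _nm5_no_antibiotics(b, base):
    _sinusitis_episodes(b, base, 4, abx=False)
    b.img(base + 10, Modality.sinus_ct, [ImagingObservation.sinus_opacification])


def _nm5_no_imaging_or_surgery(b, base):
    _sinusitis_episodes(b, base, 4)


def _nm5_abx_outside_window(b, base):
    _sinusitis_episodes(b, base, 4, abx_offset=5)
    b.img(base + 10, Modality.sinus_ct, [ImagingObservation.sinus_opacification])


def _nm6_negative_pcr(b, base):
    b.lab(base, LabKind.pcr, specimen=Specimen.upper_respiratory,
          organism="bordetella_pertussis", positive=False)


def _nm6_culture_not_pcr(b, base):
    b.lab(base, LabKind.culture, specimen=Specimen.upper_respiratory,
          organism="bordetella_pertussis", positive=True)


def _nm6_wrong_specimen(b, base):
    b.lab(base, LabKind.pcr, specimen=Specimen.other,
          organism="bordetella_pertussis", positive=True)


def _nm7_day_41(b, base):
    b.vacc(base)
    b.dx(base + 41, "varicella")


def _nm7_unvaccinated(b, base):
    b.dx(base + 60, "varicella")


def _nm8_dx_only(b, base):
    b.dx(base, "zoster")


def _nm8_negative_pcr(b, base):
    b.dx(base, "zoster")
    b.lab(base, LabKind.pcr, specimen=Specimen.skin, organism="vzv", positive=False)


def _nm8_antiviral_outside_window(b, base):
    b.dx(base, "zoster")
    b.med(base + 20, DrugClass.antiviral_vzv, "acyclovir")


def _nm9_catheter_below(b, base):
    _urine_culture(b, base, Specimen.urine_catheter, 49999)
    _pyuria(b, base, wbc_ul=50)


def _nm9_clean_catch_below(b, base):
    _urine_culture(b, base, Specimen.urine_clean_catch, 99999)
    _pyuria(b, base, wbc_ul=50)


def _nm9_pyuria_below_ul(b, base):
    _urine_culture(b, base, Specimen.urine_catheter, 80000)
    _pyuria(b, base, wbc_ul=9)


def _nm9_pyuria_below_hpf(b, base):
    _urine_culture(b, base, Specimen.urine_catheter, 80000)
    _pyuria(b, base, wbc_hpf=4)


def _nm9_ua_outside_window(b, base):
    _urine_culture(b, base, Specimen.urine_catheter, 80000)
    _pyuria(b, base + 2, wbc_ul=50)


def _nm9_culture_only(b, base):
    _urine_culture(b, base, Specimen.urine_catheter, 80000)


def _nm9_ua_only(b, base):
    _pyuria(b, base, wbc_ul=50)


def _nm10_no_antifungal(b, base):
    b.dx(base, "skin_fungal_infection")


def _nm10_negative_smear(b, base):
    b.lab(base, LabKind.fungal_smear, specimen=Specimen.skin, positive=False)


def _nm10_antifungal_outside_window(b, base):
    b.dx(base, "skin_fungal_infection")
    b.med(base + 20, DrugClass.antifungal, "clotrimazole")


def _nm11_mismatched_class(b, base):
    b.dx(base, "viral_infection_respiratory")
    b.lab(base, LabKind.pcr, specimen=Specimen.other, organism="gi_virus", positive=True)


def _nm11_dx_only(b, base):
    b.dx(base, "viral_infection_gastrointestinal")


def _nm11_lab_only(b, base):
    b.lab(base, LabKind.pcr, specimen=Specimen.upper_respiratory,
          organism="respiratory_virus", positive=True)


def _nm11_lab_outside_window(b, base):
    b.dx(base, "viral_infection_respiratory")
    b.lab(base + 20, LabKind.pcr, specimen=Specimen.upper_respiratory,
          organism="respiratory_virus", positive=True)


def _nm12_no_gastro_dx(b, base):
    b.dx(base, "celiac_disease", specialty="primary_care")
    b.lab(base, LabKind.serology_ttg_iga, specimen=Specimen.blood, positive=True,
          quantity=15.0, quantity_units=QuantityUnits.fold_uln)
    b.lab(base, LabKind.serology_ema, specimen=Specimen.blood, positive=True)


def _nm12_ttg_at_threshold(b, base):
    # TTG exactly 10x ULN fails the strict "more than 10x" criterion
    b.dx(base, "celiac_disease", specialty="gastroenterology")
    b.lab(base, LabKind.serology_ttg_iga, specimen=Specimen.blood, positive=True,
          quantity=10.0, quantity_units=QuantityUnits.fold_uln)
    b.lab(base, LabKind.serology_ema, specimen=Specimen.blood, positive=True)


def _nm12_no_confirmation(b, base):
    b.dx(base, "celiac_disease", specialty="gastroenterology")
    b.lab(base, LabKind.serology_ttg_iga, specimen=Specimen.blood, positive=True,
          quantity=15.0, quantity_units=QuantityUnits.fold_uln)


def _nm12_histology_without_serology(b, base):
    b.dx(base, "celiac_disease", specialty="gastroenterology")
    b.lab(base, LabKind.histology, specimen=Specimen.duodenal_biopsy, positive=True,
          histology_findings=(HistologyFinding.villous_atrophy,))


def _nm13_primary_care(b, base):
    b.dx(base, "kawasaki_disease", specialty="primary_care")


def _nm13_uncertain(b, base):
    b.dx(base, "kawasaki_disease", specialty="cardiology", uncertain=True)


def _nm14_dx_without_imaging(b, base):
    b.dx(base, "appendicitis")


def _nm14_imaging_without_dx(b, base):
    b.img(base, Modality.abdominal_ct, [ImagingObservation.appendicitis_suggestive])


def _nm14_normal_appendix(b, base):
    b.dx(base, "normal_appendix", specialty="surgery", section=SourceSection.operative_note)


def _nm14_incidental(b, base):
    b.dx(base, "incidental_appendectomy", specialty="surgery",
         section=SourceSection.operative_note)


def _nm14_uncertain_opnote(b, base):
    b.dx(base, "appendicitis", specialty="surgery", section=SourceSection.operative_note,
         uncertain=True)


def _make_recurrent_nm(concepts: Sequence[str], specialist: str):
    concept = concepts[0]

    def single(b, base):
        b.dx(base, concept, specialty=specialist)

    def short_span(b, base):
        b.dx(base, concept, specialty=specialist)
        b.dx(base + 150, concept, specialty="primary_care")

    def no_specialist(b, base):
        b.dx(base, concept, specialty="primary_care")
        b.dx(base + 200, concept, specialty="primary_care")

    return [
        ("single_documentation", single),
        ("span_150_days", short_span),
        ("no_specialist_diagnosis", no_specialist),
    ]


NEAR_MISS_CATALOG: dict[int, list[tuple[str, Callable[[_Sketch, int], None]]]] = {
    1: [
        ("contaminant_organism", _nm1_contaminant),
        ("nonsterile_specimen", _nm1_nonsterile),
        ("culture_without_diagnosis", _nm1_no_dx),
        ("diagnosis_outside_window", _nm1_dx_outside_window),
    ],
    2: [
        ("two_episodes", _nm2_two_episodes),
        ("negative_tests", _nm2_negative_tests),
        ("tests_without_diagnosis", _nm2_tests_without_dx),
    ],
    3: [
        ("diagnosis_only", _nm3_dx_only),
        ("fever_100_4", _nm3_fever_below),
        ("no_cough", _nm3_no_cough),
        ("no_rales", _nm3_no_rales),
        ("exam_without_diagnosis", _nm3_exam_without_dx),
        ("exam_outside_window", _nm3_exam_outside_window),
    ],
    4: [("wrong_cpt_code", _nm4_wrong_cpt)],
    5: [
        ("three_episodes", _nm5_three_episodes),
        ("no_antibiotics", _nm5_no_antibiotics),
        ("no_imaging_or_surgery", _nm5_no_imaging_or_surgery),
        ("antibiotic_outside_window", _nm5_abx_outside_window),
    ],
    6: [
        ("negative_pcr", _nm6_negative_pcr),
        ("culture_not_pcr", _nm6_culture_not_pcr),
        ("wrong_specimen", _nm6_wrong_specimen),
    ],
    7: [
        ("day_41_after_vaccination", _nm7_day_41),
        ("unvaccinated", _nm7_unvaccinated),
    ],
    8: [
        ("diagnosis_only", _nm8_dx_only),
        ("negative_pcr", _nm8_negative_pcr),
        ("antiviral_outside_window", _nm8_antiviral_outside_window),
    ],
    9: [
        ("catheter_49999_cfu", _nm9_catheter_below),
        ("clean_catch_99999_cfu", _nm9_clean_catch_below),
        ("pyuria_9_wbc_per_ul", _nm9_pyuria_below_ul),
        ("pyuria_4_wbc_per_hpf", _nm9_pyuria_below_hpf),
        ("urinalysis_outside_window", _nm9_ua_outside_window),
        ("culture_without_urinalysis", _nm9_culture_only),
        ("urinalysis_without_culture", _nm9_ua_only),
    ],
    10: [
        ("diagnosis_without_antifungal", _nm10_no_antifungal),
        ("negative_fungal_smear", _nm10_negative_smear),
        ("antifungal_outside_window", _nm10_antifungal_outside_window),
    ],
    11: [
        ("mismatched_virus_class", _nm11_mismatched_class),
        ("diagnosis_without_lab", _nm11_dx_only),
        ("lab_without_diagnosis", _nm11_lab_only),
        ("lab_outside_window", _nm11_lab_outside_window),
    ],
    12: [
        ("no_gastroenterologist_diagnosis", _nm12_no_gastro_dx),
        ("ttg_exactly_10x_uln", _nm12_ttg_at_threshold),
        ("serology_without_confirmation", _nm12_no_confirmation),
        ("histology_without_serology", _nm12_histology_without_serology),
    ],
    13: [
        ("primary_care_only", _nm13_primary_care),
        ("uncertain_specialist_diagnosis", _nm13_uncertain),
    ],
    14: [
        ("diagnosis_without_imaging", _nm14_dx_without_imaging),
        ("imaging_without_diagnosis", _nm14_imaging_without_dx),
        ("normal_appendix_operative_note", _nm14_normal_appendix),
        ("incidental_appendectomy", _nm14_incidental),
        ("uncertain_operative_note", _nm14_uncertain_opnote),
    ],
    15: _make_recurrent_nm(["autoimmune_thyroiditis"], "endocrinology"),
    16: _make_recurrent_nm(["diabetes_type1"], "endocrinology"),
    17: _make_recurrent_nm(["diabetes_type2"], "endocrinology"),
    18: _make_recurrent_nm(["ibd"], "gastroenterology"),
    19: _make_recurrent_nm(["jra_jia_ra"], "rheumatology"),
}

# near-miss variants for the breakthrough-varicella rule that place a
# varicella vaccination in the record
_VACCINATING_NM7 = {"day_41_after_vaccination"}

_NOISE_CONCEPTS = ["eczema", "atopic_dermatitis", "allergic_rhinitis",
                   "well_child_visit", "ankle_sprain"]


def _add_noise(b: _Sketch, n_events: int) -> None:
    for _ in range(n_events):
        day = int(b.rng.integers(0, MAX_NOISE_DAY))
        kind = int(b.rng.integers(4))
        if kind == 0:
            b.dx(day, _choice(b.rng, _NOISE_CONCEPTS))
        elif kind == 1:
            b.med(day, DrugClass.other, "ibuprofen")
        elif kind == 2:
            # afebrile exam; rales never set so no infection rule can use it
            b.exam(day, temperature_f=97.0 + float(b.rng.integers(0, 25)) / 10,
                   cough=bool(b.rng.integers(2)), rales=False)
        else:
            b.proc(day, "99213", "office visit")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> tuple[list[PatientRecord], list[GoldLabel]]:
    """Generate a cohort and its design labels; identical config => identical output."""
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    labels: list[GoldLabel] = []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        birth = dt.date(
            1997 + int(rng.integers(0, 10)),
            int(rng.integers(1, 13)),
            int(rng.integers(1, 29)),
        )
        designs: dict[int, str] = {}
        variants: dict[int, tuple[str, Callable]] = {}
        for aim_id in range(1, N_DEFINITIONS + 1):
            if rng.random() < config.prevalence_for(aim_id):
                designs[aim_id] = "positive"
            elif rng.random() < config.near_miss_rate:
                designs[aim_id] = "near_miss"
                catalog = NEAR_MISS_CATALOG[aim_id]
                variants[aim_id] = catalog[int(rng.integers(len(catalog)))]
            else:
                designs[aim_id] = "unrelated"

        has_vacc = designs[7] == "positive" or (
            designs[7] == "near_miss" and variants[7][0] in _VACCINATING_NM7
        )
        sketch = _Sketch(pid, birth, rng, has_vaccination=has_vacc,
                         aim8_design=designs[8])

        for aim_id in range(1, N_DEFINITIONS + 1):
            design = designs[aim_id]
            base = _slot(aim_id)
            if design == "positive":
                _POSITIVE_BUILDERS[aim_id](sketch, base)
                labels.append(GoldLabel(patient_id=pid, aim_id=aim_id, label="positive"))
            elif design == "near_miss":
                name, builder = variants[aim_id]
                builder(sketch, base)
                labels.append(
                    GoldLabel(patient_id=pid, aim_id=aim_id, label="near_miss", variant=name)
                )
            else:
                labels.append(GoldLabel(patient_id=pid, aim_id=aim_id, label="unrelated"))

        _add_noise(sketch, int(rng.poisson(config.noise_events_per_patient)))
        patients.append(sketch.build())

    return patients, labels


# ---------------------------------------------------------------------------
# scoring against gold labels
# ---------------------------------------------------------------------------

@dataclass
class ValidationScore:
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int
    false_negatives: list[GoldLabel]
    false_positives: list[GoldLabel]


def validate_against_labels(
    results: pd.DataFrame, labels: Sequence[GoldLabel]
) -> ValidationScore:
    """Score engine verdicts against the generator's design labels.

    Designed positives must be met; near-misses and unrelated designs must
    not be.  Perfect agreement (sensitivity = specificity = 1) is the
    engine's correctness contract against the generator.
    """
    met = {
        (row.patient_id, int(row.aim_id)): bool(row.met)
        for row in results.itertuples(index=False)
    }
    tp = fn = tn = fp = 0
    false_negatives: list[GoldLabel] = []
    false_positives: list[GoldLabel] = []
    for lab in labels:
        verdict = met[(lab.patient_id, lab.aim_id)]
        if lab.label == "positive":
            if verdict:
                tp += 1
            else:
                fn += 1
                false_negatives.append(lab)
        else:
            if verdict:
                fp += 1
                false_positives.append(lab)
            else:
                tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return ValidationScore(sens, spec, tp, fn, tn, fp, false_negatives, false_positives)


# ---------------------------------------------------------------------------
# boundary fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryFixture:
    """A pass-at-boundary / fail-below-boundary patient pair for one threshold."""

    name: str
    aim_id: int
    criterion: str
    description: str
    pass_patient: PatientRecord
    fail_patient: PatientRecord


def _fixture_pair(name: str, aim_id: int, criterion: str, description: str,
                  build: Callable[[_Sketch, bool], None]) -> BoundaryFixture:
    patients = []
    for passes in (True, False):
        sketch = _Sketch(f"{name}-{'pass' if passes else 'fail'}",
                         dt.date(2000, 1, 1), np.random.default_rng(0))
        build(sketch, passes)
        patients.append(sketch.build())
    return BoundaryFixture(name, aim_id, criterion, description, *patients)


def enumerate_boundary_fixtures() -> list[BoundaryFixture]:
    """One patient pair per printed threshold: at-boundary passes, below fails."""
    fixtures = []

    def fever(b, ok):
        b.dx(100, "pneumonia")
        b.exam(100, temperature_f=100.5 if ok else 100.4, cough=True, rales=True)

    fixtures.append(_fixture_pair(
        "fever_100_5_f", 3, "B", "exam fever threshold 100.5 F (inclusive)", fever))

    def varicella(b, ok):
        b.vacc(100)
        b.dx(100 + (42 if ok else 41), "varicella")

    fixtures.append(_fixture_pair(
        "varicella_42_days", 7, "A",
        "42 or more days after varicella vaccination (inclusive)", varicella))

    def strep(b, ok):
        for k in range(3 if ok else 2):
            _strep_episode(b, 100 + k * 45)

    fixtures.append(_fixture_pair(
        "strep_3_episodes_365_days", 2, "C",
        "3 or more confirmed episodes within a rolling 365 days", strep))

    def sinusitis(b, ok):
        _sinusitis_episodes(b, 100, 4 if ok else 3)
        b.img(110, Modality.sinus_ct, [ImagingObservation.sinus_opacification])

    fixtures.append(_fixture_pair(
        "sinusitis_4_episodes_365_days", 5, "A",
        "4 or more antibiotic-treated episodes within a rolling 365 days", sinusitis))

    def catheter(b, ok):
        _urine_culture(b, 100, Specimen.urine_catheter, 50000 if ok else 49999)
        _pyuria(b, 100, wbc_ul=50)

    fixtures.append(_fixture_pair(
        "catheter_50000_cfu", 9, "A",
        "catheterized specimen threshold 50,000 CFU/mL (inclusive)", catheter))

    def clean_catch(b, ok):
        _urine_culture(b, 100, Specimen.urine_clean_catch, 100000 if ok else 99999)
        _pyuria(b, 100, wbc_ul=50)

    fixtures.append(_fixture_pair(
        "clean_catch_100000_cfu", 9, "A",
        "clean-catch specimen threshold 100,000 CFU/mL (inclusive)", clean_catch))

    def pyuria_ul(b, ok):
        _urine_culture(b, 100, Specimen.urine_catheter, 80000)
        _pyuria(b, 100, wbc_ul=10 if ok else 9)

    fixtures.append(_fixture_pair(
        "pyuria_10_wbc_per_ul", 9, "B",
        "unspun urinalysis threshold 10 WBC/uL (inclusive)", pyuria_ul))

    def pyuria_hpf(b, ok):
        _urine_culture(b, 100, Specimen.urine_catheter, 80000)
        _pyuria(b, 100, wbc_hpf=5 if ok else 4)

    fixtures.append(_fixture_pair(
        "pyuria_5_wbc_per_hpf", 9, "B",
        "centrifuged urinalysis threshold 5 WBC/hpf (inclusive)", pyuria_hpf))

    def ttg(b, ok):
        b.dx(100, "celiac_disease", specialty="gastroenterology")
        b.lab(100, LabKind.serology_ttg_iga, specimen=Specimen.blood, positive=True,
              quantity=10.1 if ok else 10.0, quantity_units=QuantityUnits.fold_uln)
        b.lab(100, LabKind.serology_ema, specimen=Specimen.blood, positive=True)

    fixtures.append(_fixture_pair(
        "ttg_over_10x_uln", 12, "B",
        "TTG IgA strictly greater than 10x the upper limit of normal", ttg))

    def span(b, ok):
        b.dx(100, "diabetes_type1", specialty="endocrinology")
        b.dx(100 + (183 if ok else 182), "diabetes_type1", specialty="primary_care")

    fixtures.append(_fixture_pair(
        "documentation_span_183_days", 16, "A",
        "first-to-last documentation span of at least 183 days (inclusive)", span))

    return fixtures
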