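"""Domain model for structured EHR events and patient records.

Every evaluable fact about a patient is one of seven dated event types:
diagnoses (with provider specialty and note-section provenance), laboratory
results (with specimen source and quantitative values), CPT procedure events,
medication orders, imaging findings, vaccination events, and exam findings.
Free-text note content is modeled as pre-extracted structured fields — concept
terms, finding terms and exam flags — which is what a rule engine downstream of
an NLP front-end would consume.

All events are immutable; a :class:`PatientRecord` sorts each collection by
date on construction and rejects events that predate the birth date.
"""
from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import vocab


class SourceSection(str, Enum):
    """Where in the clinical note a diagnosis term was documented."""

    diagnosis = "diagnosis"
    history_of_present_illness = "history_of_present_illness"
    physical_examination = "physical_examination"
    operative_note = "operative_note"


class LabKind(str, Enum):
    culture = "culture"
    pcr = "pcr"
    radt = "radt"  # rapid antigen detection test (group A strep)
    serology_ttg_iga = "serology_ttg_iga"
    serology_ema = "serology_ema"
    serology_dga = "serology_dga"
    fungal_smear = "fungal_smear"
    urinalysis = "urinalysis"
    histology = "histology"


class Specimen(str, Enum):
    blood = "blood"
    csf = "csf"
    pleural_fluid = "pleural_fluid"
    pericardial_fluid = "pericardial_fluid"
    peritoneal_fluid = "peritoneal_fluid"
    synovial_fluid = "synovial_fluid"
    throat = "throat"
    upper_respiratory = "upper_respiratory"
    urine_suprapubic = "urine_suprapubic"
    urine_catheter = "urine_catheter"
    urine_clean_catch = "urine_clean_catch"
    skin = "skin"
    duodenal_biopsy = "duodenal_biopsy"
    other = "other"


URINE_SPECIMENS = frozenset(
    {Specimen.urine_suprapubic, Specimen.urine_catheter, Specimen.urine_clean_catch}
)


class QuantityUnits(str, Enum):
    cfu_per_ml = "cfu_per_ml"
    wbc_per_ul_unspun = "wbc_per_ul_unspun"
    wbc_per_hpf_centrifuged = "wbc_per_hpf_centrifuged"
    fold_uln = "fold_uln"  # multiples of the upper limit of normal


class HistologyFinding(str, Enum):
    increased_iel = "increased_iel"
    villous_atrophy = "villous_atrophy"
    crypt_hyperplasia = "crypt_hyperplasia"


class DrugClass(str, Enum):
    antibiotic = "antibiotic"
    antifungal = "antifungal"
    antiviral_vzv = "antiviral_vzv"
    other = "other"


class Modality(str, Enum):
    chest_xray = "chest_xray"
    sinus_ct = "sinus_ct"
    abdominal_ct = "abdominal_ct"
    ultrasound = "ultrasound"


class ImagingObservation(str, Enum):
    consolidation = "consolidation"
    lobar_pneumonia = "lobar_pneumonia"
    infiltrates = "infiltrates"
    sinus_opacification = "sinus_opacification"
    air_fluid_level = "air_fluid_level"
    appendicitis_suggestive = "appendicitis_suggestive"


# which observation terms are legal for each imaging modality
MODALITY_FINDINGS: dict[Modality, frozenset[ImagingObservation]] = {
    Modality.chest_xray: frozenset(
        {
            ImagingObservation.consolidation,
            ImagingObservation.lobar_pneumonia,
            ImagingObservation.infiltrates,
        }
    ),
    Modality.sinus_ct: frozenset(
        {ImagingObservation.sinus_opacification, ImagingObservation.air_fluid_level}
    ),
    Modality.abdominal_ct: frozenset({ImagingObservation.appendicitis_suggestive}),
    Modality.ultrasound: frozenset({ImagingObservation.appendicitis_suggestive}),
}


class Vaccine(str, Enum):
    varicella = "varicella"
    other = "other"


class _FrozenEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: dt.date


class DiagnosisEvent(_FrozenEvent):
    """A physician diagnosis term extracted from a clinical note."""

    concept: str
    provider_specialty: str = "other"
    source_section: SourceSection = SourceSection.diagnosis
    uncertain: bool = False  # "possible" / "rule out" qualifier

    @field_validator("concept")
    @classmethod
    def _concept_known(cls, v: str) -> str:
        if v not in vocab.CONCEPTS:
            raise ValueError(f"unknown diagnosis concept {v!r}")
        return v

    @field_validator("provider_specialty")
    @classmethod
    def _specialty_known(cls, v: str) -> str:
        if v not in vocab.SPECIALTIES:
            raise ValueError(f"unknown provider specialty {v!r}")
        return v


class LabResult(_FrozenEvent):
    """A laboratory result, qualitative and optionally quantitative."""

    kind: LabKind
    specimen: Specimen = Specimen.other
    organism: Optional[str] = None
    positive: bool = False
    quantity: Optional[float] = None
    quantity_units: Optional[QuantityUnits] = None
    histology_findings: tuple[HistologyFinding, ...] = ()

    @field_validator("organism")
    @classmethod
    def _organism_known(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in vocab.ORGANISMS:
            raise ValueError(f"unknown organism {v!r}")
        return v

    @field_validator("quantity")
    @classmethod
    def _quantity_nonneg(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("quantity must be non-negative")
        return v

    @model_validator(mode="after")
    def _consistency(self) -> "LabResult":
        if (self.quantity is None) != (self.quantity_units is None):
            raise ValueError("quantity and quantity_units must be given together")
        if self.kind is LabKind.urinalysis and self.specimen not in URINE_SPECIMENS:
            raise ValueError("urinalysis requires a urine specimen")
        return self


class ProcedureEvent(_FrozenEvent):
    cpt_code: str
    description: Optional[str] = None

    @field_validator("cpt_code")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("cpt_code must be non-empty")
        return v


class MedicationOrder(_FrozenEvent):
    drug_class: DrugClass
    name: Optional[str] = None


class ImagingFinding(_FrozenEvent):
    modality: Modality
    findings: tuple[ImagingObservation, ...] = ()

    @model_validator(mode="after")
    def _findings_legal(self) -> "ImagingFinding":
        legal = MODALITY_FINDINGS[self.modality]
        for f in self.findings:
            if f not in legal:
                raise ValueError(f"finding {f.value!r} is not legal for {self.modality.value}")
        return self


class VaccinationEvent(_FrozenEvent):
    vaccine: Vaccine


class ExamFinding(_FrozenEvent):
    """Structured physical-exam flags relevant to the infection rules."""

    temperature_f: Optional[float] = None
    cough: bool = False
    rale_crackle_crepitation: bool = False

    @field_validator("temperature_f")
    @classmethod
    def _plausible(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (90.0 <= v <= 110.0):
            raise ValueError("temperature_f outside plausible range [90, 110]")
        return v


ClinicalEvent = (
    DiagnosisEvent
    | LabResult
    | ProcedureEvent
    | MedicationOrder
    | ImagingFinding
    | VaccinationEvent
    | ExamFinding
)


class PatientRecord(BaseModel):
    """One patient's identifier, birth date, and all event collections.

    Collections are stored date-sorted (stable, so same-day events keep their
    input order); every event must be on or after the birth date.
    """

    patient_id: str
    birth_date: dt.date
    diagnoses: tuple[DiagnosisEvent, ...] = ()
    labs: tuple[LabResult, ...] = ()
    procedures: tuple[ProcedureEvent, ...] = ()
    medications: tuple[MedicationOrder, ...] = ()
    imaging: tuple[ImagingFinding, ...] = ()
    vaccinations: tuple[VaccinationEvent, ...] = ()
    exams: tuple[ExamFinding, ...] = ()

    @field_validator("patient_id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("patient_id must be non-empty")
        return v

    @model_validator(mode="after")
    def _sort_and_check(self) -> "PatientRecord":
        for field in EVENT_FIELDS:
            events = getattr(self, field)
            for ev in events:
                if ev.date < self.birth_date:
                    raise ValueError(
                        f"{field} event on {ev.date.isoformat()} predates "
                        f"birth date {self.birth_date.isoformat()}"
                    )
            object.__setattr__(
                self, field, tuple(sorted(events, key=lambda e: e.date))
            )
        return self

    @property
    def n_events(self) -> int:
        return sum(len(getattr(self, f)) for f in EVENT_FIELDS)


EVENT_FIELDS = (
    "diagnoses",
    "labs",
    "procedures",
    "medications",
    "imaging",
    "vaccinations",
    "exams",
)

EVENT_TYPES: dict[str, type[BaseModel]] = {
    "diagnoses": DiagnosisEvent,
    "labs": LabResult,
    "procedures": ProcedureEvent,
    "medications": MedicationOrder,
    "imaging": ImagingFinding,
    "vaccinations": VaccinationEvent,
    "exams": ExamFinding,
}
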