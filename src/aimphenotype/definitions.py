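"""The 19 executable phenotype definitions.

Each definition is a criterion tree (the connective grammar it was ratified
with) plus named parameters, loaded from the packaged rules file; the per-
criterion predicates live here.  Evaluating a definition against a patient
yields an :class:`AIMResult` carrying the verdict, the status of every labeled
criterion, and an evidence trail: every criterion reported true cites the
events that satisfy it.

Two global conventions apply to all rules:

* diagnoses flagged *uncertain* ("possible", "rule out") never contribute;
* printed thresholds are compared inclusively ("at least", "3 or more",
  ">= 100.5"), with one exception: the celiac TTG-IgA criterion reads "more
  than 10x the upper limit of normal" and is strict.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import vocab
from .errors import ContractError
from .events import (
    DiagnosisEvent,
    ImagingObservation,
    LabKind,
    LabResult,
    Modality,
    PatientRecord,
    QuantityUnits,
    SourceSection,
    Specimen,
)
from .primitives import (
    CriterionTree,
    eval_tree,
    group_episodes,
    link_within,
    max_count_in_window,
    recurrent_documentation,
)

N_DEFINITIONS = 19

PNEUMONIA_XRAY_FINDINGS = frozenset(
    {
        ImagingObservation.consolidation,
        ImagingObservation.lobar_pneumonia,
        ImagingObservation.infiltrates,
    }
)
SINUS_CT_FINDINGS = frozenset(
    {ImagingObservation.sinus_opacification, ImagingObservation.air_fluid_level}
)


@dataclass(frozen=True)
class AIMDefinition:
    """One phenotype definition: identity, criterion tree and parameters."""

    aim_id: int
    name: str
    category: str  # "infectious" | "inflammatory"
    tree: CriterionTree
    parameters: Mapping[str, Any]

    def display(self) -> str:
        return f"{self.aim_id}. {self.name}: {self.tree.display()}"


@dataclass
class AIMResult:
    """Per-patient, per-definition verdict with a per-criterion evidence trail."""

    patient_id: str
    aim_id: int
    met: bool
    criterion_status: dict[str, bool]
    evidence: dict[str, list]
    earliest_met_date: Optional[dt.date] = None

    def evidence_summary(self) -> str:
        parts = []
        for label in sorted(self.criterion_status):
            if self.criterion_status[label]:
                parts.append(f"{label}:{len(self.evidence.get(label, []))}")
        return ";".join(parts)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def load_registry(overrides: str | Path | Mapping | None = None) -> dict[int, AIMDefinition]:
    """Load the 19 definitions, optionally overlaying parameter overrides.

    ``overrides`` may be a YAML file path or a mapping ``{aim_id: {param:
    value}}``; only parameters already defined for that rule may be
    overridden (unknown names raise, so typos cannot silently change rules).
    """
    raw = yaml.safe_load((files("aimphenotype") / "data" / "aim_rules.yaml").read_text())
    over: Mapping = {}
    if overrides is not None:
        if isinstance(overrides, (str, Path)):
            over = yaml.safe_load(Path(overrides).read_text()) or {}
        else:
            over = overrides
        over = {int(k): v for k, v in over.items()}

    registry: dict[int, AIMDefinition] = {}
    for entry in raw:
        aim_id = int(entry["aim_id"])
        params = dict(entry.get("parameters") or {})
        for key, value in (over.get(aim_id) or {}).items():
            if key not in params:
                raise ContractError(
                    f"unknown parameter {key!r} for definition {aim_id}"
                )
            params[key] = value
        registry[aim_id] = AIMDefinition(
            aim_id=aim_id,
            name=entry["name"],
            category=entry["category"],
            tree=CriterionTree.from_spec(entry["tree"]),
            parameters=params,
        )
    _check_registry(registry)
    return registry


def _check_registry(registry: Mapping[int, AIMDefinition]) -> None:
    if sorted(registry) != list(range(1, N_DEFINITIONS + 1)):
        raise ContractError("registry must contain definitions 1..19 exactly")
    n_inf = sum(1 for d in registry.values() if d.category == "infectious")
    n_infl = sum(1 for d in registry.values() if d.category == "inflammatory")
    if (n_inf, n_infl) != (11, 8):
        raise ContractError("expected 11 infectious and 8 inflammatory definitions")


_DEFAULT_REGISTRY: dict[int, AIMDefinition] | None = None


def default_registry() -> dict[int, AIMDefinition]:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _certain_dx(
    patient: PatientRecord,
    concepts: Iterable[str],
    *,
    sections: Iterable[SourceSection] | None = None,
    specialties: Iterable[str] | None = None,
) -> list[DiagnosisEvent]:
    concepts = set(concepts)
    sections = set(sections) if sections is not None else None
    specialties = set(specialties) if specialties is not None else None
    out = []
    for d in patient.diagnoses:
        if d.uncertain or d.concept not in concepts:
            continue
        if sections is not None and d.source_section not in sections:
            continue
        if specialties is not None and d.provider_specialty not in specialties:
            continue
        out.append(d)
    return out


def _crit(events: Sequence) -> tuple[bool, list]:
    return bool(events), list(events)


Criteria = dict[str, tuple[bool, list]]


# ---------------------------------------------------------------------------
# per-definition criterion evaluators
# ---------------------------------------------------------------------------

def _aim1(p: PatientRecord, prm: Mapping) -> Criteria:
    """Pathogenic bacteria from a sterile site + a linked clinical diagnosis."""
    cultures = [
        l
        for l in p.labs
        if l.kind is LabKind.culture
        and l.positive
        and l.specimen.value in vocab.STERILE_SPECIMENS
        and l.organism in vocab.PATHOGENIC_BACTERIA
    ]
    dxs = _certain_dx(p, prm["diagnosis_concepts"])
    pairs = link_within(cultures, dxs, prm["culture_link_days"])
    linked_dx = _stable_unique([d for _, d in pairs])
    return {"A": _crit(cultures), "B": _crit(linked_dx)}


def _stable_unique(events: list) -> list:
    seen: list = []
    for ev in events:
        if all(ev is not s and ev != s for s in seen):
            seen.append(ev)
    return seen


def _aim2(p: PatientRecord, prm: Mapping) -> Criteria:
    """Sore throat/pharyngitis/tonsillitis with positive group-A strep testing,
    three or more episodes within a rolling year."""
    dxs = _certain_dx(p, prm["diagnosis_concepts"])
    tests = [
        l
        for l in p.labs
        if l.kind in {LabKind.radt, LabKind.culture, LabKind.pcr}
        and l.specimen is Specimen.throat
        and l.positive
        and l.organism in (None, "streptococcus_pyogenes")
    ]
    pairs = link_within(dxs, tests, prm["test_link_days"])
    confirmed = _stable_unique([d for d, _ in pairs])
    episodes = group_episodes(confirmed, prm["episode_gap_days"])
    n = max_count_in_window(episodes, prm["window_days"])
    return {
        "A": _crit(dxs),
        "B": _crit(confirmed),
        "C": (n >= prm["min_episodes"], confirmed if n >= prm["min_episodes"] else []),
    }


def _aim3(p: PatientRecord, prm: Mapping) -> Criteria:
    """Pneumonia diagnosis with compatible exam findings and/or chest x-ray."""
    dxs = _certain_dx(p, {"pneumonia"})
    qual_exams = [
        e
        for e in p.exams
        if e.temperature_f is not None
        and e.temperature_f >= prm["min_temperature_f"]
        and e.cough
        and e.rale_crackle_crepitation
    ]
    linked = _stable_unique(
        [e for _, e in link_within(dxs, qual_exams, prm["exam_link_days"])]
    )
    cxr = [
        im
        for im in p.imaging
        if im.modality is Modality.chest_xray and set(im.findings) & PNEUMONIA_XRAY_FINDINGS
    ]
    return {"A": _crit(dxs), "B": _crit(linked), "C": _crit(cxr)}


def _aim4(p: PatientRecord, prm: Mapping) -> Criteria:
    codes = set(str(c) for c in prm["tympanostomy_cpt_codes"])
    procs = [pr for pr in p.procedures if pr.cpt_code in codes]
    return {"A": _crit(procs)}


def _aim5(p: PatientRecord, prm: Mapping) -> Criteria:
    """Four or more antibiotic-treated sinusitis episodes in a rolling year,
    with CT evidence and/or sinus surgery."""
    dxs = [
        d
        for d in _certain_dx(p, {"sinusitis"})
        if d.source_section is not SourceSection.operative_note
    ]
    abx = [m for m in p.medications if m.drug_class.value == "antibiotic"]
    pairs = link_within(
        dxs,
        abx,
        days_before=prm["antibiotic_days_before"],
        days_after=prm["antibiotic_days_after"],
    )
    treated = _stable_unique([d for d, _ in pairs])
    episodes = group_episodes(treated, prm["episode_gap_days"])
    n = max_count_in_window(episodes, prm["window_days"])
    ct = [
        im
        for im in p.imaging
        if im.modality is Modality.sinus_ct and set(im.findings) & SINUS_CT_FINDINGS
    ]
    surgery = _certain_dx(p, {"sinusitis"}, sections={SourceSection.operative_note})
    return {
        "A": (n >= prm["min_episodes"], treated if n >= prm["min_episodes"] else []),
        "B": _crit(ct),
        "C": _crit(surgery),
    }


def _aim6(p: PatientRecord, prm: Mapping) -> Criteria:
    labs = [
        l
        for l in p.labs
        if l.kind is LabKind.pcr
        and l.positive
        and l.organism == "bordetella_pertussis"
        and l.specimen in {Specimen.upper_respiratory, Specimen.throat}
    ]
    return {"A": _crit(labs)}


def _aim7(p: PatientRecord, prm: Mapping) -> Criteria:
    """Varicella documented at least 42 days after varicella vaccination.

    Unvaccinated patients never qualify; the waiting period applies to both
    the clinical diagnosis and the PCR confirmation.
    """
    vaccinations = [v for v in p.vaccinations if v.vaccine.value == "varicella"]
    min_days = prm["min_days_after_vaccination"]

    def breakthrough(events):
        return [
            ev
            for ev in events
            if any((ev.date - v.date).days >= min_days for v in vaccinations)
        ]

    dxs = breakthrough(_certain_dx(p, {"varicella"}))
    pcr = breakthrough(
        [l for l in p.labs if l.kind is LabKind.pcr and l.positive and l.organism == "vzv"]
    )
    return {"A": _crit(dxs), "B": _crit(pcr)}


def _aim8(p: PatientRecord, prm: Mapping) -> Criteria:
    dxs = _certain_dx(p, {"zoster"})
    pcr = [l for l in p.labs if l.kind is LabKind.pcr and l.positive and l.organism == "vzv"]
    antivirals = [m for m in p.medications if m.drug_class.value == "antiviral_vzv"]
    linked = _stable_unique(
        [m for _, m in link_within(dxs, antivirals, prm["antiviral_link_days"])]
    )
    return {"A": _crit(dxs), "B": _crit(pcr), "C": _crit(linked)}


def _aim9(p: PatientRecord, prm: Mapping) -> Criteria:
    """Specimen-specific urine-culture thresholds plus linked pyuria."""

    def culture_ok(l: LabResult) -> bool:
        if l.kind is not LabKind.culture or not l.positive:
            return False
        cfu = (
            l.quantity
            if l.quantity_units is QuantityUnits.cfu_per_ml and l.quantity is not None
            else None
        )
        if l.specimen is Specimen.urine_suprapubic:
            return cfu is None or cfu >= prm["suprapubic_min_cfu"]
        if l.specimen is Specimen.urine_catheter:
            return cfu is not None and cfu >= prm["catheter_min_cfu"]
        if l.specimen is Specimen.urine_clean_catch:
            return cfu is not None and cfu >= prm["clean_catch_min_cfu"]
        return False

    cultures = [l for l in p.labs if culture_ok(l)]

    def pyuria(l: LabResult) -> bool:
        if l.kind is not LabKind.urinalysis or l.quantity is None:
            return False
        if l.quantity_units is QuantityUnits.wbc_per_ul_unspun:
            return l.quantity >= prm["pyuria_min_wbc_per_ul"]
        if l.quantity_units is QuantityUnits.wbc_per_hpf_centrifuged:
            return l.quantity >= prm["pyuria_min_wbc_per_hpf"]
        return False

    ua = [l for l in p.labs if pyuria(l)]
    linked = _stable_unique(
        [u for _, u in link_within(cultures, ua, prm["urinalysis_link_days"])]
    )
    return {"A": _crit(cultures), "B": _crit(linked)}


def _aim10(p: PatientRecord, prm: Mapping) -> Criteria:
    dxs = _certain_dx(p, {"skin_fungal_infection"})
    antifungals = [m for m in p.medications if m.drug_class.value == "antifungal"]
    treated = _stable_unique(
        [d for d, _ in link_within(dxs, antifungals, prm["antifungal_link_days"])]
    )
    labs = [
        l
        for l in p.labs
        if l.positive
        and l.specimen is Specimen.skin
        and (
            (l.kind is LabKind.culture and l.organism == "fungus")
            or l.kind is LabKind.fungal_smear
        )
    ]
    return {"A": _crit(treated), "B": _crit(labs)}


def _aim11(p: PatientRecord, prm: Mapping) -> Criteria:
    """Respiratory or GI viral-infection diagnosis with class-matched lab
    confirmation (a respiratory diagnosis needs a respiratory virus, etc.)."""
    pairs_by_class = {
        "viral_infection_respiratory": "respiratory_virus",
        "viral_infection_gastrointestinal": "gi_virus",
    }
    all_dx: list[DiagnosisEvent] = []
    confirmed: list[DiagnosisEvent] = []
    for concept, organism in pairs_by_class.items():
        dxs = _certain_dx(p, {concept})
        labs = [
            l
            for l in p.labs
            if l.kind in {LabKind.pcr, LabKind.culture}
            and l.positive
            and l.organism == organism
        ]
        all_dx.extend(dxs)
        confirmed.extend(
            _stable_unique([d for d, _ in link_within(dxs, labs, prm["lab_link_days"])])
        )
    return {"A": _crit(all_dx), "B": _crit(confirmed)}


def _aim12(p: PatientRecord, prm: Mapping) -> Criteria:
    """Celiac disease: gastroenterologist diagnosis plus serologic and/or
    histologic confirmation."""
    gastro_dx = _certain_dx(p, {"celiac_disease"}, specialties={"gastroenterology"})
    ttg = [l for l in p.labs if l.kind is LabKind.serology_ttg_iga]
    threshold = prm["ttg_fold_uln_threshold"]
    high_ttg = [
        l
        for l in ttg
        if l.quantity_units is QuantityUnits.fold_uln
        and l.quantity is not None
        and l.quantity > threshold  # strict: "more than 10x ULN"
    ]
    ema_dga = [
        l
        for l in p.labs
        if l.kind in {LabKind.serology_ema, LabKind.serology_dga} and l.positive
    ]
    pos_ttg = [l for l in ttg if l.positive]
    histology = [
        l
        for l in p.labs
        if l.kind is LabKind.histology
        and l.specimen is Specimen.duodenal_biopsy
        and l.histology_findings
    ]
    return {
        "A": _crit(gastro_dx),
        "B": _crit(high_ttg),
        "C": _crit(ema_dga),
        "D": _crit(pos_ttg),
        "E": _crit(histology),
    }


def _aim13(p: PatientRecord, prm: Mapping) -> Criteria:
    dxs = _certain_dx(p, {"kawasaki_disease"}, specialties=prm["specialist_set"])
    return {"A": _crit(dxs)}


def _aim14(p: PatientRecord, prm: Mapping) -> Criteria:
    """Appendicitis: surgeon's operative-note diagnosis, or clinical diagnosis
    with supportive imaging.  Normal/incidental appendectomies never count."""
    op_note = _certain_dx(p, {"appendicitis"}, sections={SourceSection.operative_note})
    dxs = _certain_dx(p, {"appendicitis"})
    imaging = [
        im
        for im in p.imaging
        if im.modality in {Modality.abdominal_ct, Modality.ultrasound}
        and ImagingObservation.appendicitis_suggestive in im.findings
    ]
    return {"A": _crit(op_note), "B": _crit(dxs), "C": _crit(imaging)}


def _recurrent(p: PatientRecord, prm: Mapping) -> Criteria:
    dxs = _certain_dx(p, prm["diagnosis_concepts"])
    ok, evidence = recurrent_documentation(
        dxs,
        min_count=prm["min_count"],
        min_span_days=prm["min_span_days"],
        specialist_set=prm["specialist_set"],
        specialist_min=prm["specialist_min"],
    )
    return {"A": (ok, evidence)}


_EVALUATORS: dict[int, Callable[[PatientRecord, Mapping], Criteria]] = {
    1: _aim1,
    2: _aim2,
    3: _aim3,
    4: _aim4,
    5: _aim5,
    6: _aim6,
    7: _aim7,
    8: _aim8,
    9: _aim9,
    10: _aim10,
    11: _aim11,
    12: _aim12,
    13: _aim13,
    14: _aim14,
    15: _recurrent,
    16: _recurrent,
    17: _recurrent,
    18: _recurrent,
    19: _recurrent,
}


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_aim(patient: PatientRecord, definition: AIMDefinition) -> AIMResult:
    """Evaluate one definition against one patient."""
    evaluator = _EVALUATORS.get(definition.aim_id)
    if evaluator is None:
        raise ContractError(f"unknown definition id {definition.aim_id}")
    criteria = evaluator(patient, definition.parameters)
    status = {label: met for label, (met, _) in criteria.items()}
    evidence = {label: ev for label, (_, ev) in criteria.items()}
    met = eval_tree(definition.tree, status)
    earliest = _earliest_met_date(definition.tree, status, evidence) if met else None
    return AIMResult(
        patient_id=patient.patient_id,
        aim_id=definition.aim_id,
        met=met,
        criterion_status=status,
        evidence=evidence,
        earliest_met_date=earliest,
    )


def _earliest_met_date(tree: CriterionTree, status, evidence) -> Optional[dt.date]:
    """Earliest date by which the satisfied criteria were all first documented.

    For each true criterion, take the date of its first supporting event; the
    definition is considered met from the smallest date t at which the tree is
    satisfied using only criteria first documented on or before t.
    """
    first: dict[str, dt.date] = {}
    for label, ok in status.items():
        if ok and evidence.get(label):
            first[label] = min(ev.date for ev in evidence[label])
    candidates = sorted(set(first.values()))
    for t in candidates:
        sliced = {label: status[label] and first.get(label, dt.date.max) <= t for label in status}
        if eval_tree(tree, sliced):
            return t
    return max(first.values()) if first else None


def evaluate_all(
    patient: PatientRecord, registry: Mapping[int, AIMDefinition] | None = None
) -> list[AIMResult]:
    """Evaluate all 19 definitions; results ordered by definition id."""
    registry = registry or default_registry()
    return [evaluate_aim(patient, registry[aim_id]) for aim_id in sorted(registry)]


def evaluate_cohort(
    patients: Iterable[PatientRecord],
    registry: Mapping[int, AIMDefinition] | None = None,
) -> pd.DataFrame:
    """Long-format results table: one row per (patient, definition)."""
    registry = registry or default_registry()
    rows = []
    for p in patients:
        for res in evaluate_all(p, registry):
            rows.append(
                {
                    "patient_id": res.patient_id,
                    "aim_id": res.aim_id,
                    "name": registry[res.aim_id].name,
                    "met": res.met,
                    "earliest_met_date": (
                        res.earliest_met_date.isoformat() if res.earliest_met_date else ""
                    ),
                    "evidence": res.evidence_summary(),
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "aim_id", "name", "met", "earliest_met_date", "evidence"]
    )
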