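import datetime as dt

import numpy as np
import pytest

from aimphenotype.definitions import (
    default_registry,
    evaluate_aim,
    evaluate_all,
    evaluate_cohort,
    load_registry,
)
from aimphenotype.errors import ContractError
from aimphenotype.events import (
    DiagnosisEvent,
    ExamFinding,
    ImagingFinding,
    ImagingObservation,
    LabKind,
    LabResult,
    MedicationOrder,
    Modality,
    DrugClass,
    PatientRecord,
    ProcedureEvent,
    QuantityUnits,
    SourceSection,
    Specimen,
    VaccinationEvent,
    Vaccine,
)
from aimphenotype.primitives import eval_tree
from aimphenotype.synthetic import GeneratorConfig, generate_cohort

from .conftest import BIRTH, day, patient


def _met(p, aim_id, registry):
    return evaluate_aim(p, registry[aim_id]).met


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def test_registry_has_19_definitions_11_infectious_8_inflammatory(registry):
    assert sorted(registry) == list(range(1, 20))
    categories = [registry[i].category for i in range(1, 20)]
    assert categories.count("infectious") == 11
    assert categories.count("inflammatory") == 8
    assert all(registry[i].category == "infectious" for i in range(1, 12))
    assert all(registry[i].category == "inflammatory" for i in range(12, 20))


def test_parameter_overrides_apply_and_unknown_names_raise():
    overridden = load_registry({9: {"catheter_min_cfu": 10000}})
    assert overridden[9].parameters["catheter_min_cfu"] == 10000
    with pytest.raises(ContractError, match="not_a_parameter"):
        load_registry({9: {"not_a_parameter": 1}})


def test_unknown_definition_id_raises(registry):
    from aimphenotype.definitions import AIMDefinition
    from aimphenotype.primitives import CriterionTree

    bogus = AIMDefinition(99, "bogus", "infectious", CriterionTree.leaf("A"), {})
    with pytest.raises(ContractError):
        evaluate_aim(patient(), bogus)


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------


def test_uti_catheter_culture_with_same_day_pyuria_is_met(registry):
    p = patient(
        labs=(
            LabResult(
                date=day(100), kind=LabKind.culture, specimen=Specimen.urine_catheter,
                organism="escherichia_coli", positive=True,
                quantity=50000, quantity_units=QuantityUnits.cfu_per_ml,
            ),
            LabResult(
                date=day(100), kind=LabKind.urinalysis, specimen=Specimen.urine_clean_catch,
                positive=True, quantity=10, quantity_units=QuantityUnits.wbc_per_ul_unspun,
            ),
        )
    )
    result = evaluate_aim(p, registry[9])
    assert result.met
    assert result.criterion_status == {"A": True, "B": True}


def test_suprapubic_culture_qualifies_without_quantity(registry):
    p = patient(
        labs=(
            LabResult(
                date=day(100), kind=LabKind.culture, specimen=Specimen.urine_suprapubic,
                organism="escherichia_coli", positive=True,
            ),
            LabResult(
                date=day(101), kind=LabKind.urinalysis, specimen=Specimen.urine_clean_catch,
                positive=True, quantity=7, quantity_units=QuantityUnits.wbc_per_hpf_centrifuged,
            ),
        )
    )
    assert evaluate_aim(p, registry[9]).met


def test_contaminant_never_satisfies_invasive_bacterial_rule(registry):
    def make(organism):
        return patient(
            labs=(
                LabResult(
                    date=day(50), kind=LabKind.culture, specimen=Specimen.blood,
                    organism=organism, positive=True,
                ),
            ),
            diagnoses=(
                DiagnosisEvent(date=day(52), concept="bacteremia",
                               provider_specialty="infectious_disease"),
            ),
        )

    assert _met(make("streptococcus_pneumoniae"), 1, registry)
    assert not _met(make("staphylococcus_epidermidis"), 1, registry)


def test_uncertain_diagnoses_are_excluded_everywhere(registry):
    p = patient(
        diagnoses=(
            DiagnosisEvent(date=day(10), concept="kawasaki_disease",
                           provider_specialty="cardiology", uncertain=True),
        )
    )
    assert not _met(p, 13, registry)
    certain = patient(
        diagnoses=(
            DiagnosisEvent(date=day(10), concept="kawasaki_disease",
                           provider_specialty="cardiology"),
        )
    )
    assert _met(certain, 13, registry)


def test_breakthrough_varicella_requires_vaccination(registry):
    unvaccinated = patient(
        diagnoses=(DiagnosisEvent(date=day(500), concept="varicella"),)
    )
    assert not _met(unvaccinated, 7, registry)


@pytest.mark.parametrize("days_after,expected", [(41, False), (42, True)])
def test_breakthrough_varicella_42_day_boundary(registry, days_after, expected):
    p = patient(
        vaccinations=(VaccinationEvent(date=day(365), vaccine=Vaccine.varicella),),
        diagnoses=(DiagnosisEvent(date=day(365 + days_after), concept="varicella"),),
    )
    assert _met(p, 7, registry) is expected


def test_pneumonia_met_via_imaging_without_exam(registry):
    p = patient(
        diagnoses=(DiagnosisEvent(date=day(200), concept="pneumonia"),),
        imaging=(
            ImagingFinding(date=day(201), modality=Modality.chest_xray,
                           findings=(ImagingObservation.infiltrates,)),
        ),
    )
    result = evaluate_aim(p, registry[3])
    assert result.met
    assert result.criterion_status == {"A": True, "B": False, "C": True}


def test_tympanostomy_cpt_surrogate(registry):
    p = patient(procedures=(ProcedureEvent(date=day(300), cpt_code="69436"),))
    assert _met(p, 4, registry)
    wrong = patient(procedures=(ProcedureEvent(date=day(300), cpt_code="99213"),))
    assert not _met(wrong, 4, registry)


def test_operative_note_negative_concepts_never_meet_appendicitis(registry):
    p = patient(
        diagnoses=(
            DiagnosisEvent(date=day(400), concept="normal_appendix",
                           provider_specialty="surgery",
                           source_section=SourceSection.operative_note),
        )
    )
    assert not _met(p, 14, registry)
    op = patient(
        diagnoses=(
            DiagnosisEvent(date=day(400), concept="appendicitis",
                           provider_specialty="surgery",
                           source_section=SourceSection.operative_note),
        )
    )
    assert _met(op, 14, registry)


def test_viral_infection_requires_class_matched_lab(registry):
    def make(organism):
        return patient(
            diagnoses=(DiagnosisEvent(date=day(80), concept="viral_infection_respiratory"),),
            labs=(
                LabResult(date=day(80), kind=LabKind.pcr, specimen=Specimen.other,
                          organism=organism, positive=True),
            ),
        )

    assert _met(make("respiratory_virus"), 11, registry)
    assert not _met(make("gi_virus"), 11, registry)


def test_interleaved_diagnoses_merge_into_one_episode(registry):
    """Confirmed strep diagnoses <=30 days apart are one episode, not three."""

    def strep(offset):
        return (
            DiagnosisEvent(date=day(offset), concept="pharyngitis"),
            LabResult(date=day(offset), kind=LabKind.radt, specimen=Specimen.throat,
                      organism="streptococcus_pyogenes", positive=True),
        )

    spread = [strep(0), strep(45), strep(90)]  # three distinct episodes
    p = patient(
        diagnoses=tuple(d for d, _ in spread), labs=tuple(l for _, l in spread)
    )
    assert _met(p, 2, registry)

    dense = [strep(0), strep(20), strep(40)]  # one merged episode
    q = patient(
        diagnoses=tuple(d for d, _ in dense), labs=tuple(l for _, l in dense)
    )
    assert not _met(q, 2, registry)


# ---------------------------------------------------------------------------
# whole-patient evaluation
# ---------------------------------------------------------------------------


def test_empty_patient_meets_nothing(registry):
    results = evaluate_all(patient())
    assert len(results) == 19
    assert [r.aim_id for r in results] == list(range(1, 20))
    assert not any(r.met for r in results)


def test_results_are_consistent_with_their_trees(registry, small_cohort):
    patients, _ = small_cohort
    for p in patients[:20]:
        for res in evaluate_all(p):
            tree = registry[res.aim_id].tree
            assert res.met == eval_tree(tree, res.criterion_status)


def test_every_true_criterion_cites_evidence(registry, small_cohort):
    patients, _ = small_cohort
    for p in patients:
        for res in evaluate_all(p):
            for label, ok in res.criterion_status.items():
                if ok:
                    assert res.evidence[label], (
                        f"definition {res.aim_id} criterion {label} true without evidence"
                    )


def test_earliest_met_date_present_iff_met(registry, small_cohort):
    patients, _ = small_cohort
    for p in patients[:20]:
        for res in evaluate_all(p):
            assert (res.earliest_met_date is not None) == res.met
            if res.earliest_met_date is not None:
                assert res.earliest_met_date >= p.birth_date


def test_verdicts_invariant_to_event_input_order(registry, small_cohort):
    patients, _ = small_cohort
    rng = np.random.default_rng(0)
    for p in patients[:25]:
        shuffled = {}
        for field in ("diagnoses", "labs", "procedures", "medications",
                      "imaging", "vaccinations", "exams"):
            events = list(getattr(p, field))
            rng.shuffle(events)
            shuffled[field] = tuple(events)
        q = PatientRecord(patient_id=p.patient_id, birth_date=p.birth_date, **shuffled)
        for before, after in zip(evaluate_all(p), evaluate_all(q)):
            assert before.met == after.met
            assert before.criterion_status == after.criterion_status


def test_adding_events_preserves_met_verdicts(registry, small_cohort):
    """Noise, duplicates and a whole new designed condition never unmeet a rule.

    (The one deliberate exception — an added diagnosis merging two episodes —
    is pinned separately in test_interleaved_diagnoses_merge_into_one_episode;
    the additions here occupy disjoint date slots and cannot interleave.)
    """
    from aimphenotype.synthetic import _POSITIVE_BUILDERS, _Sketch, _slot

    patients, labels = small_cohort
    by_patient = {p.patient_id: p for p in patients}
    unrelated = {}
    for lab in labels:
        if lab.label == "unrelated":
            unrelated.setdefault(lab.patient_id, []).append(lab.aim_id)

    rng = np.random.default_rng(1)
    checked = 0
    for pid, p in list(by_patient.items())[:20]:
        if not unrelated.get(pid):
            continue
        extra_aim = unrelated[pid][0]
        sketch = _Sketch(pid, p.birth_date, rng)
        _POSITIVE_BUILDERS[extra_aim](sketch, _slot(extra_aim))
        extras = sketch.build()
        merged = PatientRecord(
            patient_id=pid,
            birth_date=p.birth_date,
            **{
                field: getattr(p, field) + getattr(p, field) + getattr(extras, field)
                for field in ("diagnoses", "labs", "procedures", "medications",
                              "imaging", "vaccinations", "exams")
            },
        )
        before = {r.aim_id: r.met for r in evaluate_all(p)}
        after = {r.aim_id: r.met for r in evaluate_all(merged)}
        for aim_id, met in before.items():
            if met:
                assert after[aim_id], f"definition {aim_id} unmet after adding events"
        assert after[extra_aim]
        checked += 1
    assert checked >= 5


def test_cohort_table_shape_and_confusion_matrix(registry, small_cohort):
    patients, labels = small_cohort
    table = evaluate_cohort(patients)
    assert len(table) == len(patients) * 19
    assert list(table.columns) == [
        "patient_id", "aim_id", "name", "met", "earliest_met_date", "evidence",
    ]
    met = {(r.patient_id, r.aim_id): r.met for r in table.itertuples(index=False)}
    for lab in labels:
        expected = lab.label == "positive"
        assert met[(lab.patient_id, lab.aim_id)] == expected, (
            f"{lab.patient_id} definition {lab.aim_id} ({lab.label}/{lab.variant})"
        )


def test_empty_cohort_yields_header_only_table():
    table = evaluate_cohort([])
    assert len(table) == 0
    assert "met" in table.columns
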