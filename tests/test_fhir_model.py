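"""Profile-constrained FHIR parsing: extraction, violations, totality."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daicheck.fhir_model import (
    DEFAULT_ALLERGEN_CODE_SYSTEM,
    DEFAULT_KD_CODE_SYSTEM,
    AllergyRecord,
    MedicationOrder,
    allergy_record_to_resource,
    medication_order_to_resource,
    parse_allergy_bundle,
    parse_allergy_intolerance,
    parse_draft_orders_bundle,
    parse_medication_request,
)


def med_request(code="KD10001", **overrides):
    resource = {
        "resourceType": "MedicationRequest",
        "status": "draft",
        "intent": "order",
        "medicationCodeableConcept": {
            "coding": [{"system": DEFAULT_KD_CODE_SYSTEM, "code": code}]
        },
        "subject": {"reference": "Patient/patient-00001"},
    }
    resource.update(overrides)
    return {k: v for k, v in resource.items() if v is not None}


def allergy(code="ALG001", **overrides):
    resource = {
        "resourceType": "AllergyIntolerance",
        "category": ["medication"],
        "code": {"coding": [{"system": DEFAULT_ALLERGEN_CODE_SYSTEM, "code": code}]},
        "patient": {"reference": "Patient/patient-00001"},
    }
    resource.update(overrides)
    return {k: v for k, v in resource.items() if v is not None}


def bundle(*resources):
    return {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r} for r in resources],
    }


class TestMedicationRequest:
    def test_extracts_order_fields(self):
        order, violations = parse_medication_request(med_request())
        assert violations == []
        assert order == MedicationOrder(
            kd_code="KD10001",
            code_system=DEFAULT_KD_CODE_SYSTEM,
            display=None,
            status="draft",
            intent="order",
            patient_ref="Patient/patient-00001",
        )

    def test_missing_status_is_an_error_at_status(self):
        order, violations = parse_medication_request(med_request(status=None))
        assert order is None
        assert any(v.path == "status" and v.severity == "error" for v in violations)

    def test_medication_reference_is_unsupported(self):
        resource = med_request()
        del resource["medicationCodeableConcept"]
        resource["medicationReference"] = {"reference": "Medication/med-1"}
        order, violations = parse_medication_request(resource)
        assert order is None
        assert any("unsupported medication representation" in v.rule for v in violations)

    def test_wrong_resource_type_rejected(self):
        order, violations = parse_medication_request({"resourceType": "Patient"})
        assert order is None
        assert violations[0].path == "resourceType"

    def test_foreign_code_system_warns_but_parses(self):
        resource = med_request()
        resource["medicationCodeableConcept"]["coding"][0]["system"] = "urn:other"
        order, violations = parse_medication_request(resource)
        assert order is not None and order.code_system == "urn:other"
        assert [v.severity for v in violations] == ["warning"]

    def test_coding_with_configured_system_preferred(self):
        resource = med_request()
        resource["medicationCodeableConcept"]["coding"].insert(
            0, {"system": "urn:other", "code": "OTHER"}
        )
        order, violations = parse_medication_request(resource)
        assert order.kd_code == "KD10001"
        assert violations == []

    def test_must_support_elements_accepted_but_unused(self):
        resource = med_request(
            identifier=[{"value": "rx-1"}],
            dosageInstruction=[{"text": "1 tab po bid"}],
        )
        order, violations = parse_medication_request(resource)
        assert violations == []
        assert order.kd_code == "KD10001"

    def test_violations_independent_of_element_order(self):
        resource = med_request(status=None, intent=None)
        reordered = dict(reversed(list(resource.items())))
        _, v1 = parse_medication_request(resource)
        _, v2 = parse_medication_request(reordered)
        assert set(v1) == set(v2)


class TestAllergyIntolerance:
    def test_extracts_record_fields(self):
        record, violations = parse_allergy_intolerance(allergy())
        assert violations == []
        assert record == AllergyRecord(
            allergen_code="ALG001",
            code_system=DEFAULT_ALLERGEN_CODE_SYSTEM,
            display=None,
            category=("medication",),
            patient_ref="Patient/patient-00001",
        )

    def test_food_category_violates_fixed_value(self):
        record, violations = parse_allergy_intolerance(allergy(category=["food"]))
        assert record is None
        assert any("fixed value medication required" in v.rule for v in violations)

    def test_missing_code_is_an_error_at_code(self):
        record, violations = parse_allergy_intolerance(allergy(code=None))
        assert record is None
        assert any(v.path == "code" and v.severity == "error" for v in violations)


class TestBundles:
    def test_two_distinct_orders(self):
        orders, violations = parse_draft_orders_bundle(
            bundle(med_request("KD10001"), med_request("KD10002"))
        )
        assert [o.kd_code for o in orders] == ["KD10001", "KD10002"]
        assert violations == []

    def test_duplicate_kd_codes_deduplicated(self):
        orders, _ = parse_draft_orders_bundle(
            bundle(med_request("KD10001"), med_request("KD10001"))
        )
        assert len(orders) == 1

    def test_empty_bundle_is_no_orders_error(self):
        orders, violations = parse_draft_orders_bundle(bundle())
        assert orders == []
        assert any(v.rule == "no orders" and v.severity == "error" for v in violations)

    def test_foreign_entries_skipped_with_warning(self):
        orders, violations = parse_draft_orders_bundle(
            bundle({"resourceType": "ServiceRequest"}, med_request("KD10001"))
        )
        assert [o.kd_code for o in orders] == ["KD10001"]
        assert any(v.severity == "warning" for v in violations)

    def test_empty_allergy_bundle_is_valid(self):
        records, violations = parse_allergy_bundle(bundle())
        assert records == []
        assert violations == []


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

codes = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Nd")), min_size=1, max_size=12
)
texts = st.text(min_size=1, max_size=30).filter(lambda s: s.strip())


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    kd=codes,
    system=texts,
    display=st.none() | texts,
    status=st.sampled_from(["draft", "active", "on-hold"]),
    intent=st.sampled_from(["order", "plan"]),
    patient=codes,
)
def test_medication_order_round_trip(kd, system, display, status, intent, patient):
    """A serialized order re-parses to an equal order."""
    order = MedicationOrder(
        kd_code=kd,
        code_system=system,
        display=display.strip() if display else None,
        status=status,
        intent=intent,
        patient_ref=f"Patient/{patient}",
    )
    reparsed, violations = parse_medication_request(medication_order_to_resource(order))
    assert reparsed == order
    assert not any(v.severity == "error" for v in violations)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(code=codes, system=texts, patient=codes)
def test_allergy_record_round_trip(code, system, patient):
    record = AllergyRecord(
        allergen_code=code,
        code_system=system,
        display=None,
        category=("medication",),
        patient_ref=f"Patient/{patient}",
    )
    reparsed, violations = parse_allergy_intolerance(allergy_record_to_resource(record))
    assert reparsed == record
    assert not any(v.severity == "error" for v in violations)


json_values = st.recursive(
    st.none() | st.booleans() | st.integers() | st.floats(allow_nan=False) | st.text(max_size=20),
    lambda children: st.lists(children, max_size=4)
    | st.dictionaries(st.text(max_size=10), children, max_size=4),
    max_leaves=25,
)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(value=json_values)
def test_parsing_is_total_over_arbitrary_json(value):
    """Any JSON input yields a typed result or violations — never a crash."""
    for fn in (
        parse_medication_request,
        parse_allergy_intolerance,
        parse_draft_orders_bundle,
        parse_allergy_bundle,
    ):
        result, violations = fn(value)
        assert isinstance(violations, list)
    # And the same holds with the value embedded where resources belong.
    wrapped = {"resourceType": "Bundle", "entry": [{"resource": value}]}
    parse_draft_orders_bundle(wrapped)
    parse_allergy_bundle(wrapped)
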