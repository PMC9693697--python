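"""Profile-constrained parsing of FHIR R4 MedicationRequest and AllergyIntolerance.

Only the two resources the DAI service consumes are handled, and only the
constraints their profiles impose: medication given as
``medicationCodeableConcept`` bound to the KD product code system, allergy
``category`` fixed to ``"medication"``, ``code`` bound to the allergen value
set. Must-support elements such as ``identifier`` and ``dosageInstruction``
are accepted when present but never consulted.

Parsing is total: any JSON value yields either a typed result or a list of
:class:`ProfileViolation` records — never an unstructured exception. A parse
succeeds iff no *error*-severity violation was produced; warning-severity
violations (e.g. an unexpected code-system URI) accompany a successful parse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

__all__ = [
    "DEFAULT_KD_CODE_SYSTEM",
    "DEFAULT_ALLERGEN_CODE_SYSTEM",
    "CodeSystems",
    "MedicationOrder",
    "AllergyRecord",
    "ProfileViolation",
    "parse_medication_request",
    "parse_allergy_intolerance",
    "parse_draft_orders_bundle",
    "parse_allergy_bundle",
    "medication_order_to_resource",
    "allergy_record_to_resource",
]

# The national code systems have no published canonical URIs; these defaults
# are documented placeholders and are configurable per deployment.
DEFAULT_KD_CODE_SYSTEM = "https://example.org/fhir/CodeSystem/kd-code"
DEFAULT_ALLERGEN_CODE_SYSTEM = "https://example.org/fhir/CodeSystem/drug-allergen"


@dataclass(frozen=True)
class CodeSystems:
    """Configured code-system URIs for medication and allergen codings."""

    kd_code: str = DEFAULT_KD_CODE_SYSTEM
    allergen: str = DEFAULT_ALLERGEN_CODE_SYSTEM


@dataclass(frozen=True)
class MedicationOrder:
    """The medication data the rule engine needs from one MedicationRequest."""

    kd_code: str
    code_system: str
    display: str | None
    status: str
    intent: str
    patient_ref: str


@dataclass(frozen=True)
class AllergyRecord:
    """The allergen data the rule engine needs from one AllergyIntolerance."""

    allergen_code: str
    code_system: str
    display: str | None
    category: tuple[str, ...]
    patient_ref: str


@dataclass(frozen=True)
class ProfileViolation:
    resource_type: str
    path: str
    rule: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:
        return f"{self.severity}: {self.resource_type}.{self.path}: {self.rule}"


def has_errors(violations: list[ProfileViolation]) -> bool:
    return any(v.severity == "error" for v in violations)


def _err(rt: str, path: str, rule: str) -> ProfileViolation:
    return ProfileViolation(rt, path, rule, "error")


def _warn(rt: str, path: str, rule: str) -> ProfileViolation:
    return ProfileViolation(rt, path, rule, "warning")


def _nonempty_str(value: Any) -> bool:
    return isinstance(value, str) and bool(value.strip())


def _pick_coding(
    codeable: Any, system: str
) -> tuple[dict | None, bool]:
    """First coding matching the configured system, else the first coding.

    Returns (coding, system_matched). ``coding`` is None when no usable coding
    (a dict with a nonempty string ``code``) exists.
    """
    if not isinstance(codeable, dict):
        return None, False
    codings = codeable.get("coding")
    if not isinstance(codings, list):
        return None, False
    usable = [c for c in codings if isinstance(c, dict) and _nonempty_str(c.get("code"))]
    if not usable:
        return None, False
    for c in usable:
        if c.get("system") == system:
            return c, True
    return usable[0], False


def _reference(value: Any) -> str | None:
    if isinstance(value, dict) and _nonempty_str(value.get("reference")):
        return value["reference"]
    return None


# ---------------------------------------------------------------------------
# MedicationRequest
# ---------------------------------------------------------------------------

def parse_medication_request(
    resource: Any, systems: CodeSystems = CodeSystems()
) -> tuple[MedicationOrder | None, list[ProfileViolation]]:
    """Extract a :class:`MedicationOrder`, enforcing the profile constraints.

    Medication must be given inline as ``medicationCodeableConcept``: clients
    do not manage Medication resources, so ``medicationReference`` is an
    unsupported representation and rejected.
    """
    rt = "MedicationRequest"
    violations: list[ProfileViolation] = []
    if not isinstance(resource, dict):
        return None, [_err(rt, "resource", "resource must be a JSON object")]
    if resource.get("resourceType") != rt:
        return None, [
            _err(rt, "resourceType", f"expected {rt}, got {resource.get('resourceType')!r}")
        ]

    if "medicationReference" in resource:
        violations.append(
            _err(rt, "medicationReference", "unsupported medication representation")
        )
    coding, matched = _pick_coding(resource.get("medicationCodeableConcept"), systems.kd_code)
    if coding is None:
        if "medicationReference" not in resource:
            violations.append(
                _err(
                    rt,
                    "medicationCodeableConcept.coding",
                    "a coding with a nonempty code is required",
                )
            )
    elif not matched:
        violations.append(
            _warn(
                rt,
                "medicationCodeableConcept.coding[0].system",
                f"code system mismatch: expected {systems.kd_code!r}",
            )
        )

    status = resource.get("status")
    if not _nonempty_str(status):
        violations.append(_err(rt, "status", "status is required"))
    intent = resource.get("intent")
    if not _nonempty_str(intent):
        violations.append(_err(rt, "intent", "intent is required"))
    patient_ref = _reference(resource.get("subject"))
    if patient_ref is None:
        violations.append(_err(rt, "subject", "subject.reference is required"))

    if has_errors(violations):
        return None, violations
    assert coding is not None
    order = MedicationOrder(
        kd_code=coding["code"].strip(),
        code_system=str(coding.get("system") or ""),
        display=coding.get("display") if _nonempty_str(coding.get("display")) else None,
        status=status.strip(),
        intent=intent.strip(),
        patient_ref=patient_ref,
    )
    return order, violations


def medication_order_to_resource(order: MedicationOrder) -> dict:
    """Minimal conformant MedicationRequest carrying exactly this order's data."""
    coding: dict[str, Any] = {"system": order.code_system, "code": order.kd_code}
    if order.display is not None:
        coding["display"] = order.display
    return {
        "resourceType": "MedicationRequest",
        "status": order.status,
        "intent": order.intent,
        "medicationCodeableConcept": {"coding": [coding]},
        "subject": {"reference": order.patient_ref},
    }


# ---------------------------------------------------------------------------
# AllergyIntolerance
# ---------------------------------------------------------------------------

def parse_allergy_intolerance(
    resource: Any, systems: CodeSystems = CodeSystems()
) -> tuple[AllergyRecord | None, list[ProfileViolation]]:
    """Extract an :class:`AllergyRecord`, enforcing the fixed "medication" category."""
    rt = "AllergyIntolerance"
    violations: list[ProfileViolation] = []
    if not isinstance(resource, dict):
        return None, [_err(rt, "resource", "resource must be a JSON object")]
    if resource.get("resourceType") != rt:
        return None, [
            _err(rt, "resourceType", f"expected {rt}, got {resource.get('resourceType')!r}")
        ]

    category = resource.get("category")
    cats: tuple[str, ...] = ()
    if isinstance(category, list):
        cats = tuple(c for c in category if isinstance(c, str))
    if "medication" not in cats:
        violations.append(_err(rt, "category", "fixed value medication required"))
    elif len(cats) > 1:
        violations.append(_warn(rt, "category", "additional category values present"))

    coding, matched = _pick_coding(resource.get("code"), systems.allergen)
    if coding is None:
        violations.append(
            _err(rt, "code", "a coding with a nonempty code is required")
        )
    elif not matched:
        violations.append(
            _warn(
                rt,
                "code.coding[0].system",
                f"code system mismatch: expected {systems.allergen!r}",
            )
        )

    patient_ref = _reference(resource.get("patient"))
    if patient_ref is None:
        violations.append(_err(rt, "patient", "patient.reference is required"))

    if has_errors(violations):
        return None, violations
    assert coding is not None
    record = AllergyRecord(
        allergen_code=coding["code"].strip(),
        code_system=str(coding.get("system") or ""),
        display=coding.get("display") if _nonempty_str(coding.get("display")) else None,
        category=cats,
        patient_ref=patient_ref,
    )
    return record, violations


def allergy_record_to_resource(record: AllergyRecord) -> dict:
    coding: dict[str, Any] = {"system": record.code_system, "code": record.allergen_code}
    if record.display is not None:
        coding["display"] = record.display
    return {
        "resourceType": "AllergyIntolerance",
        "category": list(record.category),
        "code": {"coding": [coding]},
        "patient": {"reference": record.patient_ref},
    }


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def _bundle_resources(bundle: Any, rt: str) -> tuple[list[Any], list[ProfileViolation]]:
    violations: list[ProfileViolation] = []
    if not isinstance(bundle, dict):
        return [], [_err("Bundle", "resource", "bundle must be a JSON object")]
    if bundle.get("resourceType") != "Bundle":
        return [], [
            _err("Bundle", "resourceType", f"expected Bundle, got {bundle.get('resourceType')!r}")
        ]
    entries = bundle.get("entry", [])
    if entries is None:
        entries = []
    if not isinstance(entries, list):
        return [], [_err("Bundle", "entry", "entry must be an array")]
    keep: list[Any] = []
    for i, entry in enumerate(entries):
        res = entry.get("resource") if isinstance(entry, dict) else None
        if not isinstance(res, dict):
            violations.append(
                _warn("Bundle", f"entry[{i}]", "entry without a resource object skipped")
            )
            continue
        if res.get("resourceType") != rt:
            violations.append(
                _warn(
                    "Bundle",
                    f"entry[{i}]",
                    f"ignored resource of type {res.get('resourceType')!r}",
                )
            )
            continue
        keep.append(res)
    return keep, violations


def parse_draft_orders_bundle(
    bundle: Any, systems: CodeSystems = CodeSystems()
) -> tuple[list[MedicationOrder], list[ProfileViolation]]:
    """Parse the draftOrders Bundle into de-duplicated medication orders.

    Entries of other resource types are skipped with a warning; duplicate KD
    codes keep the first occurrence; a bundle containing no MedicationRequest
    entries at all is an error ("no orders").
    """
    resources, violations = _bundle_resources(bundle, "MedicationRequest")
    if isinstance(bundle, dict) and bundle.get("resourceType") == "Bundle" and not resources:
        violations.append(_err("Bundle", "entry", "no orders"))
        return [], violations
    orders: list[MedicationOrder] = []
    seen: set[str] = set()
    for res in resources:
        order, vs = parse_medication_request(res, systems)
        violations.extend(vs)
        if order is None:
            continue
        if order.kd_code in seen:
            continue
        seen.add(order.kd_code)
        orders.append(order)
    return orders, violations


def parse_allergy_bundle(
    bundle: Any, systems: CodeSystems = CodeSystems()
) -> tuple[list[AllergyRecord], list[ProfileViolation]]:
    """Parse the prefetched AllergyIntolerance Bundle; an empty bundle is valid
    (the patient simply has no recorded medication allergies)."""
    resources, violations = _bundle_resources(bundle, "AllergyIntolerance")
    records: list[AllergyRecord] = []
    for res in resources:
        record, vs = parse_allergy_intolerance(res, systems)
        violations.extend(vs)
        if record is not None:
            records.append(record)
    return records, violations
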