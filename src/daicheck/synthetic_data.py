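"""Synthetic knowledge bases, FHIR payloads, and audit logs with known ground truth.

The real service runs over a proprietary national drug catalogue and allergen
value set that cannot be redistributed. This module generates structurally
equivalent stand-ins — a KD-code-keyed product → ingredient → class hierarchy
with a cross-reactivity relation and a three-kind allergen value set — plus
fully conformant order-sign request payloads whose expected findings are
known exactly.

Ground truth is certified at generation time by the naive screening oracle,
so downstream tests never trust the generator's intent, only its certified
output. Display names are pronounceable synthetic strings; nothing here is
clinically meaningful. All generation is seed-deterministic.
"""

from __future__ import annotations

import json
import random
import uuid
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path

from .fhir_model import DEFAULT_ALLERGEN_CODE_SYSTEM, DEFAULT_KD_CODE_SYSTEM
from .knowledge_base import (
    AllergenConcept,
    AllergenKind,
    CrossReactivePair,
    Drug,
    DrugClass,
    Ingredient,
    IngredientClass,
    KnowledgeBase,
    resolve_allergen,
    resolve_medication,
    validate_referential_integrity,
)
from .rule_engine import oracle_screen, screen_pair

__all__ = [
    "GenerationError",
    "ScenarioSpec",
    "GroundTruth",
    "toy_kb",
    "generate_knowledge_base",
    "generate_requests",
    "generate_audit_log",
    "write_scenario",
]


class GenerationError(Exception):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Sizes and rates of a synthetic study scenario.

    ``planted_interactions`` is a list of ``(step, count)`` pairs: that many
    requests will contain exactly one interaction at that cascade step. The
    optional ``warning_fraction`` makes each remaining request an interaction
    request with that probability (random step), which is how a target
    warning rate such as the production service's 3.32% is emulated.
    """

    seed: int = 0
    n_patients: int = 100
    orders_per_patient: int = 2
    allergy_prevalence: float = 0.4
    planted_interactions: tuple[tuple[int, int], ...] = ()
    warning_fraction: float | None = None
    n_ingredients: int = 12
    n_drugs: int = 15
    n_drug_classes: int = 2
    n_ingredient_classes: int = 2
    n_cross_pairs: int = 3
    n_allergens: int = 8

    def __post_init__(self):
        counts = {
            "n_patients": self.n_patients,
            "orders_per_patient": self.orders_per_patient,
            "n_ingredients": self.n_ingredients,
            "n_drugs": self.n_drugs,
            "n_drug_classes": self.n_drug_classes,
            "n_ingredient_classes": self.n_ingredient_classes,
            "n_cross_pairs": self.n_cross_pairs,
            "n_allergens": self.n_allergens,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.allergy_prevalence <= 1.0:
            raise ValueError("allergy_prevalence must be in [0, 1]")
        if self.warning_fraction is not None and not 0.0 <= self.warning_fraction <= 1.0:
            raise ValueError("warning_fraction must be in [0, 1]")
        for step, count in self.planted_interactions:
            if step not in (1, 2, 3):
                raise ValueError(f"planted step must be 1, 2, or 3, got {step}")
            if count < 0:
                raise ValueError("planted count must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Expected screening outcome of one generated request, oracle-certified."""

    patient_id: str
    expected: tuple[tuple[str, str, int], ...]  # (kd_code, allergen_code, step)


# ---------------------------------------------------------------------------
# Fixed toy knowledge base
# ---------------------------------------------------------------------------

def toy_kb() -> KnowledgeBase:
    """The fixed five-ingredient fixture exercising every cascade step.

    Against allergen ALG001 (substance ING001): KD10001 and KD30001 match at
    step 1 (shared ingredient), KD10002 at step 2 (CLS_PCN co-membership),
    KD10003 at step 3 (cross-reactive pair), and KD20001/KD20002 not at all.
    Deterministic; takes no seed.
    """
    return KnowledgeBase(
        ingredients=(
            Ingredient("ING001", "Amoxirin", ("Amoxiral",)),
            Ingredient("ING002", "Cefaloden", ()),
            Ingredient("ING003", "Cefiprax", ()),
            Ingredient("ING004", "Naprovex", ()),
            Ingredient("ING005", "Profenal", ()),
        ),
        drugs=(
            Drug("KD10001", "Amoxirin 500mg Tab", frozenset({"ING001"})),
            Drug("KD10002", "Cefaloden 250mg Cap", frozenset({"ING002"})),
            Drug("KD10003", "Cefiprax 200mg Tab", frozenset({"ING003"})),
            Drug("KD20001", "Naprovex 220mg Tab", frozenset({"ING004"})),
            Drug("KD20002", "Profenal 400mg Tab", frozenset({"ING005"})),
            Drug("KD30001", "Amoxirin Plus Combination Tab", frozenset({"ING001", "ING004"})),
        ),
        drug_classes=(
            DrugClass("CLS_PCN", "Penicilloid antibacterials", frozenset({"ING001", "ING002"})),
        ),
        ingredient_classes=(
            IngredientClass("CLS_NSAID", "NSAID analgesics", frozenset({"ING004", "ING005"})),
        ),
        cross_reactive_pairs=(CrossReactivePair("ING001", "ING003"),),
        allergen_concepts=(
            AllergenConcept(
                "ALG001", "Allergy to Amoxirin", AllergenKind.SUBSTANCE, "ING001",
                ("R-HIVES",), ("SEV-MODERATE",),
            ),
            AllergenConcept(
                "ALG002", "Allergy to Cefaloden 250mg Cap", AllergenKind.PRODUCT, "KD10002",
                ("R-RASH",), ("SEV-MILD",),
            ),
            AllergenConcept(
                "ALG003", "Allergy to NSAID analgesics", AllergenKind.CLASS, "CLS_NSAID",
                ("R-ANAPHYLAXIS",), ("SEV-SEVERE",),
            ),
            AllergenConcept(
                "ALG004", "Allergy to Cefiprax", AllergenKind.SUBSTANCE, "ING003", (), (),
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Random knowledge bases
# ---------------------------------------------------------------------------

_SYLLABLES = (
    "ba", "do", "fe", "gi", "ka", "lo", "mi", "na", "pra", "re",
    "sa", "tu", "vex", "zol", "min", "dor", "cil", "pro", "lan", "tor",
)
_FORMS = ("Tab", "Cap", "Syr", "Inj")
_REACTIONS = ("R-HIVES", "R-RASH", "R-ANAPHYLAXIS", "R-NAUSEA")
_SEVERITIES = ("SEV-MILD", "SEV-MODERATE", "SEV-SEVERE")


def _synthetic_name(rng: random.Random, used: set[str]) -> str:
    for _ in range(1000):
        name = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(3, 4))).capitalize()
        if name not in used:
            used.add(name)
            return name
    raise GenerationError("exhausted the synthetic name space")


def generate_knowledge_base(spec: ScenarioSpec) -> KnowledgeBase:
    """Seeded random knowledge base satisfying every integrity invariant."""
    rng = random.Random(spec.seed)
    used_names: set[str] = set()

    ingredients = tuple(
        Ingredient(
            f"ING{i + 1:03d}",
            _synthetic_name(rng, used_names),
            (_synthetic_name(rng, used_names),) if rng.random() < 0.3 else (),
        )
        for i in range(spec.n_ingredients)
    )
    ing_codes = [i.ingredient_code for i in ingredients]
    if spec.n_drugs > 0 and not ing_codes:
        raise GenerationError("cannot generate drugs without ingredients")

    drugs = []
    for i in range(spec.n_drugs):
        k = 2 if (len(ing_codes) >= 2 and rng.random() < 0.2) else 1
        members = frozenset(rng.sample(ing_codes, k))
        first = ingredients[ing_codes.index(sorted(members)[0])]
        strength = rng.choice((50, 100, 200, 250, 500))
        drugs.append(
            Drug(
                f"KD{10001 + i}",
                f"{first.name} {strength}mg {rng.choice(_FORMS)}",
                members,
            )
        )

    def make_classes(n: int, prefix: str, cls):
        if n > 0 and len(ing_codes) < 2:
            raise GenerationError("classes need at least two ingredients")
        out = []
        for i in range(n):
            k = rng.randint(2, min(4, len(ing_codes)))
            out.append(
                cls(
                    f"{prefix}{i + 1:02d}",
                    f"{_synthetic_name(rng, used_names)} class",
                    frozenset(rng.sample(ing_codes, k)),
                )
            )
        return tuple(out)

    drug_classes = make_classes(spec.n_drug_classes, "DCL", DrugClass)
    ingredient_classes = make_classes(spec.n_ingredient_classes, "ICL", IngredientClass)

    all_pairs = [
        (a, b)
        for idx, a in enumerate(ing_codes)
        for b in ing_codes[idx + 1 :]
    ]
    if spec.n_cross_pairs > len(all_pairs):
        raise GenerationError(
            f"requested {spec.n_cross_pairs} cross pairs but only "
            f"{len(all_pairs)} distinct ingredient pairs exist"
        )
    pairs = tuple(
        CrossReactivePair(a, b) for a, b in sorted(rng.sample(all_pairs, spec.n_cross_pairs))
    )

    allergens = []
    class_codes = [c.class_code for c in drug_classes] + [
        c.class_code for c in ingredient_classes
    ]
    for i in range(spec.n_allergens):
        roll = rng.random()
        if roll < 0.3 and drugs:
            kind, target = AllergenKind.PRODUCT, rng.choice(drugs).kd_code
            display = f"Allergy to {next(d.name for d in drugs if d.kd_code == target)}"
        elif roll < 0.5 and class_codes:
            kind, target = AllergenKind.CLASS, rng.choice(class_codes)
            display = f"Allergy to class {target}"
        else:
            if not ing_codes:
                raise GenerationError("allergens need at least one ingredient")
            kind, target = AllergenKind.SUBSTANCE, rng.choice(ing_codes)
            display = (
                f"Allergy to {next(x.name for x in ingredients if x.ingredient_code == target)}"
            )
        allergens.append(
            AllergenConcept(
                f"ALG{i + 1:03d}",
                display,
                kind,
                target,
                tuple(rng.sample(_REACTIONS, rng.randint(0, 2))),
                (rng.choice(_SEVERITIES),) if rng.random() < 0.7 else (),
            )
        )

    kb = KnowledgeBase(
        ingredients=ingredients,
        drugs=tuple(drugs),
        drug_classes=drug_classes,
        ingredient_classes=ingredient_classes,
        cross_reactive_pairs=pairs,
        allergen_concepts=tuple(allergens),
    )
    violations = validate_referential_integrity(kb)
    if violations:  # pragma: no cover - construction guarantees validity
        raise GenerationError(f"generated KB is invalid: {violations}")
    return kb


# ---------------------------------------------------------------------------
# Request generation
# ---------------------------------------------------------------------------

def _medication_request(kd_code: str, display: str, patient_id: str) -> dict:
    return {
        "resourceType": "MedicationRequest",
        "status": "draft",
        "intent": "order",
        "medicationCodeableConcept": {
            "coding": [
                {"system": DEFAULT_KD_CODE_SYSTEM, "code": kd_code, "display": display}
            ]
        },
        "subject": {"reference": f"Patient/{patient_id}"},
    }


def _allergy_intolerance(code: str, display: str, patient_id: str) -> dict:
    return {
        "resourceType": "AllergyIntolerance",
        "category": ["medication"],
        "code": {
            "coding": [
                {"system": DEFAULT_ALLERGEN_CODE_SYSTEM, "code": code, "display": display}
            ]
        },
        "patient": {"reference": f"Patient/{patient_id}"},
    }


def _bundle(resources: list[dict]) -> dict:
    return {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r} for r in resources],
    }


def _match_matrix(kb: KnowledgeBase):
    """Minimal matching step (or None) for every (drug, allergen) pair."""
    by_step: dict[int, list[tuple[str, str]]] = {1: [], 2: [], 3: []}
    safe_drugs: dict[str, list[str]] = {a.allergen_code: [] for a in kb.allergen_concepts}
    for alg in kb.allergen_concepts:
        a_res = resolve_allergen(kb, alg.allergen_code)
        for drug in kb.drugs:
            m_res = resolve_medication(kb, drug.kd_code)
            f = screen_pair(kb, m_res, a_res)
            if f is None:
                safe_drugs[alg.allergen_code].append(drug.kd_code)
            else:
                by_step[int(f.step)].append((drug.kd_code, alg.allergen_code))
    return by_step, safe_drugs


def generate_requests(
    kb: KnowledgeBase, spec: ScenarioSpec
) -> list[tuple[dict, GroundTruth]]:
    """Generate conformant order-sign payloads with oracle-certified ground truth.

    One request per patient. Interaction requests carry exactly one planted
    (medication, allergen) pair at the planned step plus non-interacting
    filler orders; the remaining requests carry no interacting pair at all.
    Every request's expected findings are re-derived with the naive oracle
    before it is returned; a mismatch aborts generation.
    """
    rng = random.Random(spec.seed + 1)
    by_step, safe_drugs = _match_matrix(kb)
    drug_codes = [d.kd_code for d in kb.drugs]
    drug_names = {d.kd_code: d.name for d in kb.drugs}
    alg_displays = {a.allergen_code: a.display for a in kb.allergen_concepts}

    planned: list[int | None] = []
    for step, count in spec.planted_interactions:
        planned.extend([step] * count)
    if len(planned) > spec.n_patients:
        raise GenerationError(
            f"{len(planned)} planted interactions but only {spec.n_patients} requests"
        )
    available_steps = [s for s in (1, 2, 3) if by_step[s]]
    while len(planned) < spec.n_patients:
        if spec.warning_fraction is not None and rng.random() < spec.warning_fraction:
            if not available_steps:
                raise GenerationError("warning_fraction > 0 but no pair matches any step")
            planned.append(rng.choice(available_steps))
        else:
            planned.append(None)

    out: list[tuple[dict, GroundTruth]] = []
    for i, step in enumerate(planned):
        patient_id = f"patient-{i + 1:05d}"
        if step is not None:
            if not by_step[step]:
                raise GenerationError(
                    f"cannot plant a step-{step} interaction: no (drug, allergen) "
                    f"pair in this knowledge base matches at that step"
                )
            kd, alg = rng.choice(by_step[step])
            fillers = [c for c in safe_drugs[alg] if c != kd]
            n_fill = min(spec.orders_per_patient - 1, len(fillers))
            meds = [kd] + rng.sample(fillers, n_fill)
            algs = [alg]
            expected = ((kd, alg, step),)
        else:
            algs = []
            if kb.allergen_concepts and rng.random() < spec.allergy_prevalence:
                candidates = [a for a, ds in safe_drugs.items() if len(ds) >= 1]
                if candidates:
                    algs = [rng.choice(candidates)]
            if algs:
                pool = safe_drugs[algs[0]]
            else:
                pool = drug_codes
            if not pool:
                raise GenerationError("no drugs available for a non-interacting request")
            meds = rng.sample(pool, min(spec.orders_per_patient, len(pool)))
            expected = ()

        certified = oracle_screen(kb, meds, algs)
        got = tuple((f.kd_code, f.allergen_code, int(f.step)) for f in certified.findings)
        if sorted(got) != sorted(expected):  # pragma: no cover - construction guarantees
            raise GenerationError(
                f"ground-truth certification failed for {patient_id}: "
                f"planned {expected}, oracle found {got}"
            )

        request = {
            "hook": "order-sign",
            "hookInstance": str(uuid.UUID(int=rng.getrandbits(128), version=4)),
            "context": {
                "userId": "Practitioner/prac-0001",
                "patientId": patient_id,
                "draftOrders": _bundle(
                    [_medication_request(m, drug_names[m], patient_id) for m in meds]
                ),
            },
            "prefetch": {
                "allergyIntolerance": _bundle(
                    [_allergy_intolerance(a, alg_displays[a], patient_id) for a in algs]
                )
            },
        }
        out.append((request, GroundTruth(patient_id, expected)))
    return out


# ---------------------------------------------------------------------------
# Synthetic audit logs
# ---------------------------------------------------------------------------

def generate_audit_log(
    path: str | Path,
    n_warning: int,
    n_empty: int,
    *,
    n_providers: int = 67,
    n_patients: int = 114_694,
    seed: int = 0,
    start: datetime | None = None,
) -> Path:
    """Write a synthetic JSON-lines audit log with the given outcome counts.

    Client and patient ids cycle so the distinct counts equal
    ``min(n_providers, total)`` and ``min(n_patients, total)``. Records are
    shuffled only at the outcome level (warning records interleaved by
    stride), which is irrelevant to summarization. Intended for summarizer
    benchmarks and operational-report arithmetic checks at realistic sizes.
    """
    rng = random.Random(seed)
    total = n_warning + n_empty
    base = start or datetime(2021, 3, 1, tzinfo=timezone.utc)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    # Spread warnings evenly through the file.
    warning_positions = set()
    if n_warning:
        stride = max(1, total // n_warning)
        pos = rng.randrange(stride) if stride > 1 else 0
        while len(warning_positions) < n_warning:
            warning_positions.add(pos % total)
            pos += stride
    with open(path, "w", encoding="utf-8") as fh:
        ts = base
        ts_str = ts.strftime("%Y-%m-%dT%H:%M:%SZ")
        for i in range(total):
            if i % 1000 == 0 and i:
                ts = base + timedelta(seconds=i // 1000)
                ts_str = ts.strftime("%Y-%m-%dT%H:%M:%SZ")
            warning = i in warning_positions
            record = {
                "timestamp": ts_str,
                "client_id": f"provider-{(i % n_providers) + 1:03d}" if n_providers else None,
                "hook_instance": f"hi-{i:08d}",
                "patient_id": f"p{(i % n_patients) + 1:06d}" if n_patients else None,
                "n_orders": 1,
                "n_allergens": 1 if warning else 0,
                "n_findings": 1 if warning else 0,
                "n_cards": 1 if warning else 0,
                "outcome": "warning" if warning else "empty",
                "unresolved_codes": [],
            }
            fh.write(json.dumps(record, separators=(",", ":")) + "\n")
    return path


# ---------------------------------------------------------------------------
# Scenario export
# ---------------------------------------------------------------------------

def write_scenario(spec: ScenarioSpec, out_dir: str | Path) -> Path:
    """Materialize a scenario on disk: KB CSVs, request JSONs, ground truth."""
    from .knowledge_base import save_kb_csvs

    out = Path(out_dir)
    kb = generate_knowledge_base(spec)
    save_kb_csvs(kb, out / "kb")
    requests = generate_requests(kb, spec)
    req_dir = out / "requests"
    req_dir.mkdir(parents=True, exist_ok=True)
    truth = []
    for i, (request, gt) in enumerate(requests):
        with open(req_dir / f"request-{i + 1:05d}.json", "w", encoding="utf-8") as fh:
            json.dump(request, fh, indent=2, ensure_ascii=False)
        truth.append(
            {
                "request": f"request-{i + 1:05d}.json",
                "patient_id": gt.patient_id,
                "expected": [list(e) for e in gt.expected],
            }
        )
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    return out
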