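"""Three-step drug-allergy interaction screening.

For each (prescribed medication, recorded allergen) pair the cascade checks,
strictly in order and stopping at the first hit:

1. same product or ingredient — the allergen is the prescribed product itself
   or shares an ingredient with it (class-valued allergens are excluded here:
   an allergen that *is* a class matches at step 2 by definition);
2. same drug or ingredient class — the allergen's class, or any class
   containing one of its ingredients, also contains a medication ingredient;
3. cross-reactive allergen — an allergen ingredient and a medication
   ingredient form a known cross-reactive pair.

Reporting only the minimal matching step keeps attribution mutually
exclusive, so per-step shares of warnings sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

from .knowledge_base import (
    AllergenKind,
    AllergenResolution,
    KnowledgeBase,
    MedicationResolution,
    classes_containing,
    resolve_allergen,
    resolve_medication,
)

__all__ = [
    "MatchStep",
    "Finding",
    "ScreenResult",
    "screen_pair",
    "screen_request",
    "oracle_screen",
]


class MatchStep(IntEnum):
    SAME_PRODUCT_OR_INGREDIENT = 1
    SAME_CLASS = 2
    CROSS_REACTIVE = 3

    @property
    def label(self) -> str:
        return {
            MatchStep.SAME_PRODUCT_OR_INGREDIENT: "same product or ingredient",
            MatchStep.SAME_CLASS: "same drug or ingredient class",
            MatchStep.CROSS_REACTIVE: "cross-reactive allergen",
        }[self]


#: matched_codes holds the entity codes that triggered the match: product or
#: ingredient codes at step 1, class codes at step 2, canonical
#: (ingredient, ingredient) tuples at step 3.
@dataclass(frozen=True)
class Finding:
    kd_code: str
    allergen_code: str
    step: MatchStep
    matched_codes: frozenset


@dataclass(frozen=True)
class ScreenResult:
    findings: tuple[Finding, ...]
    unresolved: tuple[str, ...]


def screen_pair(
    kb: KnowledgeBase, med: MedicationResolution, alg: AllergenResolution
) -> Finding | None:
    """Screen one resolved (medication, allergen) pair; first matching step wins."""
    # Step 1 — same product or ingredient.
    if alg.kind is not AllergenKind.CLASS:
        matched: set = set()
        if alg.product_code is not None and alg.product_code == med.kd_code:
            matched.add(alg.product_code)
        matched |= alg.ingredient_codes & med.ingredient_codes
        if matched:
            return Finding(
                med.kd_code,
                alg.allergen_code,
                MatchStep.SAME_PRODUCT_OR_INGREDIENT,
                frozenset(matched),
            )

    # Step 2 — same drug or ingredient class.
    med_classes = med.drug_class_codes | med.ingredient_class_codes
    alg_classes = alg.class_codes | classes_containing(kb, alg.ingredient_codes)
    matched = alg_classes & med_classes
    if matched:
        return Finding(
            med.kd_code, alg.allergen_code, MatchStep.SAME_CLASS, frozenset(matched)
        )

    # Step 3 — cross-reactive allergen (pairs are stored canonically).
    pairs = kb.pair_set
    matched = set()
    for a in alg.ingredient_codes:
        for m in med.ingredient_codes:
            key = (a, m) if a <= m else (m, a)
            if key in pairs:
                matched.add(key)
    if matched:
        return Finding(
            med.kd_code, alg.allergen_code, MatchStep.CROSS_REACTIVE, frozenset(matched)
        )
    return None


def _code(item, attr: str) -> str:
    if isinstance(item, str):
        return item
    return getattr(item, attr)


def _dedupe(codes: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for c in codes:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def screen_request(
    kb: KnowledgeBase, meds: Sequence, allergies: Sequence
) -> ScreenResult:
    """Screen every (medication, allergy) pair of one request.

    ``meds`` and ``allergies`` may be parsed orders/records or bare code
    strings. Codes absent from the knowledge base produce no finding but are
    reported in ``unresolved`` (a shared service must tolerate client-side
    vocabulary drift). Findings are ordered by medication input order, then
    allergy input order.
    """
    med_codes = _dedupe(_code(m, "kd_code") for m in meds)
    alg_codes = _dedupe(_code(a, "allergen_code") for a in allergies)

    unresolved: list[str] = []
    med_res = []
    for code in med_codes:
        r = resolve_medication(kb, code)
        if r is None:
            unresolved.append(code)
        else:
            med_res.append(r)
    alg_res = []
    for code in alg_codes:
        r = resolve_allergen(kb, code)
        if r is None:
            unresolved.append(code)
        else:
            alg_res.append(r)

    findings = []
    for m in med_res:
        for a in alg_res:
            f = screen_pair(kb, m, a)
            if f is not None:
                findings.append(f)
    return ScreenResult(tuple(findings), tuple(unresolved))


# ---------------------------------------------------------------------------
# Naive oracle (tests only)
# ---------------------------------------------------------------------------

def oracle_screen(kb: KnowledgeBase, meds: Sequence, allergies: Sequence) -> ScreenResult:
    """Exhaustive re-derivation of the cascade straight from the raw tables.

    Deliberately naive — linear scans, no resolution caching — so it stays an
    independent cross-check of :func:`screen_request` on small knowledge
    bases. Not intended for production-sized catalogues.
    """

    def drug_ingredients(kd: str) -> frozenset[str] | None:
        for d in kb.drugs:
            if d.kd_code == kd:
                return d.ingredient_codes
        return None

    def allergen_row(code: str):
        for a in kb.allergen_concepts:
            if a.allergen_code == code:
                return a
        return None

    def class_members(code: str) -> frozenset[str]:
        for c in kb.drug_classes:
            if c.class_code == code:
                return c.member_ingredient_codes
        for c in kb.ingredient_classes:
            if c.class_code == code:
                return c.member_ingredient_codes
        return frozenset()

    def containing_classes(ings: frozenset[str]) -> set[str]:
        out = set()
        for c in kb.drug_classes:
            for i in ings:
                if i in c.member_ingredient_codes:
                    out.add(c.class_code)
        for c in kb.ingredient_classes:
            for i in ings:
                if i in c.member_ingredient_codes:
                    out.add(c.class_code)
        return out

    med_codes = _dedupe(_code(m, "kd_code") for m in meds)
    alg_codes = _dedupe(_code(a, "allergen_code") for a in allergies)

    unresolved: list[str] = []
    resolved_meds: list[tuple[str, frozenset[str]]] = []
    for kd in med_codes:
        ings = drug_ingredients(kd)
        if ings is None:
            unresolved.append(kd)
        else:
            resolved_meds.append((kd, ings))

    resolved_algs = []
    for code in alg_codes:
        row = allergen_row(code)
        if row is None:
            unresolved.append(code)
            continue
        if row.kind is AllergenKind.SUBSTANCE:
            a_ings: frozenset[str] = frozenset({row.target_code})
            a_product = None
            a_classes: frozenset[str] = frozenset()
        elif row.kind is AllergenKind.PRODUCT:
            a_ings = drug_ingredients(row.target_code) or frozenset()
            a_product = row.target_code
            a_classes = frozenset()
        else:
            a_ings = class_members(row.target_code)
            a_product = None
            a_classes = frozenset({row.target_code})
        resolved_algs.append((code, row.kind, a_product, a_ings, a_classes))

    findings = []
    for kd, m_ings in resolved_meds:
        for code, kind, a_product, a_ings, a_classes in resolved_algs:
            # Step 1
            if kind is not AllergenKind.CLASS:
                matched = set()
                if a_product is not None and a_product == kd:
                    matched.add(a_product)
                for i in a_ings:
                    if i in m_ings:
                        matched.add(i)
                if matched:
                    findings.append(
                        Finding(kd, code, MatchStep.SAME_PRODUCT_OR_INGREDIENT, frozenset(matched))
                    )
                    continue
            # Step 2
            m_classes = containing_classes(m_ings)
            alg_side = set(a_classes) | containing_classes(a_ings)
            matched = alg_side & m_classes
            if matched:
                findings.append(Finding(kd, code, MatchStep.SAME_CLASS, frozenset(matched)))
                continue
            # Step 3
            matched = set()
            for p in kb.cross_reactive_pairs:
                if (p.ingredient_a in a_ings and p.ingredient_b in m_ings) or (
                    p.ingredient_b in a_ings and p.ingredient_a in m_ings
                ):
                    matched.add(tuple(sorted((p.ingredient_a, p.ingredient_b))))
            if matched:
                findings.append(Finding(kd, code, MatchStep.CROSS_REACTIVE, frozenset(matched)))
    return ScreenResult(tuple(findings), tuple(unresolved))
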