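"""Drug-allergy knowledge base: master and relation tables, integrity checks, code resolution.

The knowledge base models a national drug catalogue keyed by Korea Drug (KD)
product codes. Products are composed of ingredients; ingredients are grouped
into drug classes and ingredient classes; chemically related ingredients that
predict reactions to one another (e.g. penicillins vs. cephalosporins) are
linked by cross-reactive pairs. Patient allergens reference this structure at
one of three granularities: a product, a substance (ingredient), or a class.

Codes are opaque, case-sensitive strings compared by exact equality; no
checksum or derivation logic is attempted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AllergenKind",
    "Ingredient",
    "Drug",
    "DrugClass",
    "IngredientClass",
    "CrossReactivePair",
    "AllergenConcept",
    "KnowledgeBase",
    "MedicationResolution",
    "AllergenResolution",
    "Violation",
    "KnowledgeBaseError",
    "LoadError",
    "IntegrityError",
    "TABLE_FILES",
    "load_knowledge_base",
    "load_kb_dir",
    "save_kb_csvs",
    "kb_to_dict",
    "kb_from_dict",
    "kb_to_json",
    "kb_from_json",
    "validate_referential_integrity",
    "classes_containing",
    "resolve_medication",
    "resolve_allergen",
    "search_allergens",
]

#: Default file name for each table of the CSV serialization (UTF-8, header
#: row, RFC-4180 quoting). List-valued cells use ``;`` as the item separator.
TABLE_FILES: dict[str, str] = {
    "ingredients": "ingredients.csv",
    "drugs": "drugs.csv",
    "drug_ingredients": "drug_ingredients.csv",
    "drug_classes": "drug_classes.csv",
    "drug_class_members": "drug_class_members.csv",
    "ingredient_classes": "ingredient_classes.csv",
    "ingredient_class_members": "ingredient_class_members.csv",
    "cross_reactive_pairs": "cross_reactive_pairs.csv",
    "allergens": "allergens.csv",
}

_TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "ingredients": ("ingredient_code", "name", "synonyms"),
    "drugs": ("kd_code", "name"),
    "drug_ingredients": ("kd_code", "ingredient_code"),
    "drug_classes": ("class_code", "name"),
    "drug_class_members": ("class_code", "ingredient_code"),
    "ingredient_classes": ("class_code", "name"),
    "ingredient_class_members": ("class_code", "ingredient_code"),
    "cross_reactive_pairs": ("ingredient_a", "ingredient_b"),
    "allergens": (
        "allergen_code",
        "display",
        "kind",
        "target_code",
        "reaction_codes",
        "severity_codes",
    ),
}

_LIST_SEP = ";"


class KnowledgeBaseError(Exception):
    """Base class for knowledge-base errors."""


class LoadError(KnowledgeBaseError):
    """A table file is missing or structurally unreadable."""


class IntegrityError(KnowledgeBaseError):
    """Referential-integrity violations found while loading.

    Carries *every* violation found in one pass, not just the first, so a
    curator can fix a whole batch of rows at once.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = list(violations)
        lines = "\n".join(f"  - {v}" for v in self.violations)
        super().__init__(f"{len(self.violations)} integrity violation(s):\n{lines}")


class AllergenKind(str, Enum):
    """Granularity of an allergen concept: brand product, substance, or class."""

    PRODUCT = "product"
    SUBSTANCE = "substance"
    CLASS = "class"


@dataclass(frozen=True)
class Ingredient:
    ingredient_code: str
    name: str
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class Drug:
    """A regulated medicinal product identified by its KD code."""

    kd_code: str
    name: str
    ingredient_codes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DrugClass:
    class_code: str
    name: str
    member_ingredient_codes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class IngredientClass:
    class_code: str
    name: str
    member_ingredient_codes: frozenset[str] = frozenset()


@dataclass(frozen=True, order=True)
class CrossReactivePair:
    """An unordered cross-reactivity link, stored in canonical sorted order."""

    ingredient_a: str
    ingredient_b: str

    @classmethod
    def canonical(cls, a: str, b: str) -> "CrossReactivePair":
        x, y = sorted((a, b))
        return cls(x, y)

    @property
    def is_canonical(self) -> bool:
        return self.ingredient_a < self.ingredient_b


@dataclass(frozen=True)
class AllergenConcept:
    """One entry of the allergen value set a client may record for a patient.

    ``target_code`` references a Drug (kind=product), an Ingredient
    (kind=substance) or a DrugClass/IngredientClass (kind=class). Reaction and
    severity codes are carried for display only; they never affect screening.
    """

    allergen_code: str
    display: str
    kind: AllergenKind
    target_code: str
    reaction_codes: tuple[str, ...] = ()
    severity_codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class KnowledgeBase:
    ingredients: tuple[Ingredient, ...] = ()
    drugs: tuple[Drug, ...] = ()
    drug_classes: tuple[DrugClass, ...] = ()
    ingredient_classes: tuple[IngredientClass, ...] = ()
    cross_reactive_pairs: tuple[CrossReactivePair, ...] = ()
    allergen_concepts: tuple[AllergenConcept, ...] = ()

    # Keyed lookups (first occurrence wins; validation flags duplicates).
    @cached_property
    def ingredient_index(self) -> dict[str, Ingredient]:
        return _first_wins({i.ingredient_code: i for i in reversed(self.ingredients)})

    @cached_property
    def drug_index(self) -> dict[str, Drug]:
        return _first_wins({d.kd_code: d for d in reversed(self.drugs)})

    @cached_property
    def drug_class_index(self) -> dict[str, DrugClass]:
        return _first_wins({c.class_code: c for c in reversed(self.drug_classes)})

    @cached_property
    def ingredient_class_index(self) -> dict[str, IngredientClass]:
        return _first_wins({c.class_code: c for c in reversed(self.ingredient_classes)})

    @cached_property
    def allergen_index(self) -> dict[str, AllergenConcept]:
        return _first_wins({a.allergen_code: a for a in reversed(self.allergen_concepts)})

    @cached_property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        # Canonicalized here as well so screening is insensitive to stored order.
        return frozenset(
            tuple(sorted((p.ingredient_a, p.ingredient_b)))
            for p in self.cross_reactive_pairs
        )


def _first_wins(reversed_mapping: dict) -> dict:
    # Built from the reversed sequence so earlier rows overwrite later ones.
    return dict(reversed_mapping)


@dataclass(frozen=True)
class MedicationResolution:
    """A prescribed product expanded to its ingredients and containing classes."""

    kd_code: str
    ingredient_codes: frozenset[str]
    drug_class_codes: frozenset[str]
    ingredient_class_codes: frozenset[str]


@dataclass(frozen=True)
class AllergenResolution:
    """A recorded allergen expanded to the entities it denotes.

    For a substance the ingredient set is the single target ingredient; for a
    product it is the product's ingredients (with ``product_code`` set); for a
    class it is the class members (with ``class_codes`` = {target}).
    """

    allergen_code: str
    kind: AllergenKind
    product_code: str | None
    ingredient_codes: frozenset[str]
    class_codes: frozenset[str]


@dataclass(frozen=True)
class Violation:
    """One broken referential-integrity rule: which table, which key, what rule."""

    table: str
    key: str
    rule: str

    def __str__(self) -> str:
        return f"{self.table}[{self.key}]: {self.rule}"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_referential_integrity(kb: KnowledgeBase) -> list[Violation]:
    """Check every knowledge-base invariant, reporting all violations in one pass.

    Returns an empty list iff the knowledge base is internally consistent.
    Never raises: this is the reporting primitive that loaders and curation
    tools build on.
    """
    out: list[Violation] = []
    ing_codes = _collect_keys(out, "ingredients", [i.ingredient_code for i in kb.ingredients])

    seen_drugs = _collect_keys(out, "drugs", [d.kd_code for d in kb.drugs])
    for d in kb.drugs:
        if not d.ingredient_codes:
            out.append(Violation("drugs", d.kd_code, "drug has no ingredients"))
        for code in sorted(d.ingredient_codes):
            if code not in ing_codes:
                out.append(
                    Violation("drugs", d.kd_code, f"unknown ingredient code {code!r}")
                )

    for table, classes in (
        ("drug_classes", kb.drug_classes),
        ("ingredient_classes", kb.ingredient_classes),
    ):
        _collect_keys(out, table, [c.class_code for c in classes])
        for c in classes:
            for code in sorted(c.member_ingredient_codes):
                if code not in ing_codes:
                    out.append(
                        Violation(table, c.class_code, f"unknown ingredient code {code!r}")
                    )

    seen_pairs: set[tuple[str, str]] = set()
    for p in kb.cross_reactive_pairs:
        key = f"{p.ingredient_a},{p.ingredient_b}"
        if p.ingredient_a == p.ingredient_b:
            out.append(Violation("cross_reactive_pairs", key, "self-pair"))
        elif not p.is_canonical:
            out.append(
                Violation("cross_reactive_pairs", key, "pair not in canonical order")
            )
        canon = tuple(sorted((p.ingredient_a, p.ingredient_b)))
        if canon in seen_pairs:
            out.append(Violation("cross_reactive_pairs", key, "duplicate key"))
        seen_pairs.add(canon)
        for code in (p.ingredient_a, p.ingredient_b):
            if code not in ing_codes:
                out.append(
                    Violation("cross_reactive_pairs", key, f"unknown ingredient code {code!r}")
                )

    drug_codes = {d.kd_code for d in kb.drugs}
    class_codes = {c.class_code for c in kb.drug_classes} | {
        c.class_code for c in kb.ingredient_classes
    }
    _collect_keys(out, "allergens", [a.allergen_code for a in kb.allergen_concepts])
    for a in kb.allergen_concepts:
        target_pool = {
            AllergenKind.PRODUCT: drug_codes,
            AllergenKind.SUBSTANCE: ing_codes,
            AllergenKind.CLASS: class_codes,
        }[a.kind]
        if a.target_code not in target_pool:
            out.append(
                Violation(
                    "allergens",
                    a.allergen_code,
                    f"target code {a.target_code!r} not found for kind {a.kind.value!r}",
                )
            )
    return out


def _collect_keys(out: list[Violation], table: str, keys: list[str]) -> set[str]:
    seen: set[str] = set()
    for key in keys:
        if not key:
            out.append(Violation(table, key, "empty key"))
        elif key in seen:
            out.append(Violation(table, key, "duplicate key"))
        seen.add(key)
    return seen


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

def load_knowledge_base(table_paths: Mapping[str, str | Path]) -> KnowledgeBase:
    """Load the CSV tables named in ``table_paths`` into a validated KnowledgeBase.

    ``table_paths`` maps each table name of :data:`TABLE_FILES` to a file path.
    Cross-reactive pairs are canonicalized and de-duplicated on the way in.

    Raises :class:`LoadError` if a table is missing or malformed and
    :class:`IntegrityError` (listing every violation) if the loaded data is
    internally inconsistent.
    """
    rows: dict[str, list[dict[str, str]]] = {}
    for table in TABLE_FILES:
        if table not in table_paths:
            raise LoadError(f"missing table {table!r}: no path supplied")
        path = Path(table_paths[table])
        if not path.is_file():
            raise LoadError(f"missing table {table!r}: file not found: {path}")
        rows[table] = _read_csv(table, path)
    return _assemble(rows)


def load_kb_dir(kb_dir: str | Path) -> KnowledgeBase:
    """Load a knowledge base from a directory using the default file names."""
    base = Path(kb_dir)
    return load_knowledge_base({t: base / fn for t, fn in TABLE_FILES.items()})


def _read_csv(table: str, path: Path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        required = _TABLE_COLUMNS[table]
        if header is None or not set(required).issubset(header):
            raise LoadError(
                f"table {table!r} at {path}: header must contain columns {list(required)}"
            )
        out = []
        for row in reader:
            out.append({k: (row.get(k) or "").strip() for k in required})
        return out


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in cell.split(_LIST_SEP) if s.strip())


def _assemble(rows: dict[str, list[dict[str, str]]]) -> KnowledgeBase:
    extra: list[Violation] = []

    ingredients = tuple(
        Ingredient(r["ingredient_code"], r["name"], _split_list(r["synonyms"]))
        for r in rows["ingredients"]
    )

    drug_ings: dict[str, set[str]] = {}
    declared_drugs = {r["kd_code"] for r in rows["drugs"]}
    for i, r in enumerate(rows["drug_ingredients"], start=2):
        if r["kd_code"] not in declared_drugs:
            extra.append(
                Violation(
                    "drug_ingredients",
                    r["kd_code"],
                    f"row {i}: unknown kd_code {r['kd_code']!r}",
                )
            )
            continue
        drug_ings.setdefault(r["kd_code"], set()).add(r["ingredient_code"])
    drugs = tuple(
        Drug(r["kd_code"], r["name"], frozenset(drug_ings.get(r["kd_code"], ())))
        for r in rows["drugs"]
    )

    def classes(table: str, member_table: str, cls):
        members: dict[str, set[str]] = {}
        declared = {r["class_code"] for r in rows[table]}
        for i, r in enumerate(rows[member_table], start=2):
            if r["class_code"] not in declared:
                extra.append(
                    Violation(
                        member_table,
                        r["class_code"],
                        f"row {i}: unknown class_code {r['class_code']!r}",
                    )
                )
                continue
            members.setdefault(r["class_code"], set()).add(r["ingredient_code"])
        return tuple(
            cls(r["class_code"], r["name"], frozenset(members.get(r["class_code"], ())))
            for r in rows[table]
        )

    drug_classes = classes("drug_classes", "drug_class_members", DrugClass)
    ingredient_classes = classes(
        "ingredient_classes", "ingredient_class_members", IngredientClass
    )

    pairs = sorted(
        {
            CrossReactivePair.canonical(r["ingredient_a"], r["ingredient_b"])
            for r in rows["cross_reactive_pairs"]
        }
    )

    allergens: list[AllergenConcept] = []
    for i, r in enumerate(rows["allergens"], start=2):
        try:
            kind = AllergenKind(r["kind"])
        except ValueError:
            extra.append(
                Violation(
                    "allergens",
                    r["allergen_code"],
                    f"row {i}: invalid kind {r['kind']!r}",
                )
            )
            continue
        allergens.append(
            AllergenConcept(
                r["allergen_code"],
                r["display"],
                kind,
                r["target_code"],
                _split_list(r["reaction_codes"]),
                _split_list(r["severity_codes"]),
            )
        )

    kb = KnowledgeBase(
        ingredients=ingredients,
        drugs=drugs,
        drug_classes=drug_classes,
        ingredient_classes=ingredient_classes,
        cross_reactive_pairs=tuple(pairs),
        allergen_concepts=tuple(allergens),
    )
    violations = extra + validate_referential_integrity(kb)
    if violations:
        raise IntegrityError(violations)
    return kb


def save_kb_csvs(kb: KnowledgeBase, out_dir: str | Path) -> dict[str, Path]:
    """Write the knowledge base to CSV files in ``out_dir``; returns the paths."""
    base = Path(out_dir)
    base.mkdir(parents=True, exist_ok=True)
    paths = {t: base / fn for t, fn in TABLE_FILES.items()}

    def write(table: str, rows: Iterable[Iterable[str]]) -> None:
        with open(paths[table], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_TABLE_COLUMNS[table])
            w.writerows(rows)

    write(
        "ingredients",
        [(i.ingredient_code, i.name, _LIST_SEP.join(i.synonyms)) for i in kb.ingredients],
    )
    write("drugs", [(d.kd_code, d.name) for d in kb.drugs])
    write(
        "drug_ingredients",
        [(d.kd_code, c) for d in kb.drugs for c in sorted(d.ingredient_codes)],
    )
    write("drug_classes", [(c.class_code, c.name) for c in kb.drug_classes])
    write(
        "drug_class_members",
        [
            (c.class_code, m)
            for c in kb.drug_classes
            for m in sorted(c.member_ingredient_codes)
        ],
    )
    write("ingredient_classes", [(c.class_code, c.name) for c in kb.ingredient_classes])
    write(
        "ingredient_class_members",
        [
            (c.class_code, m)
            for c in kb.ingredient_classes
            for m in sorted(c.member_ingredient_codes)
        ],
    )
    write(
        "cross_reactive_pairs",
        [(p.ingredient_a, p.ingredient_b) for p in kb.cross_reactive_pairs],
    )
    write(
        "allergens",
        [
            (
                a.allergen_code,
                a.display,
                a.kind.value,
                a.target_code,
                _LIST_SEP.join(a.reaction_codes),
                _LIST_SEP.join(a.severity_codes),
            )
            for a in kb.allergen_concepts
        ],
    )
    return paths


def kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "ingredients": [
            {"ingredient_code": i.ingredient_code, "name": i.name, "synonyms": list(i.synonyms)}
            for i in kb.ingredients
        ],
        "drugs": [
            {"kd_code": d.kd_code, "name": d.name, "ingredient_codes": sorted(d.ingredient_codes)}
            for d in kb.drugs
        ],
        "drug_classes": [
            {
                "class_code": c.class_code,
                "name": c.name,
                "member_ingredient_codes": sorted(c.member_ingredient_codes),
            }
            for c in kb.drug_classes
        ],
        "ingredient_classes": [
            {
                "class_code": c.class_code,
                "name": c.name,
                "member_ingredient_codes": sorted(c.member_ingredient_codes),
            }
            for c in kb.ingredient_classes
        ],
        "cross_reactive_pairs": [
            [p.ingredient_a, p.ingredient_b] for p in kb.cross_reactive_pairs
        ],
        "allergens": [
            {
                "allergen_code": a.allergen_code,
                "display": a.display,
                "kind": a.kind.value,
                "target_code": a.target_code,
                "reaction_codes": list(a.reaction_codes),
                "severity_codes": list(a.severity_codes),
            }
            for a in kb.allergen_concepts
        ],
    }


def kb_from_dict(doc: Mapping) -> KnowledgeBase:
    return KnowledgeBase(
        ingredients=tuple(
            Ingredient(i["ingredient_code"], i["name"], tuple(i.get("synonyms", ())))
            for i in doc.get("ingredients", ())
        ),
        drugs=tuple(
            Drug(d["kd_code"], d["name"], frozenset(d.get("ingredient_codes", ())))
            for d in doc.get("drugs", ())
        ),
        drug_classes=tuple(
            DrugClass(c["class_code"], c["name"], frozenset(c.get("member_ingredient_codes", ())))
            for c in doc.get("drug_classes", ())
        ),
        ingredient_classes=tuple(
            IngredientClass(
                c["class_code"], c["name"], frozenset(c.get("member_ingredient_codes", ()))
            )
            for c in doc.get("ingredient_classes", ())
        ),
        cross_reactive_pairs=tuple(
            CrossReactivePair(a, b) for a, b in doc.get("cross_reactive_pairs", ())
        ),
        allergen_concepts=tuple(
            AllergenConcept(
                a["allergen_code"],
                a["display"],
                AllergenKind(a["kind"]),
                a["target_code"],
                tuple(a.get("reaction_codes", ())),
                tuple(a.get("severity_codes", ())),
            )
            for a in doc.get("allergens", ())
        ),
    )


def kb_to_json(kb: KnowledgeBase) -> str:
    """Stable, lossless single-file JSON serialization of the knowledge base."""
    return json.dumps(kb_to_dict(kb), indent=2, sort_keys=True, ensure_ascii=False)


def kb_from_json(text: str) -> KnowledgeBase:
    return kb_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Resolution and search
# ---------------------------------------------------------------------------

def classes_containing(kb: KnowledgeBase, ingredient_codes: Iterable[str]) -> frozenset[str]:
    """Codes of every drug class or ingredient class containing any of the ingredients."""
    codes = set(ingredient_codes)
    hits = {
        c.class_code
        for c in kb.drug_classes
        if c.member_ingredient_codes & codes
    }
    hits |= {
        c.class_code
        for c in kb.ingredient_classes
        if c.member_ingredient_codes & codes
    }
    return frozenset(hits)


def resolve_medication(kb: KnowledgeBase, kd_code: str) -> MedicationResolution | None:
    """Expand a prescribed KD code to its ingredients and containing classes.

    Returns ``None`` for a KD code absent from the catalogue; the caller
    decides whether that is an error or merely an unresolved code.
    """
    drug = kb.drug_index.get(kd_code)
    if drug is None:
        return None
    ings = drug.ingredient_codes
    return MedicationResolution(
        kd_code=kd_code,
        ingredient_codes=ings,
        drug_class_codes=frozenset(
            c.class_code for c in kb.drug_classes if c.member_ingredient_codes & ings
        ),
        ingredient_class_codes=frozenset(
            c.class_code for c in kb.ingredient_classes if c.member_ingredient_codes & ings
        ),
    )


def resolve_allergen(kb: KnowledgeBase, allergen_code: str) -> AllergenResolution | None:
    """Expand a recorded allergen code to the product/ingredients/classes it denotes."""
    alg = kb.allergen_index.get(allergen_code)
    if alg is None:
        return None
    if alg.kind is AllergenKind.SUBSTANCE:
        return AllergenResolution(
            allergen_code, alg.kind, None, frozenset({alg.target_code}), frozenset()
        )
    if alg.kind is AllergenKind.PRODUCT:
        drug = kb.drug_index.get(alg.target_code)
        ings = drug.ingredient_codes if drug is not None else frozenset()
        return AllergenResolution(
            allergen_code, alg.kind, alg.target_code, ings, frozenset()
        )
    cls = kb.drug_class_index.get(alg.target_code) or kb.ingredient_class_index.get(
        alg.target_code
    )
    members = cls.member_ingredient_codes if cls is not None else frozenset()
    return AllergenResolution(
        allergen_code, alg.kind, None, members, frozenset({alg.target_code})
    )


def search_allergens(kb: KnowledgeBase, query: str) -> list[AllergenConcept]:
    """Case-insensitive substring search over the allergen value set.

    Matches against the allergen display and the names and synonyms of the
    ingredients it resolves to. Results are ordered by (earliest match
    position, allergen code), which makes repeated calls deterministic.
    """
    q = query.strip().lower()
    if not q:
        raise ValueError("query must be nonempty after trimming")
    scored: list[tuple[int, str, AllergenConcept]] = []
    for alg in kb.allergen_concepts:
        haystacks = [alg.display]
        res = resolve_allergen(kb, alg.allergen_code)
        if res is not None:
            for code in sorted(res.ingredient_codes):
                ing = kb.ingredient_index.get(code)
                if ing is not None:
                    haystacks.append(ing.name)
                    haystacks.extend(ing.synonyms)
        positions = [h.lower().find(q) for h in haystacks]
        hits = [p for p in positions if p >= 0]
        if hits:
            scored.append((min(hits), alg.allergen_code, alg))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [alg for _, _, alg in scored]
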