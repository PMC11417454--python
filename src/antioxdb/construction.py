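"""Construction of the composition table from prioritized source databases.

The matching/imputation protocol attempts, for every (food, component) pair,
a fixed sequence of methods and records which one produced the value:

1. direct match — a source record with an identical canonical name and the
   same form, taken from the highest-priority source in the component's
   lane; multiple records for the same (name, form) are varieties and are
   averaged;
2. moisture conversion — a same-name record in a *different* form, rescaled
   by the dry-matter ratio ``(100 - water_target) / (100 - water_source)``;
3. recipe composition — for prepared dishes, the ingredient-weight-weighted
   mean per 100 g of combined raw ingredient mass;
4. similar-food substitution — the value of the most similar food that
   already has one (same genus > same family > same plant part > same
   color, ties broken by food_id);
5. logical zero — rule-based zeros for food groups that cannot contain the
   compound (e.g. flavonoids in animal-based groups);
6. otherwise the cell stays missing.

Two priority lanes order the sources: one for vitamins and carotenoids, one
for flavonoids.  The whole build is a pure function of its inputs; rerunning
it yields an identical table and match ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .taxonomy import (
    ComponentRegistry,
    CompositionCell,
    CompositionTable,
    FoodItem,
    Provenance,
    SIMILARITY_ATTRIBUTES,
)

logger = logging.getLogger(__name__)

#: preference order for the donor form when converting between forms
FORM_PREFERENCE = ("raw", "boiled", "blanched", "dried", "prepared")

#: default priority lanes (source identifiers in decreasing priority)
DEFAULT_LANES: dict[str, tuple[str, ...]] = {
    "vitamins_carotenoids": ("KMFDS", "USDA_SR28", "JMEXT"),
    "flavonoids": (
        "USDA_flavonoid",
        "USDA_isoflavone",
        "USDA_proanthocyanidin",
        "PhenolExplorer",
    ),
}

#: animal-based food groups that receive logical zeros for carotenoids and
#: flavonoids
ANIMAL_GROUPS = frozenset(
    {
        "Meats and their products",
        "Processed meats",
        "Fish and shellfish",
        "Eggs",
        "Milk and dairy products",
        "Fats and oils",
    }
)

#: tea-derived flavan-3-ols present only in beverages
TEA_COMPONENTS = (
    "theaflavin",
    "thearubigin",
    "theaflavin_3_gallate",
    "theaflavin_3p_gallate",
    "theaflavin_33p_digallate",
)


def canonical_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace (no fuzzy matching)."""
    return " ".join(name.split()).casefold()


# ---------------------------------------------------------------------------
# input types


@dataclass(frozen=True)
class SourceRecord:
    """One per-food per-component value in a source database."""

    name: str
    form: str
    component_id: str
    value: float
    water_content: Optional[float] = None
    #: basis of the reported amount; glycoside records are converted to the
    #: aglycone at ingest using the molecular-weight table
    basis: str = "aglycone"
    glycoside: Optional[str] = None


class SourceDatabase:
    """A named source database with an internal (name, form, component) index."""

    def __init__(self, source_id: str, records: Sequence[SourceRecord]):
        self.source_id = source_id
        self.records = list(records)
        self._by_exact: dict[tuple[str, str, str], list[SourceRecord]] = {}
        self._by_name: dict[tuple[str, str], list[SourceRecord]] = {}
        for rec in self.records:
            canon = canonical_name(rec.name)
            self._by_exact.setdefault((canon, rec.form, rec.component_id), []).append(rec)
            self._by_name.setdefault((canon, rec.component_id), []).append(rec)

    def lookup(self, names: Iterable[str], form: str, component_id: str) -> list[SourceRecord]:
        for name in names:
            recs = self._by_exact.get((canonical_name(name), form, component_id))
            if recs:
                return recs
        return []

    def lookup_other_forms(
        self, names: Iterable[str], form: str, component_id: str
    ) -> list[SourceRecord]:
        for name in names:
            recs = self._by_name.get((canonical_name(name), component_id))
            if recs:
                other = [r for r in recs if r.form != form and r.water_content is not None]
                if other:
                    return other
        return []


@dataclass(frozen=True)
class PriorityLane:
    """Ordered source identifiers for one component family."""

    lane: str
    source_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.source_ids)) != len(self.source_ids):
            raise ValueError(f"lane {self.lane}: priority ranks must be unique")


@dataclass(frozen=True)
class Recipe:
    """A prepared dish defined by ingredient foods and gram weights."""

    dish_id: str
    ingredients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValueError(f"{self.dish_id}: recipe needs at least one ingredient")
        for fid, grams in self.ingredients:
            if grams <= 0:
                raise ValueError(f"{self.dish_id}: non-positive weight for {fid}")


@dataclass(frozen=True)
class MolecularWeightEntry:
    """Glycoside -> aglycone conversion factors (g/mol)."""

    glycoside_name: str
    aglycone_component_id: str
    mw_glycoside: float
    mw_aglycone: float

    def __post_init__(self) -> None:
        if self.mw_glycoside <= 0 or self.mw_aglycone <= 0:
            raise ValueError("molecular weights must be positive")
        if self.mw_aglycone > self.mw_glycoside:
            raise ValueError("aglycone cannot be heavier than its glycoside")


@dataclass(frozen=True)
class ZeroRule:
    """Assign value 0 to missing cells of given components in given groups.

    Either ``food_groups`` (apply inside these groups) or ``exclude_groups``
    (apply everywhere *except* these groups) must be set.
    """

    component_ids: frozenset[str]
    food_groups: Optional[frozenset[str]] = None
    exclude_groups: Optional[frozenset[str]] = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if not self.component_ids:
            raise ValueError("zero rule needs at least one component")
        if (self.food_groups is None) == (self.exclude_groups is None):
            raise ValueError("exactly one of food_groups/exclude_groups required")
        if self.food_groups is not None and not self.food_groups:
            raise ValueError("zero rule needs at least one food group")

    def applies_to(self, food: FoodItem) -> bool:
        if self.food_groups is not None:
            return food.food_group in self.food_groups
        return food.food_group not in self.exclude_groups  # type: ignore[operator]


def default_zero_rules(registry: ComponentRegistry) -> list[ZeroRule]:
    """The canonical zero rules: carotenoids and flavonoids absent from
    animal-based groups; tea flavan-3-ols absent outside beverages."""
    carot_flav = frozenset(
        c.component_id
        for c in registry
        if c.antioxidant_class in ("carotenoids", "flavonoids")
    )
    rules = [
        ZeroRule(
            component_ids=carot_flav,
            food_groups=ANIMAL_GROUPS,
            rationale="carotenoids and flavonoids are not expected in animal-based groups",
        )
    ]
    tea = frozenset(cid for cid in TEA_COMPONENTS if cid in registry)
    if tea:
        rules.append(
            ZeroRule(
                component_ids=tea,
                exclude_groups=frozenset({"Beverages and drinks"}),
                rationale="theaflavins and thearubigins occur only in tea beverages",
            )
        )
    return rules


# ---------------------------------------------------------------------------
# elementary operations


def deduplicate_foods(candidates: Sequence[FoodItem]) -> list[FoodItem]:
    """Collapse foods identical in (canonical primary name, form), keeping
    the first occurrence; output order is first-occurrence order."""
    seen: set[tuple[str, str]] = set()
    out: list[FoodItem] = []
    for food in candidates:
        key = (canonical_name(food.names[0]), food.form)
        if key not in seen:
            seen.add(key)
            out.append(food)
    return out


def average_varieties(values: Sequence[float]) -> float:
    """Arithmetic mean over varieties of the same food item."""
    if len(values) == 0:
        raise ValueError("cannot average an empty list of variety values")
    return float(np.mean(values))


def moisture_convert(value: float, water_source: float, water_target: float) -> float:
    """Rescale a per-100 g amount between forms by the dry-matter ratio."""
    for w in (water_source, water_target):
        if not (0 <= w < 100):
            raise ValueError(f"water content must lie in [0, 100), got {w}")
    return value * (100.0 - water_target) / (100.0 - water_source)


def glycoside_to_aglycone(value: float, entry: MolecularWeightEntry) -> float:
    """Express a glycoside amount as its aglycone equivalent."""
    return value * entry.mw_aglycone / entry.mw_glycoside


def match_direct(
    food: FoodItem,
    component_id: str,
    lane_sources: Sequence[SourceDatabase],
) -> Optional[CompositionCell]:
    """Identical-name, identical-form match from the highest-priority source.

    Multiple records in the chosen source are varieties and are averaged
    (provenance ``variety_average``); a single record is ``source_direct``.
    """
    for source in lane_sources:
        recs = source.lookup(food.names, food.form, component_id)
        if recs:
            if len(recs) > 1:
                return CompositionCell(
                    food.food_id,
                    component_id,
                    average_varieties([r.value for r in recs]),
                    Provenance.VARIETY_AVERAGE.value,
                    source.source_id,
                )
            return CompositionCell(
                food.food_id,
                component_id,
                recs[0].value,
                Provenance.SOURCE_DIRECT.value,
                source.source_id,
            )
    return None


def match_moisture(
    food: FoodItem,
    component_id: str,
    lane_sources: Sequence[SourceDatabase],
) -> Optional[CompositionCell]:
    """Same-name different-form match converted by water content.

    Lane priority decides the source first; within the source the donor
    form follows a fixed preference order, and varieties within the chosen
    form are converted individually then averaged.
    """
    if food.water_content is None:
        return None
    for source in lane_sources:
        recs = source.lookup_other_forms(food.names, food.form, component_id)
        if not recs:
            continue
        by_form: dict[str, list[SourceRecord]] = {}
        for r in recs:
            by_form.setdefault(r.form, []).append(r)
        for form in FORM_PREFERENCE:
            if form in by_form:
                converted = [
                    moisture_convert(r.value, r.water_content, food.water_content)
                    for r in by_form[form]
                ]
                return CompositionCell(
                    food.food_id,
                    component_id,
                    average_varieties(converted),
                    Provenance.MOISTURE_CONVERSION.value,
                    source.source_id,
                )
    return None


def recipe_compose(
    recipe: Recipe, table: CompositionTable, component_id: str
) -> Optional[float]:
    """Weight-weighted mean per 100 g of combined ingredient mass.

    Any ingredient missing the component makes the dish value missing
    (conservative propagation, logged).
    """
    total = 0.0
    weighted = 0.0
    for fid, grams in recipe.ingredients:
        v = table.values.at[fid, component_id]
        if pd.isna(v):
            logger.warning(
                "recipe %s: ingredient %s missing %s; dish value left missing",
                recipe.dish_id, fid, component_id,
            )
            return None
        total += grams
        weighted += grams * float(v)
    return weighted / total


def _similarity(food: FoodItem, donor: FoodItem) -> tuple[int, ...]:
    score = []
    for attr in SIMILARITY_ATTRIBUTES:
        a, b = food.attributes.get(attr), donor.attributes.get(attr)
        score.append(int(a is not None and a == b))
    return tuple(score)


def substitute_similar(
    food: FoodItem,
    donors: Sequence[FoodItem],
    table: CompositionTable,
    component_id: str,
) -> Optional[CompositionCell]:
    """Borrow the value of the most similar donor food.

    Donors are scored lexicographically: same genus > same family > same
    plant part > same color; ties broken by lexicographic food_id.  A donor
    must share at least one attribute and have a non-missing value.
    """
    best: Optional[tuple[tuple[int, ...], str, FoodItem]] = None
    for donor in donors:
        if donor.food_id == food.food_id:
            continue
        if pd.isna(table.values.at[donor.food_id, component_id]):
            continue
        score = _similarity(food, donor)
        if not any(score):
            continue
        key = (tuple(-s for s in score), donor.food_id)
        if best is None or key < (best[0], best[1]):
            best = (key[0], donor.food_id, donor)
    if best is None:
        return None
    donor = best[2]
    return CompositionCell(
        food.food_id,
        component_id,
        float(table.values.at[donor.food_id, component_id]),
        Provenance.SIMILAR_FOOD.value,
        None,
    )


def assign_logical_zeros(
    table: CompositionTable, rules: Sequence[ZeroRule]
) -> CompositionTable:
    """Fill missing cells matched by a zero rule with value 0.

    Cells that already contain data are never overwritten; the input table
    is modified in place and returned.
    """
    for rule in rules:
        for cid in sorted(rule.component_ids):
            if cid not in table.registry:
                raise ValueError(f"zero rule references unknown component: {cid}")
        for food in table.foods:
            if not rule.applies_to(food):
                continue
            for cid in sorted(rule.component_ids):
                if pd.isna(table.values.at[food.food_id, cid]):
                    table.set_cell(food.food_id, cid, 0.0, Provenance.LOGICAL_ZERO)
    return table


# ---------------------------------------------------------------------------
# glycoside normalisation and recipe ordering


def normalize_sources(
    sources: Mapping[str, SourceDatabase],
    mw_table: Sequence[MolecularWeightEntry],
) -> dict[str, SourceDatabase]:
    """Convert glycoside-basis records to aglycone equivalents."""
    mw_index = {e.glycoside_name: e for e in mw_table}
    out: dict[str, SourceDatabase] = {}
    for sid, src in sources.items():
        records = []
        for rec in src.records:
            if rec.basis == "glycoside":
                if rec.glycoside is None or rec.glycoside not in mw_index:
                    raise ValueError(
                        f"{sid}: glycoside record for {rec.component_id} without a "
                        f"molecular-weight entry ({rec.glycoside!r})"
                    )
                entry = mw_index[rec.glycoside]
                records.append(
                    SourceRecord(
                        name=rec.name,
                        form=rec.form,
                        component_id=rec.component_id,
                        value=glycoside_to_aglycone(rec.value, entry),
                        water_content=rec.water_content,
                        basis="aglycone",
                    )
                )
            else:
                records.append(rec)
        out[sid] = SourceDatabase(sid, records)
    return out


def order_recipes(recipes: Sequence[Recipe]) -> list[Recipe]:
    """Topologically order dishes so ingredients are resolved first.

    Raises on cyclic recipes (a dish depending on itself directly or
    transitively).
    """
    by_dish = {r.dish_id: r for r in recipes}
    state: dict[str, int] = {}
    ordered: list[Recipe] = []

    def visit(dish_id: str, stack: list[str]) -> None:
        if state.get(dish_id) == 2:
            return
        if state.get(dish_id) == 1:
            cycle = " -> ".join(stack + [dish_id])
            raise ValueError(f"cyclic recipe dependency: {cycle}")
        state[dish_id] = 1
        for fid, _ in by_dish[dish_id].ingredients:
            if fid in by_dish:
                visit(fid, stack + [dish_id])
        state[dish_id] = 2
        ordered.append(by_dish[dish_id])

    for r in recipes:
        visit(r.dish_id, [])
    return ordered


# ---------------------------------------------------------------------------
# full protocol


def lane_for_component(registry: ComponentRegistry, component_id: str) -> str:
    cls = registry.get(component_id).antioxidant_class
    return "flavonoids" if cls == "flavonoids" else "vitamins_carotenoids"


def build_database(
    foods: Sequence[FoodItem],
    sources: Mapping[str, SourceDatabase],
    lanes: Mapping[str, Sequence[str]] | None = None,
    recipes: Sequence[Recipe] = (),
    mw_table: Sequence[MolecularWeightEntry] = (),
    zero_rules: Sequence[ZeroRule] | None = None,
    registry: ComponentRegistry | None = None,
) -> tuple[CompositionTable, pd.DataFrame]:
    """Run the full matching protocol; return the table and a match ledger.

    The ledger has one row per (food, component) cell with columns
    ``food_id, component_id, method, source_db``; ``method`` is the
    provenance label, ``missing`` where no method applied.
    """
    from .taxonomy import default_registry, validate_table

    registry = registry or default_registry()
    lanes = dict(lanes) if lanes is not None else dict(DEFAULT_LANES)
    if zero_rules is None:
        zero_rules = default_zero_rules(registry)

    foods = deduplicate_foods(foods)
    sources = normalize_sources(sources, mw_table)
    dish_ids = {r.dish_id for r in recipes}
    recipes_ordered = order_recipes(recipes)
    table = CompositionTable(foods, registry)

    lane_sources: dict[str, list[SourceDatabase]] = {
        lane: [sources[sid] for sid in sids if sid in sources]
        for lane, sids in lanes.items()
    }

    for cid in registry.component_ids:
        srcs = lane_sources.get(lane_for_component(registry, cid), [])

        # steps 1-2: direct match, then moisture conversion
        for food in foods:
            cell = match_direct(food, cid, srcs) or match_moisture(food, cid, srcs)
            if cell is not None:
                table.set_cell(food.food_id, cid, cell.value, cell.provenance, cell.source_db)

        # step 3: recipe composition for prepared dishes, ingredients first
        for recipe in recipes_ordered:
            if not pd.isna(table.values.at[recipe.dish_id, cid]):
                continue
            value = recipe_compose(recipe, table, cid)
            if value is not None:
                table.set_cell(recipe.dish_id, cid, value, Provenance.RECIPE)

        # step 4: similar-food substitution from already-resolved donors
        donors = [
            f for f in foods
            if f.food_id not in dish_ids
            and not pd.isna(table.values.at[f.food_id, cid])
        ]
        for food in foods:
            if not pd.isna(table.values.at[food.food_id, cid]):
                continue
            cell = substitute_similar(food, donors, table, cid)
            if cell is not None:
                table.set_cell(food.food_id, cid, cell.value, cell.provenance)

    # step 5: logical zeros (never overwrite data)
    assign_logical_zeros(table, zero_rules)

    violations = validate_table(table)
    if violations:  # pragma: no cover - defensive; the protocol cannot produce these
        raise AssertionError(f"built table failed validation: {violations[:3]}")

    ledger = table.to_frame().rename(columns={"provenance": "method"})[
        ["food_id", "component_id", "method", "source_db"]
    ]
    return table, ledger


# ---------------------------------------------------------------------------
# delimited-text interchange


def read_sources_csv(path) -> dict[str, SourceDatabase]:
    """Read source records: source_id, name, form, component_id, value,
    water_content, basis, glycoside."""
    df = pd.read_csv(path)
    out: dict[str, list[SourceRecord]] = {}
    for row in df.itertuples(index=False):
        rec = SourceRecord(
            name=row.name,
            form=row.form,
            component_id=row.component_id,
            value=float(row.value),
            water_content=None if pd.isna(row.water_content) else float(row.water_content),
            basis=getattr(row, "basis", "aglycone") if isinstance(getattr(row, "basis", None), str) else "aglycone",
            glycoside=getattr(row, "glycoside", None) if isinstance(getattr(row, "glycoside", None), str) else None,
        )
        out.setdefault(row.source_id, []).append(rec)
    return {sid: SourceDatabase(sid, recs) for sid, recs in out.items()}


def write_sources_csv(sources: Mapping[str, SourceDatabase], path) -> None:
    rows = []
    for sid in sources:
        for rec in sources[sid].records:
            rows.append(
                {
                    "source_id": sid,
                    "name": rec.name,
                    "form": rec.form,
                    "component_id": rec.component_id,
                    "value": rec.value,
                    "water_content": rec.water_content,
                    "basis": rec.basis,
                    "glycoside": rec.glycoside,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_recipes_csv(path) -> list[Recipe]:
    """Read recipes: dish_id, ingredient_id, grams (one row per ingredient)."""
    df = pd.read_csv(path, dtype={"dish_id": str, "ingredient_id": str})
    recipes = []
    for dish_id, grp in df.groupby("dish_id", sort=False):
        recipes.append(
            Recipe(
                dish_id=str(dish_id),
                ingredients=tuple(
                    (str(r.ingredient_id), float(r.grams)) for r in grp.itertuples()
                ),
            )
        )
    return recipes


def write_recipes_csv(recipes: Sequence[Recipe], path) -> None:
    rows = [
        {"dish_id": r.dish_id, "ingredient_id": fid, "grams": grams}
        for r in recipes
        for fid, grams in r.ingredients
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
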