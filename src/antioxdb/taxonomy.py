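"""Antioxidant taxonomy, units, and the composition-table data model.

The default registry describes 48 measured antioxidant components grouped
into five classes — retinol, carotenoids, vitamin C, vitamin E, and
flavonoids — with the flavonoids split into seven subclasses (flavonols,
flavones, flavanones, flavan-3-ols, anthocyanins, isoflavones,
proanthocyanidins).  Forty-one components carry a vitamin C equivalent
antioxidant capacity (VCEAC) and enter total antioxidant capacity (TAC)
estimation; the remaining seven (retinol, gallocatechin, formononetin, the
4-6 and 7-10 proanthocyanidin oligomers, proanthocyanidin polymers, and the
total-isoflavone aggregate) are stored but never contribute to TAC.

Composition values are amounts per 100 g edible portion.  Units are fixed
per component (micrograms or milligrams per 100 g); all TAC arithmetic is
performed after conversion to mg/100 g.  A *missing* value is distinct from
a *logical zero*: zeros are data, missing cells are the absence of data, and
coverage statistics count zeros as data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# units

UG = "ug_per_100g"
MG = "mg_per_100g"
UNITS = (UG, MG)

CLASSES = ("retinol", "carotenoids", "vitamin_C", "vitamin_E", "flavonoids")
SUBCLASSES = (
    "flavonols",
    "flavones",
    "flavanones",
    "flavan_3_ols",
    "anthocyanins",
    "isoflavones",
    "proanthocyanidins",
)
FORMS = ("raw", "dried", "boiled", "blanched", "prepared")

#: taxonomy attributes used for similar-food substitution, in priority order
SIMILARITY_ATTRIBUTES = ("genus", "family", "plant_part", "color")


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an amount between micrograms and milligrams per 100 g."""
    if from_unit not in UNITS or to_unit not in UNITS:
        raise ValueError(f"unsupported unit pair: {from_unit!r} -> {to_unit!r}")
    if from_unit == to_unit:
        return value
    return value / 1000.0 if from_unit == UG else value * 1000.0


class Provenance(str, Enum):
    """How a composition value was obtained."""

    SOURCE_DIRECT = "source_direct"
    VARIETY_AVERAGE = "variety_average"
    MOISTURE_CONVERSION = "moisture_conversion"
    RECIPE = "recipe"
    SIMILAR_FOOD = "similar_food"
    LOGICAL_ZERO = "logical_zero"
    MISSING = "missing"


PROVENANCE_VALUES = tuple(p.value for p in Provenance)
#: provenance labels that count as data (everything except missing)
DATA_PROVENANCES = tuple(p.value for p in Provenance if p is not Provenance.MISSING)


# ---------------------------------------------------------------------------
# components and registry


@dataclass(frozen=True)
class AntioxidantComponent:
    """One measured compound with class/subclass membership and TAC eligibility.

    ``is_aggregate`` marks pseudo-components that summarise others (the
    total-isoflavone column); aggregates are excluded from class and
    subclass sums to avoid double counting.
    """

    component_id: str
    name: str
    unit: str
    antioxidant_class: str
    flavonoid_subclass: Optional[str] = None
    tac_eligible: bool = True
    is_aggregate: bool = False

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"{self.component_id}: unknown unit {self.unit!r}")
        if self.antioxidant_class not in CLASSES:
            raise ValueError(
                f"{self.component_id}: unknown class {self.antioxidant_class!r}"
            )
        if self.antioxidant_class == "flavonoids":
            if self.flavonoid_subclass not in SUBCLASSES:
                raise ValueError(
                    f"{self.component_id}: flavonoid requires a known subclass, "
                    f"got {self.flavonoid_subclass!r}"
                )
        elif self.flavonoid_subclass is not None:
            raise ValueError(
                f"{self.component_id}: subclass only allowed for flavonoids"
            )


class ComponentRegistry:
    """Ordered collection of antioxidant components keyed by component_id."""

    def __init__(self, components: Sequence[AntioxidantComponent]):
        if not components:
            raise ValueError("no components")
        self._components: dict[str, AntioxidantComponent] = {}
        for comp in components:
            if comp.component_id in self._components:
                raise ValueError(f"duplicate component_id: {comp.component_id}")
            self._components[comp.component_id] = comp

    def __len__(self) -> int:
        return len(self._components)

    def __iter__(self) -> Iterator[AntioxidantComponent]:
        return iter(self._components.values())

    def __contains__(self, component_id: str) -> bool:
        return component_id in self._components

    def get(self, component_id: str) -> AntioxidantComponent:
        try:
            return self._components[component_id]
        except KeyError:
            raise KeyError(f"unknown component: {component_id}") from None

    @property
    def component_ids(self) -> list[str]:
        return list(self._components)

    def unit_of(self, component_id: str) -> str:
        return self.get(component_id).unit

    def by_class(self, antioxidant_class: str) -> list[AntioxidantComponent]:
        if antioxidant_class not in CLASSES:
            raise ValueError(f"unknown class: {antioxidant_class}")
        return [
            c for c in self if c.antioxidant_class == antioxidant_class
        ]

    def by_subclass(self, subclass: str) -> list[AntioxidantComponent]:
        if subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass: {subclass}")
        return [c for c in self if c.flavonoid_subclass == subclass]

    def tac_eligible_ids(self) -> list[str]:
        return [c.component_id for c in self if c.tac_eligible]

    def validate_default_counts(self) -> None:
        """Enforce the counts of the canonical 48-component taxonomy."""
        if len(self) != 48:
            raise ValueError(f"default taxonomy must have 48 components, got {len(self)}")
        n_eligible = len(self.tac_eligible_ids())
        if n_eligible != 41:
            raise ValueError(
                f"default taxonomy must have 41 TAC-eligible components, got {n_eligible}"
            )
        expected_class = {
            "retinol": 1,
            "carotenoids": 5,
            "vitamin_C": 1,
            "vitamin_E": 4,
            "flavonoids": 37,
        }
        for cls, n in expected_class.items():
            got = len(self.by_class(cls))
            if got != n:
                raise ValueError(f"class {cls}: expected {n} components, got {got}")
        expected_sub = {
            "flavonols": 4,
            "flavones": 2,
            "flavanones": 3,
            "flavan_3_ols": 11,
            "anthocyanins": 6,
            "isoflavones": 6,
            "proanthocyanidins": 5,
        }
        for sub, n in expected_sub.items():
            got = len(self.by_subclass(sub))
            if got != n:
                raise ValueError(f"subclass {sub}: expected {n} components, got {got}")


def _c(cid, name, unit, cls, sub=None, tac=True, agg=False) -> dict:
    return dict(
        component_id=cid,
        name=name,
        unit=unit,
        antioxidant_class=cls,
        flavonoid_subclass=sub,
        tac_eligible=tac,
        is_aggregate=agg,
    )


#: the canonical 48-component taxonomy (default configuration)
DEFAULT_TAXONOMY: dict = {
    "default": True,
    "components": [
        _c("retinol", "Retinol", UG, "retinol", tac=False),
        _c("vitamin_c", "Vitamin C (ascorbic acid)", MG, "vitamin_C"),
        _c("alpha_tocopherol", "Alpha-tocopherol", MG, "vitamin_E"),
        _c("beta_tocopherol", "Beta-tocopherol", MG, "vitamin_E"),
        _c("gamma_tocopherol", "Gamma-tocopherol", MG, "vitamin_E"),
        _c("delta_tocopherol", "Delta-tocopherol", MG, "vitamin_E"),
        _c("alpha_carotene", "Alpha-carotene", UG, "carotenoids"),
        _c("beta_carotene", "Beta-carotene", UG, "carotenoids"),
        _c("lycopene", "Lycopene", UG, "carotenoids"),
        _c("beta_cryptoxanthin", "Beta-cryptoxanthin", UG, "carotenoids"),
        _c("lutein_zeaxanthin", "Lutein and zeaxanthin", UG, "carotenoids"),
        _c("quercetin", "Quercetin", MG, "flavonoids", "flavonols"),
        _c("kaempferol", "Kaempferol", MG, "flavonoids", "flavonols"),
        _c("myricetin", "Myricetin", MG, "flavonoids", "flavonols"),
        _c("isorhamnetin", "Isorhamnetin", MG, "flavonoids", "flavonols"),
        _c("luteolin", "Luteolin", MG, "flavonoids", "flavones"),
        _c("apigenin", "Apigenin", MG, "flavonoids", "flavones"),
        _c("hesperetin", "Hesperetin", MG, "flavonoids", "flavanones"),
        _c("naringenin", "Naringenin", MG, "flavonoids", "flavanones"),
        _c("eriodictyol", "Eriodictyol", MG, "flavonoids", "flavanones"),
        _c("catechin", "Catechin", MG, "flavonoids", "flavan_3_ols"),
        _c("epicatechin", "Epicatechin", MG, "flavonoids", "flavan_3_ols"),
        _c("epigallocatechin", "Epigallocatechin", MG, "flavonoids", "flavan_3_ols"),
        _c("epicatechin_3_gallate", "Epicatechin 3-gallate", MG, "flavonoids", "flavan_3_ols"),
        _c("epigallocatechin_3_gallate", "Epigallocatechin 3-gallate", MG, "flavonoids", "flavan_3_ols"),
        _c("gallocatechin", "Gallocatechin", MG, "flavonoids", "flavan_3_ols", tac=False),
        _c("theaflavin", "Theaflavin", MG, "flavonoids", "flavan_3_ols"),
        _c("thearubigin", "Thearubigin", MG, "flavonoids", "flavan_3_ols"),
        _c("theaflavin_3_gallate", "Theaflavin 3-gallate", MG, "flavonoids", "flavan_3_ols"),
        _c("theaflavin_3p_gallate", "Theaflavin 3'-gallate", MG, "flavonoids", "flavan_3_ols"),
        _c("theaflavin_33p_digallate", "Theaflavin 3,3'-digallate", MG, "flavonoids", "flavan_3_ols"),
        _c("cyanidin", "Cyanidin", MG, "flavonoids", "anthocyanins"),
        _c("delphinidin", "Delphinidin", MG, "flavonoids", "anthocyanins"),
        _c("malvidin", "Malvidin", MG, "flavonoids", "anthocyanins"),
        _c("pelargonidin", "Pelargonidin", MG, "flavonoids", "anthocyanins"),
        _c("peonidin", "Peonidin", MG, "flavonoids", "anthocyanins"),
        _c("petunidin", "Petunidin", MG, "flavonoids", "anthocyanins"),
        _c("total_isoflavones", "Total isoflavones", MG, "flavonoids", "isoflavones", tac=False, agg=True),
        _c("daidzein", "Daidzein", MG, "flavonoids", "isoflavones"),
        _c("genistein", "Genistein", MG, "flavonoids", "isoflavones"),
        _c("glycitein", "Glycitein", MG, "flavonoids", "isoflavones"),
        _c("biochanin_a", "Biochanin A", MG, "flavonoids", "isoflavones"),
        _c("formononetin", "Formononetin", MG, "flavonoids", "isoflavones", tac=False),
        _c("pa_dimers", "Proanthocyanidin dimers", MG, "flavonoids", "proanthocyanidins"),
        _c("pa_trimers", "Proanthocyanidin trimers", MG, "flavonoids", "proanthocyanidins"),
        _c("pa_4_6mers", "Proanthocyanidin 4-6 monomers", MG, "flavonoids", "proanthocyanidins", tac=False),
        _c("pa_7_10mers", "Proanthocyanidin 7-10 monomers", MG, "flavonoids", "proanthocyanidins", tac=False),
        _c("pa_polymers", "Proanthocyanidin polymers", MG, "flavonoids", "proanthocyanidins", tac=False),
    ],
}


def load_taxonomy(config: Mapping) -> ComponentRegistry:
    """Build a component registry from a taxonomy configuration mapping.

    The configuration lists components with class, optional flavonoid
    subclass, unit, and TAC eligibility.  A configuration declaring
    ``default: true`` is additionally checked against the canonical counts
    (48 components, 41 TAC-eligible, the fixed class/subclass sizes).
    """
    entries = config.get("components") or []
    if not entries:
        raise ValueError("no components")
    components = []
    for entry in entries:
        components.append(
            AntioxidantComponent(
                component_id=entry["component_id"],
                name=entry.get("name", entry["component_id"]),
                unit=entry["unit"],
                antioxidant_class=entry["antioxidant_class"],
                flavonoid_subclass=entry.get("flavonoid_subclass"),
                tac_eligible=bool(entry.get("tac_eligible", True)),
                is_aggregate=bool(entry.get("is_aggregate", False)),
            )
        )
    registry = ComponentRegistry(components)
    if config.get("default"):
        registry.validate_default_counts()
    return registry


def default_registry() -> ComponentRegistry:
    """The canonical 48-component registry."""
    return load_taxonomy(DEFAULT_TAXONOMY)


# ---------------------------------------------------------------------------
# foods


@dataclass(frozen=True)
class FoodItem:
    """One food on the food list, identified by name(s) and form.

    ``attributes`` holds the taxonomy descriptors (genus, family,
    plant_part, color) used for similar-food substitution.
    ``water_content`` is grams of water per 100 g edible portion.
    """

    food_id: str
    names: tuple[str, ...]
    food_group: str
    form: str = "raw"
    water_content: Optional[float] = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"{self.food_id}: at least one name required")
        if self.form not in FORMS:
            raise ValueError(f"{self.food_id}: unknown form {self.form!r}")
        if self.water_content is not None and not (0 <= self.water_content < 100):
            raise ValueError(
                f"{self.food_id}: water_content must lie in [0, 100), "
                f"got {self.water_content}"
            )


@dataclass(frozen=True)
class CompositionCell:
    """One (food, component) value with its provenance label."""

    food_id: str
    component_id: str
    value: Optional[float]
    provenance: str
    source_db: Optional[str] = None


# ---------------------------------------------------------------------------
# composition table


class CompositionTable:
    """Foods x components matrix of per-100 g values with per-cell provenance.

    Internally three aligned DataFrames (values, provenance, source) indexed
    by food_id with one column per component.  Missing values are NaN with
    provenance ``missing``.
    """

    def __init__(self, foods: Sequence[FoodItem], registry: ComponentRegistry):
        ids = [f.food_id for f in foods]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate food_id in food list")
        self.registry = registry
        self.foods: list[FoodItem] = list(foods)
        self._food_index: dict[str, FoodItem] = {f.food_id: f for f in foods}
        cols = registry.component_ids
        self.values = pd.DataFrame(np.nan, index=ids, columns=cols, dtype=float)
        self.provenance = pd.DataFrame(
            Provenance.MISSING.value, index=ids, columns=cols, dtype=object
        )
        self.source = pd.DataFrame(None, index=ids, columns=cols, dtype=object)

    # -- access ------------------------------------------------------------

    @property
    def food_ids(self) -> list[str]:
        return list(self.values.index)

    def food(self, food_id: str) -> FoodItem:
        return self._food_index[food_id]

    def get_cell(self, food_id: str, component_id: str) -> CompositionCell:
        value = self.values.at[food_id, component_id]
        source = self.source.at[food_id, component_id]
        return CompositionCell(
            food_id=food_id,
            component_id=component_id,
            value=None if pd.isna(value) else float(value),
            provenance=str(self.provenance.at[food_id, component_id]),
            source_db=None if pd.isna(source) else str(source),
        )

    def set_cell(
        self,
        food_id: str,
        component_id: str,
        value: Optional[float],
        provenance: str | Provenance,
        source_db: Optional[str] = None,
    ) -> None:
        prov = Provenance(provenance).value
        if value is None:
            if prov != Provenance.MISSING.value:
                raise ValueError("missing value requires provenance 'missing'")
            self.values.at[food_id, component_id] = np.nan
        else:
            self.values.at[food_id, component_id] = float(value)
        self.provenance.at[food_id, component_id] = prov
        self.source.at[food_id, component_id] = source_db if source_db is not None else np.nan

    def values_mg(self) -> pd.DataFrame:
        """Values converted to mg/100 g (the common TAC basis)."""
        out = self.values.copy()
        for comp in self.registry:
            if comp.unit == UG:
                out[comp.component_id] = out[comp.component_id] / 1000.0
        return out

    def copy(self) -> "CompositionTable":
        clone = CompositionTable(self.foods, self.registry)
        clone.values = self.values.copy()
        clone.provenance = self.provenance.copy()
        clone.source = self.source.copy()
        return clone

    # -- interchange ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per (food, component) cell."""
        rows = []
        for fid in self.food_ids:
            for cid in self.registry.component_ids:
                v = self.values.at[fid, cid]
                rows.append(
                    {
                        "food_id": fid,
                        "component_id": cid,
                        "value": np.nan if pd.isna(v) else float(v),
                        "unit": self.registry.unit_of(cid),
                        "provenance": self.provenance.at[fid, cid],
                        "source_db": self.source.at[fid, cid],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    food_id: str
    component_id: str
    kind: str
    detail: str


def validate_table(table: CompositionTable) -> list[Violation]:
    """Report every violated cell invariant; empty list iff the table is valid.

    Checked per cell: non-negative value, provenance label known,
    value-missing <-> provenance-missing consistency, and logical zeros
    actually being zero.
    """
    out: list[Violation] = []
    for fid in table.food_ids:
        for cid in table.registry.component_ids:
            v = table.values.at[fid, cid]
            prov = table.provenance.at[fid, cid]
            missing = pd.isna(v)
            if prov not in PROVENANCE_VALUES:
                out.append(Violation(fid, cid, "unknown_provenance", str(prov)))
                continue
            if missing != (prov == Provenance.MISSING.value):
                out.append(
                    Violation(
                        fid, cid, "provenance_inconsistency",
                        f"value={'missing' if missing else v} but provenance={prov}",
                    )
                )
            if not missing and v < 0:
                out.append(Violation(fid, cid, "negative_value", f"value={v}"))
            if prov == Provenance.LOGICAL_ZERO.value and not missing and v != 0:
                out.append(
                    Violation(fid, cid, "provenance_inconsistency",
                              f"logical_zero with value={v}")
                )
    return out


# ---------------------------------------------------------------------------
# delimited-text interchange

_ATTR_COLS = list(SIMILARITY_ATTRIBUTES)


def write_foods_csv(foods: Sequence[FoodItem], path) -> None:
    rows = []
    for f in foods:
        row = {
            "food_id": f.food_id,
            "names": "|".join(f.names),
            "food_group": f.food_group,
            "form": f.form,
            "water_content": f.water_content,
        }
        for a in _ATTR_COLS:
            row[a] = f.attributes.get(a)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_foods_csv(path) -> list[FoodItem]:
    df = pd.read_csv(path, dtype={"food_id": str, "names": str})
    foods = []
    for row in df.itertuples(index=False):
        attrs = {
            a: getattr(row, a)
            for a in _ATTR_COLS
            if a in df.columns and isinstance(getattr(row, a), str)
        }
        wc = row.water_content
        foods.append(
            FoodItem(
                food_id=row.food_id,
                names=tuple(str(row.names).split("|")),
                food_group=row.food_group,
                form=row.form,
                water_content=None if pd.isna(wc) else float(wc),
                attributes=attrs,
            )
        )
    return foods


def write_table_csv(table: CompositionTable, path) -> None:
    """One row per (food, component): food_id, component_id, value, unit,
    provenance, source_db; missing values encoded as empty fields."""
    table.to_frame().to_csv(path, index=False)


def read_table_csv(path, foods: Sequence[FoodItem], registry: ComponentRegistry) -> CompositionTable:
    df = pd.read_csv(path, dtype={"food_id": str, "component_id": str, "source_db": str})
    table = CompositionTable(foods, registry)
    for row in df.itertuples(index=False):
        if row.component_id not in registry:
            raise ValueError(f"unknown component in table: {row.component_id}")
        if row.unit != registry.unit_of(row.component_id):
            raise ValueError(
                f"unit mismatch for {row.component_id}: file says {row.unit}, "
                f"registry says {registry.unit_of(row.component_id)}"
            )
        missing = pd.isna(row.value)
        source = row.source_db if isinstance(row.source_db, str) else None
        table.set_cell(
            row.food_id,
            row.component_id,
            None if missing else float(row.value),
            row.provenance,
            source,
        )
    return table
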