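"""Synthetic inputs with the statistical structure the pipeline assumes.

Real source food-composition databases and cohort FFQ responses are not
redistributable, so every pipeline stage is exercised on generated inputs:
overlapping prioritized source databases with component-specific
missingness, foods in raw and dried forms linked by the exact moisture
formula, prepared dishes with recipes, glycoside-basis records paired with
a molecular-weight table, a VCEAC table, an FFQ design, and cohorts of
responses with planted exclusion-rule violators.

Defaults mirror the study conditions: 412 foods, 106 FFQ items, three
vitamins-lane and four flavonoid-lane sources in the canonical priority
order, 9 frequency categories, seasonal durations of 3/6/9/12 months, and a
log-normal daily energy distribution with mean 1,678 and SD 516 kcal.

Ground-truth intake profiles are computed by a deliberately naive
re-summation over the built composition table — an independent code path
from the vectorized scorer — so the two can be compared as a dual-path
oracle.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .construction import (
    DEFAULT_LANES,
    MolecularWeightEntry,
    Recipe,
    SourceDatabase,
    SourceRecord,
)
from .ffq import (
    FfqDesign,
    FfqItem,
    FfqResponse,
    FrequencyMap,
    IntakeProfile,
    ItemAnswer,
)
from .tac import VceacTable
from .taxonomy import (
    MG,
    UG,
    ComponentRegistry,
    CompositionTable,
    FoodItem,
    default_registry,
)

PLANT_GROUPS = (
    "Vegetables",
    "Fruits",
    "Cereals and grains",
    "Legumes and their products",
    "Potatoes and starches",
    "Mushrooms",
    "Seaweeds",
    "Seasonings",
)
ANIMAL_GROUPS_POOL = (
    "Meats and their products",
    "Fish and shellfish",
    "Eggs",
    "Milk and dairy products",
    "Fats and oils",
)
BEVERAGE_GROUP = "Beverages and drinks"
DISH_GROUP = "Prepared dishes"

PLANT_PARTS = ("leaf", "stem", "root", "fruit", "seed")
COLORS = ("red", "green", "yellow", "white", "purple", "orange")

TEA_COMPONENT_IDS = (
    "theaflavin",
    "thearubigin",
    "theaflavin_3_gallate",
    "theaflavin_3p_gallate",
    "theaflavin_33p_digallate",
)

#: public molecular weights (g/mol) for glycoside -> aglycone conversion
DEFAULT_MW_TABLE = (
    MolecularWeightEntry("quercetin-3-O-glucoside", "quercetin", 464.38, 302.24),
    MolecularWeightEntry("kaempferol-3-O-glucoside", "kaempferol", 448.38, 286.24),
    MolecularWeightEntry("myricetin-3-O-glucoside", "myricetin", 480.38, 318.24),
    MolecularWeightEntry("luteolin-7-O-glucoside", "luteolin", 448.38, 286.24),
    MolecularWeightEntry("cyanidin-3-O-glucoside", "cyanidin", 449.39, 287.24),
)
_GLYCOSIDE_OF = {e.aglycone_component_id: e for e in DEFAULT_MW_TABLE}

#: typical per-100 g scale (median of the log-normal) for truth values, by class
_CLASS_SCALE = {
    "retinol": 40.0,        # ug, animal foods
    "vitamin_C": 20.0,      # mg
    "vitamin_E": 1.0,       # mg
    "carotenoids": 300.0,   # ug
    "flavonoids": 3.0,      # mg
}

#: per-source missingness probability by class (flavonoid sources are far
#: sparser than the vitamin sources, as in the real databases)
_DEFAULT_MISSINGNESS = {
    "retinol": 0.02,
    "vitamin_C": 0.02,
    "vitamin_E": 0.05,
    "carotenoids": 0.10,
    "flavonoids": 0.45,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory."""

    seed: int
    n_foods: int = 412
    n_items: int = 106
    n_participants: int = 5000
    n_recipes: int = 40
    ingredients_per_recipe: tuple[int, int] = (2, 5)
    animal_fraction: float = 0.25
    dried_fraction: float = 0.08
    unmatched_fraction: float = 0.05
    variety_fraction: float = 0.05
    missingness: Optional[Mapping[str, float]] = None
    seasonal_fraction: float = 0.15
    frequency_probs: tuple[float, ...] = (
        0.55, 0.15, 0.10, 0.08, 0.05, 0.03, 0.025, 0.01, 0.005,
    )
    item_missing_prob: float = 0.005
    missing_violator_fraction: float = 0.0
    energy_outlier_fraction: float = 0.0
    energy_lognorm_mu: float = 7.3802   # mean 1,678 kcal/day
    energy_lognorm_sigma: float = 0.3006  # SD 516 kcal/day

    def __post_init__(self) -> None:
        for name in (
            "animal_fraction", "dried_fraction", "unmatched_fraction",
            "variety_fraction", "seasonal_fraction", "item_missing_prob",
            "missing_violator_fraction", "energy_outlier_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if len(self.frequency_probs) != 9 or abs(sum(self.frequency_probs) - 1) > 1e-9:
            raise ValueError("frequency_probs must be 9 probabilities summing to 1")
        for name in ("n_foods", "n_items", "n_participants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_recipes + int(self.dried_fraction * self.n_foods) >= self.n_foods:
            raise ValueError("n_foods too small for the requested recipes/dried forms")

    def missingness_for(self, registry: ComponentRegistry, component_id: str) -> float:
        if self.missingness is not None and component_id in self.missingness:
            return self.missingness[component_id]
        return _DEFAULT_MISSINGNESS[registry.get(component_id).antioxidant_class]


def canned_config(name: str, seed: int) -> SimulationConfig:
    """Versioned scenarios: 'tiny' (fast unit-scale), 'table2-like'
    (study-scale food list), 'cohort-5k' (study-scale with 5,000
    participants)."""
    if name == "tiny":
        return SimulationConfig(
            seed=seed, n_foods=20, n_items=8, n_participants=30, n_recipes=3,
            ingredients_per_recipe=(2, 3), dried_fraction=0.1,
            unmatched_fraction=0.1, variety_fraction=0.1,
        )
    if name == "table2-like":
        return SimulationConfig(seed=seed, n_participants=200)
    if name == "cohort-5k":
        return SimulationConfig(seed=seed, n_participants=5000)
    raise ValueError(f"unknown scenario: {name}")


@dataclass
class SyntheticSources:
    """Generated source databases plus the hidden ground-truth composition."""

    foods: list[FoodItem]
    recipes: list[Recipe]
    sources: dict[str, SourceDatabase]
    truth: "np.ndarray"
    truth_index: list[str]
    truth_columns: list[str]
    mw_table: tuple[MolecularWeightEntry, ...]
    config: SimulationConfig

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(self.truth, index=self.truth_index, columns=self.truth_columns)


@dataclass
class SyntheticCohort:
    responses: list[FfqResponse]
    truth_profiles: Optional[list[IntakeProfile]]
    planted_missing_ids: list[str]
    planted_outlier_ids: list[str]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# sources


def gen_sources(
    config: SimulationConfig, registry: ComponentRegistry | None = None
) -> SyntheticSources:
    """Generate the food list, recipes, source databases, and ground truth.

    Every provenance pathway is reachable: direct matches and variety
    averages (records present in sources), moisture conversion (dried foods
    whose raw form alone is recorded), recipes (prepared dishes), similar
    foods (foods absent from all sources but sharing a genus with a recorded
    one), and logical zeros (animal-based groups and non-beverage foods for
    tea compounds).
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)

    n_dishes = config.n_recipes
    n_dried = int(config.dried_fraction * config.n_foods)
    n_base = config.n_foods - n_dishes - n_dried
    n_animal = int(config.animal_fraction * n_base)
    n_plant = n_base - n_animal
    if n_plant < 4:
        raise ValueError("config leaves too few plant foods")

    genus_pool = [f"genus_{i:03d}" for i in range(max(3, n_plant // 3))]
    family_pool = [f"family_{i:02d}" for i in range(max(2, n_plant // 8))]

    foods: list[FoodItem] = []
    for i in range(n_plant):
        # the first two plant foods are tea beverages so the tea pathway
        # exists; beverages carry no botanical attributes, so they never act
        # as similar-food donors (tea compounds must not leak into produce)
        group = BEVERAGE_GROUP if i < 2 else str(rng.choice(PLANT_GROUPS))
        attributes = (
            {}
            if group == BEVERAGE_GROUP
            else {
                "genus": str(rng.choice(genus_pool)),
                "family": str(rng.choice(family_pool)),
                "plant_part": str(rng.choice(PLANT_PARTS)),
                "color": str(rng.choice(COLORS)),
            }
        )
        foods.append(
            FoodItem(
                food_id=f"food_{i:04d}",
                names=(f"synthfood {i:04d}",),
                food_group=group,
                form="raw",
                water_content=float(rng.uniform(60, 95)),
                attributes=attributes,
            )
        )
    for j in range(n_animal):
        i = n_plant + j
        foods.append(
            FoodItem(
                food_id=f"food_{i:04d}",
                names=(f"synthfood {i:04d}",),
                food_group=str(rng.choice(ANIMAL_GROUPS_POOL)),
                form="raw",
                water_content=float(rng.uniform(40, 80)),
                attributes={},
            )
        )

    plant_foods = foods[:n_plant]
    animal_foods = foods[n_plant:]

    # foods absent from every source: values only reachable via a donor
    # sharing the same genus
    n_unmatched = int(config.unmatched_fraction * n_plant)
    unmatched_ids = {f.food_id for f in plant_foods[2 : 2 + n_unmatched]}
    matched_plant = [f for f in plant_foods if f.food_id not in unmatched_ids]
    # guarantee a same-genus donor for each unmatched food
    for k, fid in enumerate(sorted(unmatched_ids)):
        donor = matched_plant[2 + (k % max(1, len(matched_plant) - 2))]
        idx = next(i for i, f in enumerate(foods) if f.food_id == fid)
        attrs = dict(foods[idx].attributes)
        attrs["genus"] = donor.attributes.get("genus", attrs.get("genus", ""))
        foods[idx] = FoodItem(
            food_id=foods[idx].food_id,
            names=foods[idx].names,
            food_group=foods[idx].food_group,
            form=foods[idx].form,
            water_content=foods[idx].water_content,
            attributes=attrs,
        )
    plant_foods = foods[:n_plant]

    # ground truth per (food, component), complete for base foods
    cols = registry.component_ids
    col_pos = {cid: k for k, cid in enumerate(cols)}
    truth_rows: dict[str, np.ndarray] = {}
    for f in foods:
        row = np.zeros(len(cols))
        for comp in registry:
            cid = comp.component_id
            cls = comp.antioxidant_class
            scale = _CLASS_SCALE[cls]
            value = float(rng.lognormal(np.log(scale), 0.8))
            if cls == "retinol":
                row[col_pos[cid]] = value if f.food_group in ANIMAL_GROUPS_POOL else 0.0
            elif cls in ("carotenoids", "flavonoids"):
                if f.food_group in ANIMAL_GROUPS_POOL:
                    row[col_pos[cid]] = 0.0
                elif cid in TEA_COMPONENT_IDS:
                    row[col_pos[cid]] = value if f.food_group == BEVERAGE_GROUP else 0.0
                else:
                    row[col_pos[cid]] = value
            else:  # vitamins C and E occur everywhere
                row[col_pos[cid]] = value
        # the aggregate column summarises the individual isoflavones
        if "total_isoflavones" in col_pos:
            row[col_pos["total_isoflavones"]] = (
                row[col_pos["daidzein"]]
                + row[col_pos["genistein"]]
                + row[col_pos["glycitein"]]
            )
        truth_rows[f.food_id] = row

    # dried variants of matched plant foods: truth by the exact moisture
    # formula; sources record only the raw form
    dried_sources = rng.choice(
        [f.food_id for f in matched_plant[2:]], size=min(n_dried, len(matched_plant) - 2),
        replace=False,
    )
    dried_foods: list[FoodItem] = []
    for k, raw_id in enumerate(sorted(dried_sources)):
        raw = next(f for f in foods if f.food_id == raw_id)
        i = n_base + k
        water_dried = float(rng.uniform(5, 15))
        dried = FoodItem(
            food_id=f"food_{i:04d}",
            names=raw.names,
            food_group=raw.food_group,
            form="dried",
            water_content=water_dried,
            attributes=dict(raw.attributes),
        )
        factor = (100.0 - water_dried) / (100.0 - raw.water_content)
        truth_rows[dried.food_id] = truth_rows[raw_id] * factor
        dried_foods.append(dried)
    foods = foods + dried_foods

    # prepared dishes with recipes over matched base foods
    # dishes draw on matched plant and animal foods; tea beverages are not
    # recipe ingredients, so dish tea-compound content is genuinely zero
    ingredient_pool = [
        f.food_id for f in matched_plant if f.food_group != BEVERAGE_GROUP
    ] + [f.food_id for f in animal_foods]
    recipes: list[Recipe] = []
    lo, hi = config.ingredients_per_recipe
    for k in range(n_dishes):
        i = n_base + len(dried_foods) + k
        n_ing = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(ingredient_pool, size=min(n_ing, len(ingredient_pool)), replace=False)
        ingredients = tuple(
            (str(fid), float(rng.uniform(20, 150))) for fid in chosen
        )
        dish = FoodItem(
            food_id=f"food_{i:04d}",
            names=(f"synthdish {k:03d}",),
            food_group=DISH_GROUP,
            form="prepared",
            water_content=None,
            attributes={},
        )
        recipes.append(Recipe(dish_id=dish.food_id, ingredients=ingredients))
        total = sum(g for _, g in ingredients)
        truth_rows[dish.food_id] = (
            sum(truth_rows[fid] * g for fid, g in ingredients) / total
        )
        foods.append(dish)

    # observed source databases: values equal truth, with per-source
    # component-specific missingness; flavonoid sources cover their own
    # subclass families, Phenol-Explorer reports glycoside-basis records
    recordable = [f for f in matched_plant] + animal_foods
    source_specs: list[tuple[str, set[str]]] = []
    vit_ids = {
        c.component_id for c in registry if c.antioxidant_class != "flavonoids"
    }
    flav_ids = {
        c.component_id for c in registry if c.antioxidant_class == "flavonoids"
    }
    iso_ids = {c.component_id for c in registry if c.flavonoid_subclass == "isoflavones"}
    pa_ids = {
        c.component_id for c in registry if c.flavonoid_subclass == "proanthocyanidins"
    }
    source_specs.append(("KMFDS", vit_ids))
    source_specs.append(("USDA_SR28", vit_ids))
    source_specs.append(("JMEXT", vit_ids))
    source_specs.append(("USDA_flavonoid", flav_ids - iso_ids - pa_ids))
    source_specs.append(("USDA_isoflavone", iso_ids))
    source_specs.append(("USDA_proanthocyanidin", pa_ids))
    source_specs.append(("PhenolExplorer", flav_ids))

    sources: dict[str, SourceDatabase] = {}
    for sid, covered in source_specs:
        records: list[SourceRecord] = []
        for f in recordable:
            # animal foods: no carotenoid/flavonoid records (logical-zero path)
            for cid in cols:
                if cid not in covered:
                    continue
                comp = registry.get(cid)
                if f.food_group in ANIMAL_GROUPS_POOL and comp.antioxidant_class in (
                    "carotenoids",
                    "flavonoids",
                ):
                    continue
                if cid in TEA_COMPONENT_IDS and f.food_group != BEVERAGE_GROUP:
                    continue
                if rng.random() < config.missingness_for(registry, cid):
                    continue
                value = float(truth_rows[f.food_id][col_pos[cid]])
                basis, glyco = "aglycone", None
                if sid == "PhenolExplorer" and cid in _GLYCOSIDE_OF:
                    entry = _GLYCOSIDE_OF[cid]
                    value = value * entry.mw_glycoside / entry.mw_aglycone
                    basis, glyco = "glycoside", entry.glycoside_name
                if sid == "KMFDS" and rng.random() < config.variety_fraction:
                    for mult in (0.9, 1.1):  # two varieties averaging to truth
                        records.append(
                            SourceRecord(
                                name=f.names[0], form=f.form, component_id=cid,
                                value=value * mult, water_content=f.water_content,
                                basis=basis, glycoside=glyco,
                            )
                        )
                else:
                    records.append(
                        SourceRecord(
                            name=f.names[0], form=f.form, component_id=cid,
                            value=value, water_content=f.water_content,
                            basis=basis, glycoside=glyco,
                        )
                    )
        sources[sid] = SourceDatabase(sid, records)

    food_ids = [f.food_id for f in foods]
    truth = np.vstack([truth_rows[fid] for fid in food_ids])
    return SyntheticSources(
        foods=foods,
        recipes=recipes,
        sources=sources,
        truth=truth,
        truth_index=food_ids,
        truth_columns=list(cols),
        mw_table=DEFAULT_MW_TABLE,
        config=config,
    )


def gen_vceac(registry: ComponentRegistry, seed: int) -> VceacTable:
    """Synthetic VCEAC table: vitamin C fixed at 1.0, other eligible
    components log-normal around 1 mg VCE/mg."""
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for cid in registry.tac_eligible_ids():
        values[cid] = 1.0 if cid == "vitamin_c" else float(rng.lognormal(0.0, 0.4))
    return VceacTable(values)


# ---------------------------------------------------------------------------
# FFQ design and cohort


def gen_design(
    config: SimulationConfig, foods: Sequence[FoodItem]
) -> FfqDesign:
    """Generate an FFQ design whose item recipes draw on the food list."""
    rng = np.random.default_rng(config.seed + 1)
    food_ids = [f.food_id for f in foods]
    items = []
    for i in range(config.n_items):
        n_foods = int(rng.integers(1, 4))
        chosen = rng.choice(food_ids, size=n_foods, replace=False)
        recipe = tuple((str(fid), float(rng.uniform(30, 150))) for fid in chosen)
        ref = sum(g for _, g in recipe)
        n_portions = int(rng.integers(3, 5))
        multipliers = (0.5, 1.0, 1.5, 2.0)[:n_portions]
        items.append(
            FfqItem(
                item_id=i + 1,
                portion_options=tuple(round(ref * m, 1) for m in multipliers),
                item_recipe=recipe,
                seasonal=bool(rng.random() < config.seasonal_fraction),
                energy_kcal_per_100g=float(rng.uniform(15, 80)),
            )
        )
    return FfqDesign(items=tuple(items), frequency_map=FrequencyMap())


def _naive_profile(
    response: FfqResponse,
    design: FfqDesign,
    table: CompositionTable,
    vceac: VceacTable,
    registry: ComponentRegistry,
) -> IntakeProfile:
    """Ground-truth scoring by plain re-summation.

    Deliberately naive and independent of the vectorized scorer: per-item
    loops, explicit unit conversion, explicit class sums.
    """
    import math

    values = {
        fid: {
            cid: (None if math.isnan(v) else float(v))
            for cid, v in zip(table.registry.component_ids, table.values.loc[fid])
        }
        for fid in table.food_ids
    }
    intakes = {cid: 0.0 for cid in registry.component_ids}
    energy = 0.0
    n_missing_items = 0
    for item in design.items:
        answer = response.answers.get(item.item_id)
        if answer is None or answer.frequency is None:
            n_missing_items += 1
            continue
        freq = design.frequency_map.times_per_day[answer.frequency]
        portion_grams = item.portion_options[answer.portion]
        ref = sum(g for _, g in item.item_recipe)
        duration = 1.0
        if item.seasonal:
            months = answer.season_months if answer.season_months else 12
            duration = months / 12.0
        for fid, grams in item.item_recipe:
            grams_in_portion = grams * portion_grams / ref
            for cid in registry.component_ids:
                v = values[fid][cid]
                if v is None:
                    continue
                intakes[cid] += freq * grams_in_portion * v / 100.0 * duration
        energy += freq * portion_grams * item.energy_kcal_per_100g / 100.0 * duration

    subclass_totals: dict[str, float] = {}
    class_totals: dict[str, float] = {}
    for comp in registry:
        if comp.is_aggregate:
            continue
        v = intakes[comp.component_id]
        v_mg = v / 1000.0 if comp.unit == UG else v
        if comp.flavonoid_subclass is not None:
            subclass_totals[comp.flavonoid_subclass] = (
                subclass_totals.get(comp.flavonoid_subclass, 0.0) + v_mg
            )
        else:
            unit = UG if comp.antioxidant_class == "retinol" else MG
            v_cls = v if unit == comp.unit else v_mg
            class_totals[comp.antioxidant_class] = (
                class_totals.get(comp.antioxidant_class, 0.0) + v_cls
            )
    class_totals["flavonoids"] = sum(subclass_totals.values())

    dtac = 0.0
    for comp in registry:
        if not comp.tac_eligible:
            continue
        v = intakes[comp.component_id]
        v_mg = v / 1000.0 if comp.unit == UG else v
        dtac += v_mg * vceac[comp.component_id]

    return IntakeProfile(
        participant_id=response.participant_id,
        component_intakes=intakes,
        class_totals=class_totals,
        subclass_totals=subclass_totals,
        dtac_mg_vce=dtac,
        energy_kcal=energy,
        n_missing_items=n_missing_items,
    )


def gen_cohort(
    config: SimulationConfig,
    design: FfqDesign,
    table: CompositionTable,
    vceac: VceacTable,
    registry: ComponentRegistry | None = None,
    n_participants: Optional[int] = None,
    compute_truth: bool = True,
) -> SyntheticCohort:
    """Sample FFQ responses and (optionally) naive ground-truth profiles.

    Plants ``missing_violator_fraction`` participants with more than 10
    missing items and ``energy_outlier_fraction`` with maximal responses
    (high-energy outliers); their ids are reported so exclusion audits can
    be checked against the plan.
    """
    registry = registry or table.registry
    rng = np.random.default_rng(config.seed + 2)
    n = n_participants if n_participants is not None else config.n_participants
    n_items = len(design.items)
    ids = [f"participant_{i:06d}" for i in range(n)]

    n_miss = int(config.missing_violator_fraction * n)
    n_out = int(config.energy_outlier_fraction * n)
    special = rng.choice(n, size=min(n, n_miss + n_out), replace=False)
    missing_idx = set(special[:n_miss].tolist())
    outlier_idx = set(special[n_miss : n_miss + n_out].tolist())

    responses: list[FfqResponse] = []
    for p in range(n):
        answers: dict[int, ItemAnswer] = {}
        freqs = rng.choice(9, size=n_items, p=config.frequency_probs)
        missing_mask = rng.random(n_items) < config.item_missing_prob
        if p in missing_idx:
            k = int(rng.integers(11, min(21, n_items + 1)))
            forced = rng.choice(n_items, size=k, replace=False)
            missing_mask = missing_mask.copy()
            missing_mask[forced] = True
        for j, item in enumerate(design.items):
            if missing_mask[j]:
                answers[item.item_id] = ItemAnswer(frequency=None)
                continue
            freq = 8 if p in outlier_idx else int(freqs[j])
            portion = (
                len(item.portion_options) - 1
                if p in outlier_idx
                else int(rng.integers(0, len(item.portion_options)))
            )
            season = None
            if item.seasonal:
                season = int(rng.choice((3, 6, 9, 12)))
            answers[item.item_id] = ItemAnswer(
                frequency=freq, portion=portion, season_months=season
            )
        responses.append(FfqResponse(participant_id=ids[p], answers=answers))

    truth_profiles = None
    if compute_truth:
        truth_profiles = [
            _naive_profile(r, design, table, vceac, registry) for r in responses
        ]
    return SyntheticCohort(
        responses=responses,
        truth_profiles=truth_profiles,
        planted_missing_ids=[ids[i] for i in sorted(missing_idx)],
        planted_outlier_ids=[ids[i] for i in sorted(outlier_idx)],
        config=config,
    )


def gen_energy_sample(config: SimulationConfig, n: int, seed_offset: int = 3) -> np.ndarray:
    """Continuous log-normal daily energy intakes (kcal/day)."""
    rng = np.random.default_rng(config.seed + seed_offset)
    return rng.lognormal(config.energy_lognorm_mu, config.energy_lognorm_sigma, n)


def config_metadata(config: SimulationConfig) -> dict:
    """Echo of the configuration for output metadata."""
    return asdict(config)
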