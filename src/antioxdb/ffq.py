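"""FFQ scoring: responses -> daily intakes, class aggregates, dTAC, energy.

The semiquantitative FFQ has 106 items; each item carries 3-4 portion-size
options in grams, a recipe mapping the item to foods in the composition
table (grams per reference portion), and an optional seasonal flag.  A
response gives, per item, one of 9 frequency categories (from "never or
rarely" = 0 times/day up to 3 times/day), a portion category, and — for
seasonal items — a consumption duration of 3, 6, 9 or 12 months.

Daily intake of a component from one item is

    frequency/day x sum over recipe foods of
        (grams of the food in the chosen portion x amount per 100 g / 100)
    x seasonal factor (months / 12; 1 for non-seasonal items),

summed over items.  Energy flows through the same arithmetic using the
per-item energy density.  Missing composition values contribute zero (and
are counted); items with a missing frequency contribute zero and count
toward the missing-item exclusion rule.

The cohort exclusion filter removes participants with energy intake below
the 0.5th or above the 95.5th percentile of the input cohort (linear
interpolation between order statistics; strict comparisons) or with more
than 10 missing items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .tac import VceacTable, diet_tac
from .taxonomy import (
    MG,
    UG,
    ComponentRegistry,
    CompositionTable,
    convert_units,
)

SEASONAL_MONTHS = (3, 6, 9, 12)

#: the unit each antioxidant class total is expressed in (the printed units)
CLASS_UNITS = {
    "retinol": UG,
    "carotenoids": MG,
    "vitamin_C": MG,
    "vitamin_E": MG,
    "flavonoids": MG,
}

#: default frequency-to-times/day map for the 9 categories; design files may
#: override but must state their own
DEFAULT_FREQUENCY_LABELS = (
    "never_or_rarely",
    "once_per_month",
    "2_3_per_month",
    "1_2_per_week",
    "3_4_per_week",
    "5_6_per_week",
    "once_per_day",
    "twice_per_day",
    "3_per_day",
)
DEFAULT_FREQUENCY_TIMES = (0.0, 0.0329, 0.0822, 0.2143, 0.5, 0.7857, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FrequencyMap:
    """Ordered frequency categories and their times-per-day equivalents."""

    labels: tuple[str, ...] = DEFAULT_FREQUENCY_LABELS
    times_per_day: tuple[float, ...] = DEFAULT_FREQUENCY_TIMES

    def __post_init__(self) -> None:
        if len(self.labels) != 9 or len(self.times_per_day) != 9:
            raise ValueError("frequency map must have exactly 9 categories")
        if self.times_per_day[0] != 0.0:
            raise ValueError("first category must map to 0 (never or rarely)")
        if self.times_per_day[-1] != 3.0:
            raise ValueError("last category must map to 3 times per day")
        if any(b < a for a, b in zip(self.times_per_day, self.times_per_day[1:])):
            raise ValueError("times per day must be non-decreasing")


@dataclass(frozen=True)
class FfqItem:
    """One FFQ item: portion options, seasonality, and its food recipe."""

    item_id: int
    portion_options: tuple[float, ...]
    item_recipe: tuple[tuple[str, float], ...]
    seasonal: bool = False
    energy_kcal_per_100g: float = 0.0

    def __post_init__(self) -> None:
        if not 3 <= len(self.portion_options) <= 4:
            raise ValueError(f"item {self.item_id}: 3 or 4 portion options required")
        if any(g <= 0 for g in self.portion_options):
            raise ValueError(f"item {self.item_id}: portion options must be positive")
        if any(b <= a for a, b in zip(self.portion_options, self.portion_options[1:])):
            raise ValueError(f"item {self.item_id}: portion options must increase")
        if not self.item_recipe:
            raise ValueError(f"item {self.item_id}: item recipe must be non-empty")

    @property
    def reference_grams(self) -> float:
        return sum(g for _, g in self.item_recipe)


@dataclass(frozen=True)
class FfqDesign:
    items: tuple[FfqItem, ...]
    frequency_map: FrequencyMap = FrequencyMap()

    def __post_init__(self) -> None:
        ids = [i.item_id for i in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in design")

    def item(self, item_id: int) -> FfqItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item: {item_id}")


@dataclass(frozen=True)
class ItemAnswer:
    """One participant's answer to one item; frequency None = item missing."""

    frequency: Optional[int]
    portion: int = 0
    season_months: Optional[int] = None


@dataclass(frozen=True)
class FfqResponse:
    participant_id: str
    answers: Mapping[int, ItemAnswer]


@dataclass
class IntakeProfile:
    """Per-participant daily intakes and aggregates.

    Component intakes are in each component's registry unit per day; class
    totals are in the class's printed unit (retinol ug/day, all others
    mg/day); subclass totals in mg/day.  The flavonoid class total equals
    the sum of the seven subclass totals exactly.
    """

    participant_id: str
    component_intakes: dict[str, float]
    class_totals: dict[str, float]
    subclass_totals: dict[str, float]
    dtac_mg_vce: float
    energy_kcal: float
    n_missing_items: int
    missing_contributors: dict[str, int] = field(default_factory=dict)


def seasonal_factor(months: int) -> float:
    """Fraction of the year a seasonal food is consumed."""
    if months not in SEASONAL_MONTHS:
        raise ValueError(f"seasonal duration must be one of {SEASONAL_MONTHS}, got {months}")
    return months / 12.0


def aggregate_intakes(
    component_intakes: Mapping[str, float], registry: ComponentRegistry
) -> tuple[dict[str, float], dict[str, float]]:
    """Class and subclass totals from per-component intakes (registry units).

    Aggregate pseudo-components (total isoflavones) are excluded so members
    are not double counted.  The flavonoid class total is computed as the
    sum of the seven subclass totals.
    """
    subclass_totals: dict[str, float] = {}
    class_totals: dict[str, float] = {}
    for comp in registry:
        if comp.is_aggregate:
            continue
        v = component_intakes.get(comp.component_id, 0.0)
        if comp.flavonoid_subclass is not None:
            sub = comp.flavonoid_subclass
            subclass_totals[sub] = subclass_totals.get(sub, 0.0) + convert_units(
                v, comp.unit, MG
            )
        cls = comp.antioxidant_class
        if cls != "flavonoids":
            class_totals[cls] = class_totals.get(cls, 0.0) + convert_units(
                v, comp.unit, CLASS_UNITS[cls]
            )
    class_totals["flavonoids"] = sum(subclass_totals.values())
    return class_totals, subclass_totals


# ---------------------------------------------------------------------------
# scoring


def item_component_intake(
    answer: Optional[ItemAnswer],
    item: FfqItem,
    table: CompositionTable,
    component_id: str,
    freq_map: FrequencyMap = FrequencyMap(),
) -> tuple[float, int]:
    """Daily intake of one component from one item, in the registry unit.

    Returns (amount/day, number of recipe foods with a missing composition
    value — these contribute zero).
    """
    if answer is None or answer.frequency is None:
        return 0.0, 0
    freq = freq_map.times_per_day[answer.frequency]
    if answer.portion >= len(item.portion_options):
        raise ValueError(
            f"item {item.item_id}: portion category {answer.portion} out of range"
        )
    portion_grams = item.portion_options[answer.portion]
    scale = portion_grams / item.reference_grams
    season = 1.0
    if item.seasonal:
        season = seasonal_factor(answer.season_months if answer.season_months else 12)
    total = 0.0
    n_missing = 0
    for fid, grams in item.item_recipe:
        v = table.values.at[fid, component_id]
        if pd.isna(v):
            n_missing += 1
            continue
        total += grams * scale * float(v) / 100.0
    return freq * total * season, n_missing


class ScoringContext:
    """Precomputed (item, portion) -> component vectors for fast scoring.

    Built once per (design, table) pair; amounts are in registry units per
    chosen portion.
    """

    def __init__(self, design: FfqDesign, table: CompositionTable):
        self.design = design
        registry = table.registry
        self.component_ids = registry.component_ids
        n_items = len(design.items)
        max_p = max(len(it.portion_options) for it in design.items)
        n_comp = len(self.component_ids)
        self.portion_amounts = np.zeros((n_items, max_p, n_comp))
        self.portion_energy = np.zeros((n_items, max_p))
        self.n_portions = np.array([len(it.portion_options) for it in design.items])
        self.seasonal = np.array([it.seasonal for it in design.items])
        self.missing_foods = np.zeros((n_items, n_comp), dtype=int)
        self.item_index = {it.item_id: i for i, it in enumerate(design.items)}
        values = table.values.to_numpy()
        food_pos = {fid: i for i, fid in enumerate(table.food_ids)}
        for i, it in enumerate(design.items):
            ref = it.reference_grams
            per_ref = np.zeros(n_comp)
            for fid, grams in it.item_recipe:
                row = values[food_pos[fid]]
                miss = np.isnan(row)
                self.missing_foods[i] += miss.astype(int)
                per_ref += np.where(miss, 0.0, row) * grams / 100.0
            for p, portion_grams in enumerate(it.portion_options):
                self.portion_amounts[i, p] = per_ref * portion_grams / ref
                self.portion_energy[i, p] = (
                    portion_grams * it.energy_kcal_per_100g / 100.0
                )


def score_participant(
    response: FfqResponse,
    design: FfqDesign,
    table: CompositionTable,
    vceac: VceacTable,
    registry: ComponentRegistry | None = None,
    context: ScoringContext | None = None,
) -> IntakeProfile:
    """Score one participant's FFQ response into an IntakeProfile."""
    registry = registry or table.registry
    ctx = context or ScoringContext(design, table)
    fmap = design.frequency_map
    n_comp = len(ctx.component_ids)
    intake = np.zeros(n_comp)
    missing_contrib = np.zeros(n_comp, dtype=int)
    energy = 0.0
    n_missing_items = 0
    unknown = set(response.answers) - set(ctx.item_index)
    if unknown:
        raise KeyError(f"response references unknown items: {sorted(unknown)}")
    for item in design.items:
        i = ctx.item_index[item.item_id]
        answer = response.answers.get(item.item_id)
        if answer is None or answer.frequency is None:
            n_missing_items += 1
            continue
        freq = fmap.times_per_day[answer.frequency]
        if answer.portion >= ctx.n_portions[i]:
            raise ValueError(
                f"item {item.item_id}: portion category {answer.portion} out of range"
            )
        season = 1.0
        if item.seasonal:
            season = seasonal_factor(answer.season_months if answer.season_months else 12)
        w = freq * season
        intake += w * ctx.portion_amounts[i, answer.portion]
        energy += w * ctx.portion_energy[i, answer.portion]
        if freq > 0:
            missing_contrib += ctx.missing_foods[i]

    component_intakes = dict(zip(ctx.component_ids, intake.tolist()))
    class_totals, subclass_totals = aggregate_intakes(component_intakes, registry)
    intakes_mg = {
        cid: convert_units(v, registry.unit_of(cid), MG)
        for cid, v in component_intakes.items()
    }
    dtac = diet_tac(intakes_mg, vceac, registry)
    return IntakeProfile(
        participant_id=response.participant_id,
        component_intakes=component_intakes,
        class_totals=class_totals,
        subclass_totals=subclass_totals,
        dtac_mg_vce=dtac,
        energy_kcal=energy,
        n_missing_items=n_missing_items,
        missing_contributors={
            cid: int(n)
            for cid, n in zip(ctx.component_ids, missing_contrib)
            if n > 0
        },
    )


def score_cohort(
    responses: Sequence[FfqResponse],
    design: FfqDesign,
    table: CompositionTable,
    vceac: VceacTable,
    registry: ComponentRegistry | None = None,
    collect_contributions: bool = False,
) -> tuple[list[IntakeProfile], Optional[pd.DataFrame]]:
    """Score a cohort; optionally accumulate cohort-summed per-food
    contributions (foods x components, registry units x person-days)."""
    registry = registry or table.registry
    ctx = ScoringContext(design, table)
    profiles = [
        score_participant(r, design, table, vceac, registry, ctx) for r in responses
    ]
    contributions = None
    if collect_contributions:
        n_items = len(design.items)
        max_p = ctx.portion_amounts.shape[1]
        weight = np.zeros((n_items, max_p))
        fmap = design.frequency_map
        for r in responses:
            for item in design.items:
                a = r.answers.get(item.item_id)
                if a is None or a.frequency is None:
                    continue
                season = 1.0
                if item.seasonal:
                    season = seasonal_factor(a.season_months if a.season_months else 12)
                weight[ctx.item_index[item.item_id], a.portion] += (
                    fmap.times_per_day[a.frequency] * season
                )
        values = np.nan_to_num(table.values.to_numpy(), nan=0.0)
        food_pos = {fid: i for i, fid in enumerate(table.food_ids)}
        contrib = np.zeros_like(values)
        for i, it in enumerate(design.items):
            ref = it.reference_grams
            for p, portion_grams in enumerate(it.portion_options):
                w = weight[i, p]
                if w == 0:
                    continue
                for fid, grams in it.item_recipe:
                    fi = food_pos[fid]
                    contrib[fi] += w * grams * (portion_grams / ref) * values[fi] / 100.0
        contributions = pd.DataFrame(
            contrib, index=table.food_ids, columns=ctx.component_ids
        )
    return profiles, contributions


# ---------------------------------------------------------------------------
# exclusions


@dataclass(frozen=True)
class ExclusionAudit:
    """Bookkeeping for the cohort exclusion filter."""

    n_input: int
    n_retained: int
    n_excluded: int
    n_low_energy: int = 0
    n_high_energy: int = 0
    n_missing_rule: int = 0
    n_overlap: int = 0
    lower_value: Optional[float] = None
    upper_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_excluded:
            raise ValueError("audit counts must satisfy input = retained + excluded")


def combine_audits(audits: Sequence[ExclusionAudit]) -> ExclusionAudit:
    """Pool per-cohort exclusion audits into one (percentile bounds dropped,
    as each cohort's bounds are its own)."""
    if not audits:
        raise ValueError("no audits to combine")
    return ExclusionAudit(
        n_input=sum(a.n_input for a in audits),
        n_retained=sum(a.n_retained for a in audits),
        n_excluded=sum(a.n_excluded for a in audits),
        n_low_energy=sum(a.n_low_energy for a in audits),
        n_high_energy=sum(a.n_high_energy for a in audits),
        n_missing_rule=sum(a.n_missing_rule for a in audits),
        n_overlap=sum(a.n_overlap for a in audits),
    )


def apply_exclusions(
    profiles: Sequence[IntakeProfile],
    lower_pct: float = 0.5,
    upper_pct: float = 95.5,
    max_missing: int = 10,
    energy_bounds: Optional[tuple[float, float]] = None,
) -> tuple[list[IntakeProfile], list[IntakeProfile], ExclusionAudit]:
    """Drop implausible reporters and heavy non-responders.

    Excluded: energy strictly below the ``lower_pct`` percentile or strictly
    above the ``upper_pct`` percentile of the *input* cohort (linear
    interpolation between order statistics), or more than ``max_missing``
    missing items.  ``energy_bounds`` reapplies previously computed
    percentile values instead of recomputing ranks.
    """
    if not profiles:
        raise ValueError("empty cohort")
    energy = np.array([p.energy_kcal for p in profiles], dtype=float)
    if energy_bounds is None:
        lo = float(np.percentile(energy, lower_pct))
        hi = float(np.percentile(energy, upper_pct))
    else:
        lo, hi = energy_bounds
    low = energy < lo
    high = energy > hi
    miss = np.array([p.n_missing_items > max_missing for p in profiles])
    excluded_mask = low | high | miss
    retained = [p for p, e in zip(profiles, excluded_mask) if not e]
    excluded = [p for p, e in zip(profiles, excluded_mask) if e]
    audit = ExclusionAudit(
        n_input=len(profiles),
        n_retained=len(retained),
        n_excluded=len(excluded),
        n_low_energy=int(low.sum()),
        n_high_energy=int(high.sum()),
        n_missing_rule=int(miss.sum()),
        n_overlap=int(((low | high) & miss).sum()),
        lower_value=lo,
        upper_value=hi,
    )
    return retained, excluded, audit


# ---------------------------------------------------------------------------
# interchange


def profiles_to_frame(profiles: Sequence[IntakeProfile]) -> pd.DataFrame:
    """One row per participant: components, class/subclass totals, dTAC,
    energy, missing-item count."""
    rows = []
    for p in profiles:
        row: dict = {"participant_id": p.participant_id}
        row.update(p.component_intakes)
        row.update({f"class_{k}": v for k, v in p.class_totals.items()})
        row.update({f"subclass_{k}": v for k, v in p.subclass_totals.items()})
        row["dTAC_mgVCE"] = p.dtac_mg_vce
        row["energy_kcal"] = p.energy_kcal
        row["n_missing_items"] = p.n_missing_items
        rows.append(row)
    return pd.DataFrame(rows)


def design_to_dict(design: FfqDesign) -> dict:
    return {
        "frequency_map": {
            "labels": list(design.frequency_map.labels),
            "times_per_day": list(design.frequency_map.times_per_day),
        },
        "items": [
            {
                "item_id": it.item_id,
                "portion_options": list(it.portion_options),
                "seasonal": it.seasonal,
                "energy_kcal_per_100g": it.energy_kcal_per_100g,
                "item_recipe": [[fid, grams] for fid, grams in it.item_recipe],
            }
            for it in design.items
        ],
    }


def design_from_dict(data: Mapping) -> FfqDesign:
    fm = data.get("frequency_map")
    freq_map = (
        FrequencyMap(tuple(fm["labels"]), tuple(fm["times_per_day"]))
        if fm
        else FrequencyMap()
    )
    items = tuple(
        FfqItem(
            item_id=int(d["item_id"]),
            portion_options=tuple(float(g) for g in d["portion_options"]),
            item_recipe=tuple((str(f), float(g)) for f, g in d["item_recipe"]),
            seasonal=bool(d.get("seasonal", False)),
            energy_kcal_per_100g=float(d.get("energy_kcal_per_100g", 0.0)),
        )
        for d in data["items"]
    )
    return FfqDesign(items=items, frequency_map=freq_map)


def write_design_yaml(design: FfqDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def read_design_yaml(path) -> FfqDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def responses_to_frame(responses: Sequence[FfqResponse], design: FfqDesign) -> pd.DataFrame:
    """One row per participant, columns item{n}_freq / _portion / _season."""
    rows = []
    for r in responses:
        row: dict = {"participant_id": r.participant_id}
        for it in design.items:
            a = r.answers.get(it.item_id)
            row[f"item{it.item_id}_freq"] = None if a is None else a.frequency
            row[f"item{it.item_id}_portion"] = None if a is None else a.portion
            row[f"item{it.item_id}_season"] = None if a is None else a.season_months
        rows.append(row)
    return pd.DataFrame(rows)


def write_responses_csv(responses: Sequence[FfqResponse], design: FfqDesign, path) -> None:
    responses_to_frame(responses, design).to_csv(path, index=False)


def read_responses_csv(path, design: FfqDesign) -> list[FfqResponse]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out = []
    for row in df.itertuples(index=False):
        answers: dict[int, ItemAnswer] = {}
        for it in design.items:
            freq = getattr(row, f"item{it.item_id}_freq")
            portion = getattr(row, f"item{it.item_id}_portion")
            season = getattr(row, f"item{it.item_id}_season")
            answers[it.item_id] = ItemAnswer(
                frequency=None if pd.isna(freq) else int(freq),
                portion=0 if pd.isna(portion) else int(portion),
                season_months=None if pd.isna(season) else int(season),
            )
        out.append(FfqResponse(participant_id=row.participant_id, answers=answers))
    return out
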