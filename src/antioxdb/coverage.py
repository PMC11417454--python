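"""Coverage percentages, provenance/source counts, and intake contributions.

Coverage of a component is the proportion of foods on the list with a
non-missing value (logical zeros count as data), printed as a percentage
rounded half-up to one decimal.  Class and subclass aggregates are
unweighted means of member coverages: a subclass aggregates its component
coverages (computed unrounded, rounded once); the flavonoid class total
aggregates the seven subclass coverages at their printed (1-decimal)
precision, which is the arithmetic the printed tables follow.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .taxonomy import (
    ComponentRegistry,
    CompositionTable,
    DATA_PROVENANCES,
    Provenance,
    SUBCLASSES,
)


def coverage_percent(n_with_data: int, n_total: int) -> float:
    """Percent of foods with data, rounded half-up to 1 decimal."""
    if n_total <= 0:
        raise ValueError("total number of foods must be positive")
    return round_half_up(100.0 * n_with_data / n_total, 1)


def aggregate_coverage(percents: Sequence[float]) -> float:
    """Unweighted mean of coverage percentages, rounded half-up to 1 decimal."""
    if len(percents) == 0:
        raise ValueError("cannot aggregate an empty set of coverages")
    return round_half_up(float(np.mean(percents)), 1)


def component_coverage(table: CompositionTable, component_id: str) -> float:
    """Coverage of one component: foods with non-missing values (zeros
    included) over total foods."""
    if component_id not in table.registry:
        raise KeyError(f"unknown component: {component_id}")
    n = int(table.values[component_id].notna().sum())
    return coverage_percent(n, len(table.food_ids))


def _unrounded_component_coverage(table: CompositionTable, component_id: str) -> float:
    n = int(table.values[component_id].notna().sum())
    return 100.0 * n / len(table.food_ids)


def class_coverage(
    table: CompositionTable,
    class_or_subclass: str,
    include_aggregates: bool = False,
) -> float:
    """Aggregate coverage for an antioxidant class or flavonoid subclass.

    Subclasses and non-flavonoid classes: mean of member-component coverages
    (aggregate pseudo-components excluded unless ``include_aggregates``).
    The flavonoid class: mean of the seven subclass coverages, each at
    1-decimal precision.
    """
    registry = table.registry
    if class_or_subclass == "flavonoids":
        return aggregate_coverage(
            [class_coverage(table, sub, include_aggregates) for sub in SUBCLASSES]
        )
    if class_or_subclass in SUBCLASSES:
        members = registry.by_subclass(class_or_subclass)
    else:
        members = registry.by_class(class_or_subclass)
    if not include_aggregates:
        members = [c for c in members if not c.is_aggregate]
    if not members:
        raise ValueError(f"no components in {class_or_subclass}")
    return aggregate_coverage(
        [_unrounded_component_coverage(table, c.component_id) for c in members]
    )


def any_value_coverage(table: CompositionTable) -> float:
    """Percent of foods with at least one non-missing component value."""
    n = int(table.values.notna().any(axis=1).sum())
    return coverage_percent(n, len(table.food_ids))


def provenance_counts(
    table: CompositionTable, ledger: pd.DataFrame
) -> pd.DataFrame:
    """Per-component counts by source database and by imputation method.

    One row per component with a column per source, a column per method,
    ``n_foods_with_data``, and ``coverage_pct``.  Method counts sum to
    ``n_foods_with_data``.  Raises if the ledger disagrees with the table.
    """
    n_foods = len(table.food_ids)
    expected = n_foods * len(table.registry.component_ids)
    if len(ledger) != expected:
        raise ValueError(
            f"ledger/table mismatch: {len(ledger)} rows for {expected} cells"
        )
    for cid, grp in ledger.groupby("component_id"):
        n_missing_table = int(table.values[cid].isna().sum())
        n_missing_ledger = int((grp["method"] == Provenance.MISSING.value).sum())
        if n_missing_table != n_missing_ledger:
            raise ValueError(f"ledger/table mismatch for component {cid}")

    source_ids = sorted(
        s for s in ledger["source_db"].dropna().unique() if isinstance(s, str)
    )
    rows = []
    for cid in table.registry.component_ids:
        grp = ledger[ledger["component_id"] == cid]
        row: dict = {"component_id": cid}
        for sid in source_ids:
            row[f"source_{sid}"] = int((grp["source_db"] == sid).sum())
        for method in DATA_PROVENANCES:
            row[f"method_{method}"] = int((grp["method"] == method).sum())
        n_with = int((grp["method"] != Provenance.MISSING.value).sum())
        row["n_foods_with_data"] = n_with
        row["n_missing"] = n_foods - n_with
        row["coverage_pct"] = coverage_percent(n_with, n_foods)
        rows.append(row)
    return pd.DataFrame(rows).set_index("component_id")


def coverage_report(
    table: CompositionTable, ledger: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Component rows plus class/subclass aggregate rows and an overall
    any-value row, mirroring the layout of a printed coverage table."""
    registry = table.registry
    rows = []
    if ledger is not None:
        counts = provenance_counts(table, ledger)
    for comp in registry:
        cid = comp.component_id
        row = {
            "row": cid,
            "kind": "component",
            "class": comp.antioxidant_class,
            "subclass": comp.flavonoid_subclass,
            "coverage_pct": component_coverage(table, cid),
        }
        if ledger is not None:
            row.update(counts.loc[cid].to_dict())
        rows.append(row)
    for cls in ("retinol", "carotenoids", "vitamin_C", "vitamin_E", "flavonoids"):
        rows.append(
            {
                "row": cls,
                "kind": "class",
                "coverage_pct": class_coverage(table, cls),
            }
        )
    for sub in SUBCLASSES:
        rows.append(
            {
                "row": sub,
                "kind": "subclass",
                "coverage_pct": class_coverage(table, sub),
            }
        )
    rows.append(
        {"row": "any_value", "kind": "overall", "coverage_pct": any_value_coverage(table)}
    )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Pretty-printed text table of a coverage report."""
    return report.to_string(index=False, na_rep="-")


def percent_contribution(
    contributions: pd.DataFrame, component_id: str
) -> pd.DataFrame:
    """Percent contribution of each food to cohort intake of a component.

    ``contributions`` is the foods x components matrix of cohort-summed
    per-food intake contributions from :func:`antioxdb.ffq.score_cohort`.
    Returns foods ranked by contribution; percentages sum to 100.
    """
    if component_id not in contributions.columns:
        raise KeyError(f"unknown component: {component_id}")
    col = contributions[component_id]
    total = float(col.sum())
    if total <= 0:
        raise ValueError(f"zero total cohort intake for {component_id}")
    out = pd.DataFrame(
        {
            "food_id": col.index,
            "contribution": col.to_numpy(dtype=float),
            "percent": 100.0 * col.to_numpy(dtype=float) / total,
        }
    ).sort_values(["percent", "food_id"], ascending=[False, True], ignore_index=True)
    return out
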