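"""Total antioxidant capacity (TAC) as a VCEAC-weighted sum.

The vitamin C equivalent antioxidant capacity (VCEAC) of a compound is the
mass of vitamin C with the same radical-scavenging capacity per mg of
compound.  The TAC of a food is

    TAC (mg VCE/100 g) = sum over TAC-eligible components of
                         amount (mg/100 g) x VCEAC (mg VCE/mg),

and dietary TAC (dTAC) applies the same weights to daily intakes in mg/day.
Seven registry components never contribute (no confirmed VCEAC): retinol,
gallocatechin, formononetin, the 4-6 and 7-10 proanthocyanidin oligomers,
proanthocyanidin polymers, and the total-isoflavone aggregate — isoflavones
enter through the four individual compounds (daidzein, genistein, glycitein,
biochanin A) instead.

Missing amounts contribute zero; callers that need to surface this get the
count of missing contributors from :func:`table_tac`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .taxonomy import ComponentRegistry, CompositionTable


@dataclass(frozen=True)
class VceacTable:
    """Mapping component_id -> mg vitamin C equivalents per mg of component."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for cid, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative VCEAC for {cid}")
        if "vitamin_c" in self.values and self.values["vitamin_c"] != 1.0:
            raise ValueError("vitamin C must map to VCEAC 1.0 by definition")

    def __contains__(self, component_id: str) -> bool:
        return component_id in self.values

    def __getitem__(self, component_id: str) -> float:
        return self.values[component_id]

    def validate_complete(self, registry: ComponentRegistry) -> None:
        """Require an entry for every TAC-eligible component."""
        missing = [cid for cid in registry.tac_eligible_ids() if cid not in self.values]
        if missing:
            raise ValueError(f"VCEAC table lacks eligible components: {missing}")


def _weighted_sum(
    amounts_mg: Mapping[str, Optional[float]] | pd.Series,
    vceac: VceacTable,
    registry: ComponentRegistry,
) -> float:
    total = 0.0
    get = amounts_mg.get if hasattr(amounts_mg, "get") else amounts_mg.__getitem__
    for cid in registry.tac_eligible_ids():
        try:
            amount = get(cid)
        except KeyError:
            amount = None
        if amount is None or (isinstance(amount, float) and np.isnan(amount)):
            continue
        if cid not in vceac:
            raise ValueError(
                f"VCEAC missing for eligible component {cid} with a non-missing amount"
            )
        total += float(amount) * vceac[cid]
    return total


def food_tac(
    amounts_mg_per_100g: Mapping[str, Optional[float]] | pd.Series,
    vceac: VceacTable,
    registry: ComponentRegistry,
) -> float:
    """TAC of one food in mg VCE per 100 g from per-component mg/100 g amounts.

    Missing amounts contribute 0; TAC-ineligible components never contribute.
    Amounts must already be on the mg/100 g basis.
    """
    return _weighted_sum(amounts_mg_per_100g, vceac, registry)


def diet_tac(
    intakes_mg_per_day: Mapping[str, Optional[float]] | pd.Series,
    vceac: VceacTable,
    registry: ComponentRegistry,
) -> float:
    """Dietary TAC in mg VCE per day from per-component mg/day intakes.

    Linear in the intake vector: the same weighted sum as :func:`food_tac`.
    """
    return _weighted_sum(intakes_mg_per_day, vceac, registry)


def table_tac(table: CompositionTable, vceac: VceacTable) -> pd.DataFrame:
    """Per-food TAC for a whole composition table.

    Returns a DataFrame indexed by food_id with ``tac_mg_vce_per_100g`` and
    ``n_missing_contributors`` (eligible components whose amount was missing
    and therefore treated as zero).
    """
    registry = table.registry
    eligible = registry.tac_eligible_ids()
    mg = table.values_mg()[eligible]
    weights = np.array([vceac[cid] if cid in vceac else np.nan for cid in eligible])
    present = mg.notna().to_numpy()
    needs = present & np.isnan(weights)[None, :]
    if needs.any():
        i, j = np.argwhere(needs)[0]
        raise ValueError(
            f"VCEAC missing for eligible component {eligible[j]} with a "
            f"non-missing amount (food {mg.index[i]})"
        )
    tac = np.nansum(mg.to_numpy() * weights[None, :], axis=1)
    n_missing = (~present).sum(axis=1)
    return pd.DataFrame(
        {"tac_mg_vce_per_100g": tac, "n_missing_contributors": n_missing},
        index=mg.index,
    )


def read_vceac_csv(path) -> VceacTable:
    """Read a VCEAC table: component_id, vceac_mg_vce_per_mg."""
    df = pd.read_csv(path, dtype={"component_id": str})
    return VceacTable(
        {r.component_id: float(r.vceac_mg_vce_per_mg) for r in df.itertuples(index=False)}
    )


def write_vceac_csv(vceac: VceacTable, path) -> None:
    pd.DataFrame(
        {
            "component_id": list(vceac.values),
            "vceac_mg_vce_per_mg": [vceac.values[c] for c in vceac.values],
        }
    ).to_csv(path, index=False)
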