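"""Difference-method estimation of ingredient energy values.

When a test ingredient replaces a fraction r of a basal diet, the test
diet's energy density is the mixture e_test = (1-r) e_basal + r e_ing, so

    e_ing = (e_test - (1 - r) e_basal) / r.

The division by r amplifies measurement noise by ~1/r (3.5x at the study's
r = 0.289), which is why ingredient-level ME/DE ratios can stray above 100
under noise; such values are tolerated with a warning, never truncated.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Optional, Sequence, Tuple

from .datamodel import DataQualityWarning, EnergyBalanceResult, IngredientEnergyValues


def ingredient_energy(e_test: float, e_basal: float, r: float) -> float:
    """Back out the ingredient energy from diet-level energies, MJ/kg DM."""
    if not 0.0 < r <= 1.0:
        raise ValueError(f"substitution rate must be in (0, 1], got {r}")
    return (e_test - (1.0 - r) * e_basal) / r


def ingredient_energy_per_sow(
    pairs: Sequence[Tuple[EnergyBalanceResult, EnergyBalanceResult]],
    r: float,
    ingredient_id: Optional[str] = None,
) -> IngredientEnergyValues:
    """Per-sow difference-method values averaged into one ingredient estimate.

    Each pair is (test-diet result, basal-diet result) for matched sows.
    DE/ME/NE are differenced pair-by-pair and averaged; the ME/DE and NE/ME
    ratios are computed from the averaged energies.
    """
    if not pairs:
        raise ValueError("need at least one (test, basal) result pair")
    diet_ids = {t.diet_id for t, _ in pairs}
    if len(diet_ids) != 1:
        raise ValueError(f"pairs mix test diets: {sorted(diet_ids)}")
    ingredient_id = ingredient_id or diet_ids.pop()

    per_sow = {
        attr: [
            ingredient_energy(getattr(t, attr), getattr(b, attr), r)
            for t, b in pairs
        ]
        for attr in ("de_mj_kg_dm", "me_mj_kg_dm", "ne_mj_kg_dm")
    }
    de = sum(per_sow["de_mj_kg_dm"]) / len(pairs)
    me = sum(per_sow["me_mj_kg_dm"]) / len(pairs)
    ne = sum(per_sow["ne_mj_kg_dm"]) / len(pairs)
    me_de = 100.0 * me / de
    ne_me = 100.0 * ne / me
    if me_de > 100.0:
        warnings.warn(
            f"{ingredient_id}: ME/DE = {me_de:.2f}% exceeds 100 "
            "(difference-method noise amplification)",
            DataQualityWarning,
            stacklevel=2,
        )
    values = IngredientEnergyValues(
        ingredient_id=ingredient_id,
        de=de,
        me=me,
        ne=ne,
        me_de_pct=me_de,
        ne_me_pct=ne_me,
        n_observations=len(pairs),
    )
    for issue in values.validate():
        warnings.warn(issue, DataQualityWarning, stacklevel=2)
    return values


def summarize_ingredients(
    values: Sequence[IngredientEnergyValues],
) -> Dict[str, Dict[str, Optional[float]]]:
    """Mean, min, max and CV (%) of DE/ME/NE across ingredients.

    CV uses the n-1 sample standard deviation and is reported as missing
    (None) for a single ingredient.
    """
    if not values:
        raise ValueError("no ingredient values to summarize")
    out: Dict[str, Dict[str, Optional[float]]] = {}
    for attr in ("de", "me", "ne"):
        xs = [getattr(v, attr) for v in values]
        n = len(xs)
        m = sum(xs) / n
        if n > 1:
            sd = math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))
            cv: Optional[float] = 100.0 * sd / m
        else:
            cv = None
        out[attr] = {"mean": m, "min": min(xs), "max": max(xs), "cv": cv}
    return out
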