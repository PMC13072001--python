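"""Total-collection balance arithmetic: digestibility, N balance, DE/ME/NE.

The energy cascade for one sow-period:

    DE  = (GE intake - fecal GE) / DMI                       [MJ/kg DM]
    ME  = DE - (urinary GE + CH4 energy) / DMI               [MJ/kg DM]
    THP = mean fed-day Brouwer heat / BW^0.75                [kJ/kg^0.75/d]
    RE  = ME intake - THP                                    [kJ/kg^0.75/d]
    REP = retained N x 6.25 x 23.86 / BW^0.75                [kJ/kg^0.75/d]
    REL = RE - REP
    NE  = (RE + FHP) x BW^0.75 / DMI                         [MJ/kg DM]

Methane energy uses 39.54 kJ/L (enthalpy of combustion). Negative
digestibilities (possible when endogenous losses exceed the marginal
ingredient contribution) are flagged, never clipped.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

from .constants import DEFAULT_CONSTANTS, Constants
from .datamodel import (
    CalorimetryDay,
    CollectionKind,
    CollectionRecord,
    DataQualityWarning,
    EnergyBalanceResult,
    SowPeriod,
    State,
)


class InsufficientDataError(ValueError):
    pass


def digestibility_coefficient(intake_qty: float, fecal_qty: float) -> float:
    """Apparent total-tract digestibility, % = 100 (intake - fecal)/intake."""
    if intake_qty <= 0:
        raise ValueError(f"intake must be > 0, got {intake_qty}")
    if fecal_qty < 0:
        raise ValueError(f"fecal quantity must be >= 0, got {fecal_qty}")
    d = 100.0 * (intake_qty - fecal_qty) / intake_qty
    if d < 0:
        warnings.warn(
            f"negative digestibility ({d:.2f}%): fecal output exceeds intake",
            DataQualityWarning,
            stacklevel=2,
        )
    return d


def nitrogen_balance(
    n_intake: float, n_feces: float, n_urine: float
) -> Tuple[float, Dict[str, float]]:
    """Retained N, g/d, with its components: intake - feces - urine."""
    for name, v in (("n_intake", n_intake), ("n_feces", n_feces), ("n_urine", n_urine)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    retained = n_intake - n_feces - n_urine
    return retained, {
        "intake": n_intake,
        "feces": n_feces,
        "urine": n_urine,
        "retained": retained,
    }


def diet_energy_values(
    sp: SowPeriod,
    feces: CollectionRecord,
    urine: CollectionRecord,
    fed_days: Sequence[CalorimetryDay],
    fhp: float,
    constants: Constants = DEFAULT_CONSTANTS,
    nutrient_intake_g_d: Optional[Dict[str, float]] = None,
    nutrient_fecal_g_d: Optional[Dict[str, float]] = None,
) -> EnergyBalanceResult:
    """Full energy-balance evaluation of one sow-period.

    Parameters
    ----------
    sp : SowPeriod
        Intake, body weight and feed gross energy for the period.
    feces, urine : CollectionRecord
        Total-collection records (fecal GE per kg DM, urinary GE per day).
    fed_days : sequence of CalorimetryDay
        Fed-state days carrying integrated gas volumes and Brouwer THP.
    fhp : float
        Fasting heat production, kJ/kg BW^0.75/d, from
        :func:`sowcal.calorimetry.fasting_heat_production`.
    nutrient_intake_g_d, nutrient_fecal_g_d : dict, optional
        Matched analyte flows (g/d) for extra digestibility coefficients
        (CP, NDF, ADF, EE, OM...). DM and GE are always computed.
    """
    if not fed_days:
        raise InsufficientDataError(f"{sp.sow_id}/{sp.period}: no fed calorimetry days")
    if any(d.state is not State.FED for d in fed_days):
        raise ValueError("fed_days must all be fed-state")
    if sp.dm_intake_kg_d <= 0:
        raise InsufficientDataError(f"{sp.sow_id}/{sp.period}: zero DM intake")
    if feces.kind is not CollectionKind.FECES or urine.kind is not CollectionKind.URINE:
        raise ValueError("collection records must be one feces and one urine record")

    result_warnings: list[str] = []
    dmi = sp.dm_intake_kg_d
    mbw = sp.metabolic_bw

    # --- digestibility -------------------------------------------------
    ge_intake_mj = sp.feed_ge_mj_kg_dm * dmi
    fecal_ge_mj = feces.energy_mj_d()
    digest: Dict[str, float] = {
        "DM": digestibility_coefficient(dmi, feces.dm_kg_d()),
        "GE": digestibility_coefficient(ge_intake_mj, fecal_ge_mj),
    }
    if nutrient_intake_g_d:
        for analyte, intake in nutrient_intake_g_d.items():
            fecal = (nutrient_fecal_g_d or {}).get(analyte, 0.0)
            digest[analyte] = digestibility_coefficient(intake, fecal)
    for analyte, d in digest.items():
        if d < 0:
            result_warnings.append(f"digestibility[{analyte}] negative: {d:.2f}%")

    # --- nitrogen ------------------------------------------------------
    n_intake = sp.n_intake_g_d if sp.n_intake_g_d is not None else 0.0
    n_retained, _ = nitrogen_balance(n_intake, feces.n_g_d, urine.n_g_d)

    # --- energy cascade ------------------------------------------------
    de = (ge_intake_mj - fecal_ge_mj) / dmi
    ue_mj = urine.energy_mj_d()
    vch4 = sum(d.vch4_l for d in fed_days) / len(fed_days)
    ch4_mj = constants.ch4_energy_kj_per_l * vch4 / 1000.0
    me = de - (ue_mj + ch4_mj) / dmi
    if not de >= me:
        result_warnings.append(f"ME ({me:.3f}) exceeds DE ({de:.3f})")

    me_intake = me * 1000.0 * dmi / mbw
    thp = sum(d.thp_kj for d in fed_days) / len(fed_days) / mbw
    re = me_intake - thp
    rep = n_retained * constants.n_to_protein * constants.protein_energy_kj_g / mbw
    rel = re - rep
    ne = (re + fhp) * mbw / dmi / 1000.0
    if not me >= ne:
        result_warnings.append(f"NE ({ne:.3f}) exceeds ME ({me:.3f})")

    de_intake_mj = de * dmi
    ue_pct = 100.0 * ue_mj / de_intake_mj
    ch4_pct = 100.0 * ch4_mj / de_intake_mj
    me_de = 100.0 * me / de
    ne_me = 100.0 * ne / me

    return EnergyBalanceResult(
        sow_id=sp.sow_id,
        period=sp.period,
        diet_id=sp.diet_id,
        digestibility=digest,
        n_intake_g_d=n_intake,
        n_feces_g_d=feces.n_g_d,
        n_urine_g_d=urine.n_g_d,
        n_retained_g_d=n_retained,
        de_mj_kg_dm=de,
        me_mj_kg_dm=me,
        ne_mj_kg_dm=ne,
        me_intake=me_intake,
        thp=thp,
        fhp=fhp,
        re=re,
        rep=rep,
        rel=rel,
        ue_pct_de=ue_pct,
        ch4_pct_de=ch4_pct,
        me_de_pct=me_de,
        ne_me_pct=ne_me,
        warnings=result_warnings,
    )


def energy_ratio_suite(r: EnergyBalanceResult) -> Dict[str, float]:
    """The DE-partition ratios; UE/DE + CH4E/DE + ME/DE closes to 100."""
    total = r.ue_pct_de + r.ch4_pct_de + r.me_de_pct
    if abs(total - 100.0) > 0.05:
        warnings.warn(
            f"DE partition sums to {total:.3f}, not 100", DataQualityWarning,
            stacklevel=2,
        )
    return {
        "ue_pct_de": r.ue_pct_de,
        "ch4_pct_de": r.ch4_pct_de,
        "me_de_pct": r.me_de_pct,
        "ne_me_pct": r.ne_me_pct,
        "partition_sum": total,
    }
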