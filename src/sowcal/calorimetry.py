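"""Open-circuit indirect calorimetry: gas volumes, heat production, RQ, FHP.

The chamber is treated as an open-circuit system at steady state: the
recorded differential concentration (exhaust minus inlet, inlet-corrected
sign) times exhaust flow is the instantaneous gas exchange rate, and daily
volumes are trapezoidal integrals of that rate. No washout/lag correction is
applied. Gas volumes are assumed already reduced to a common reference
condition by the analyser; an STP correction hook exists in `Constants` via
coefficient overrides but is off by default.

Heat production follows the Brouwer equation,

    THP (kJ) = 16.18 VO2 + 5.02 VCO2 - 2.17 VCH4 - 5.99 UN,

with volumes in litres per day and urinary nitrogen UN in grams per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import List, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_CONSTANTS, Constants
from .datamodel import CalorimetryDay, DataQualityWarning, GasExchangeRecord, State


class InsufficientDataError(ValueError):
    """Too few or too sparse gas records to evaluate the requested window."""


@dataclass(frozen=True)
class GasVolumes:
    """Integrated gas exchange over a window, litres."""

    vo2_l: float
    vco2_l: float
    vch4_l: float
    coverage: float  # fraction of the window spanned by records


def integrate_gas_day(
    records: Sequence[GasExchangeRecord],
    window: Tuple[datetime, datetime],
    gap_warn_minutes: float = DEFAULT_CONSTANTS.gap_warn_minutes,
) -> GasVolumes:
    """Trapezoidal integration of gas exchange over a half-open window.

    Records at or after ``window[0]`` and strictly before ``window[1]`` are
    used. Sampling gaps longer than ``gap_warn_minutes`` and record spans
    below 98% of the window produce coverage warnings; a negative computed
    volume (calibration drift) is flagged but returned as-is.
    """
    start, end = window
    if not end > start:
        raise InsufficientDataError(f"empty window [{start}, {end})")
    inside = [r for r in records if start <= r.timestamp < end]
    if len(inside) < 2:
        raise InsufficientDataError(
            f"need >= 2 gas records in [{start}, {end}), got {len(inside)}"
        )
    inside.sort(key=lambda r: r.timestamp)

    t = np.array([(r.timestamp - start).total_seconds() / 60.0 for r in inside])
    gaps = np.diff(t)
    if gaps.size and gaps.max() > gap_warn_minutes:
        warnings.warn(
            f"gas sampling gap of {gaps.max():.1f} min exceeds {gap_warn_minutes} min",
            DataQualityWarning,
            stacklevel=2,
        )
    window_min = (end - start).total_seconds() / 60.0
    coverage = (t[-1] - t[0]) / window_min
    if coverage < 0.98:
        warnings.warn(
            f"gas records span {coverage:.1%} of the window", DataQualityWarning,
            stacklevel=2,
        )

    flow = np.array([r.flow_l_min for r in inside])
    volumes = []
    for attr in ("o2_conc", "co2_conc", "ch4_conc"):
        conc = np.array([getattr(r, attr) for r in inside])
        v = float(np.trapezoid(conc * flow, t))
        if v < 0:
            warnings.warn(
                f"negative integrated volume for {attr} ({v:.2f} L): "
                "possible analyser calibration drift",
                DataQualityWarning,
                stacklevel=2,
            )
        volumes.append(v)
    return GasVolumes(volumes[0], volumes[1], volumes[2], float(coverage))


def brouwer_thp(
    vo2_l: float,
    vco2_l: float,
    vch4_l: float = 0.0,
    urinary_n_g: float = 0.0,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Total heat production, kJ, from daily gas volumes and urinary N."""
    if min(vo2_l, vco2_l, vch4_l, urinary_n_g) < 0:
        warnings.warn(
            "negative input to the Brouwer equation", DataQualityWarning, stacklevel=2
        )
    b = constants.brouwer
    return b.o2 * vo2_l + b.co2 * vco2_l - b.ch4 * vch4_l - b.un * urinary_n_g


def respiratory_quotient(vo2_l: float, vco2_l: float) -> float:
    """RQ = VCO2/VO2; ~1.0 on carbohydrate, ~0.7 on fat oxidation."""
    if vo2_l <= 0:
        raise ValueError(f"RQ undefined for VO2 = {vo2_l}")
    return vco2_l / vo2_l


def make_calorimetry_day(
    sow_id: str,
    date: datetime,
    state: State,
    volumes: GasVolumes,
    urinary_n_g: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> CalorimetryDay:
    """Bundle integrated volumes into a :class:`CalorimetryDay` with THP and RQ."""
    return CalorimetryDay(
        sow_id=sow_id,
        date=date,
        state=state,
        vo2_l=volumes.vo2_l,
        vco2_l=volumes.vco2_l,
        vch4_l=volumes.vch4_l,
        urinary_n_g=urinary_n_g,
        thp_kj=brouwer_thp(
            volumes.vo2_l, volumes.vco2_l, volumes.vch4_l, urinary_n_g, constants
        ),
        rq=respiratory_quotient(volumes.vo2_l, volumes.vco2_l),
    )


def fasting_heat_production(
    records: Sequence[GasExchangeRecord],
    fast_window: Tuple[datetime, datetime],
    urinary_n_g: float,
    bw_kg: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Fasting heat production, kJ per kg metabolic BW per day.

    Gas exchange is integrated over the overnight fasting window (22:00 to
    06:00 in the study schedule), the Brouwer equation applied with the
    fasting-day urinary N prorated to the window length, and the total
    scaled linearly to 24 h before normalising by BW^0.75. The linear x3
    extrapolation is a documented convention; override
    ``constants.fasting_scale_to_day`` to change it.
    """
    if bw_kg <= 0:
        raise ValueError("bw_kg must be > 0")
    start, end = fast_window
    hours = (end - start).total_seconds() / 3600.0
    volumes = integrate_gas_day(records, fast_window, constants.gap_warn_minutes)
    if volumes.coverage < constants.min_fasting_coverage:
        raise InsufficientDataError(
            f"fasting window coverage {volumes.coverage:.1%} below the "
            f"{constants.min_fasting_coverage:.0%} minimum"
        )
    un_window = (
        urinary_n_g * hours / 24.0 if constants.include_un_in_fhp else 0.0
    )
    thp_window = brouwer_thp(
        volumes.vo2_l, volumes.vco2_l, volumes.vch4_l, un_window, constants
    )
    daily = thp_window * constants.fasting_scale_to_day
    return daily / bw_kg**0.75


def fed_day_windows(
    day_starts: Sequence[datetime], hours: float = 24.0
) -> List[Tuple[datetime, datetime]]:
    """Convenience: [start, start + hours) windows for a list of fed days."""
    return [(s, s + timedelta(hours=hours)) for s in day_starts]
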