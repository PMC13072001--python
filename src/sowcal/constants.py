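"""Physical constants and trial conventions.

Everything downstream of gas analysis runs in kJ internally; MJ appears only
at I/O boundaries. All coefficients are stored positive; the sign of the
methane and urinary-nitrogen terms lives in the Brouwer formula itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class BrouwerCoefficients:
    """Coefficients of the Brouwer heat-production equation, kJ per unit.

    THP (kJ) = o2·VO2(L) + co2·VCO2(L) − ch4·VCH4(L) − un·UN(g)
    """

    o2: float = 16.18
    co2: float = 5.02
    ch4: float = 2.17
    un: float = 5.99


@dataclass(frozen=True)
class Constants:
    """Conventions of the sow calorimetry trial.

    Attributes
    ----------
    brouwer : BrouwerCoefficients
        Heat-equivalents of the respiratory gases and urinary N.
    ch4_energy_kj_per_l : float
        Enthalpy of combustion of methane, used to convert eructated/expelled
        CH4 volume to an energy loss when stepping from DE to ME.
    protein_energy_kj_g : float
        Energy content of retained body protein, kJ/g.
    n_to_protein : float
        Kjeldahl conversion, g protein per g N.
    feeding_level_kj_me_kg075 : float
        Daily ME allowance of a gestating sow, kJ per kg metabolic body
        weight (BW^0.75); 1.3 x maintenance.
    substitution_rate_default : float
        As-fed fraction of the basal corn-soybean portion replaced by the
        test ingredient in difference-method trials.
    fasting_window_hours : float
        Length of the overnight gas-exchange window used for fasting heat
        production (22:00 on the fasting day to 06:00 next morning).
    fasting_scale_to_day : float
        Factor extrapolating the fasting window total to a daily rate
        (24 h / 8 h = 3; linear extrapolation, configurable).
    include_un_in_fhp : bool
        Whether the urinary-N term of the Brouwer equation is applied when
        computing fasting heat production.
    gap_warn_minutes : float
        Gaps between gas samples longer than this raise a coverage warning.
    min_fasting_coverage : float
        Minimum fraction of the fasting window that must be covered by gas
        records for FHP to be computed.
    float_precision : int
        Decimal places used when writing result tables.
    """

    brouwer: BrouwerCoefficients = field(default_factory=BrouwerCoefficients)
    ch4_energy_kj_per_l: float = 39.54
    protein_energy_kj_g: float = 23.86
    n_to_protein: float = 6.25
    feeding_level_kj_me_kg075: float = 544.0
    substitution_rate_default: float = 0.289
    fasting_window_hours: float = 8.0
    fasting_scale_to_day: float = 3.0
    include_un_in_fhp: bool = True
    gap_warn_minutes: float = 10.0
    min_fasting_coverage: float = 0.90
    float_precision: int = 6

    def with_overrides(self, **kwargs: Any) -> "Constants":
        brouwer_keys = {k: v for k, v in kwargs.items() if k in ("o2", "co2", "ch4", "un")}
        rest = {k: v for k, v in kwargs.items() if k not in brouwer_keys}
        out = self
        if brouwer_keys:
            out = replace(out, brouwer=replace(out.brouwer, **brouwer_keys))
        if rest:
            out = replace(out, **rest)
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "Constants":
        return cls().with_overrides(**dict(mapping))


DEFAULT_CONSTANTS = Constants()
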