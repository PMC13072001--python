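"""Domain types shared by every stage of the energy-evaluation pipeline.

Conventions
-----------
* Percentages are stored on the 0-100 scale, matching how feed tables are
  printed, never as fractions.
* Energies are kJ internally; energy densities of feeds are MJ/kg DM, which
  is how they are reported.
* Soft invariant violations (an analyte slightly over an analytical
  tolerance, a negative digestibility) are *flagged* via `DataQualityWarning`
  or returned warning lists, never silently clipped; hard violations
  (negative body weight, zero dry matter) raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Dict, List, Optional, Sequence


class DataQualityWarning(UserWarning):
    """A measurement violates a soft analytical invariant."""


class Basis(str, Enum):
    """Reporting basis of a chemical composition."""

    AS_FED = "as_fed"
    DM = "dm"


class State(str, Enum):
    """Nutritional state of the sow during a calorimetry measurement."""

    FED = "fed"
    FASTED = "fasted"


#: analytes recognised in composition tables, in canonical order
ANALYTES = (
    "dm", "gross_energy", "cp", "ndf", "adf", "ash", "ee", "starch",
    "idf", "sdf", "tdf", "ca", "p",
)

#: tolerance (percentage points) on the TDF = IDF + SDF closure
TDF_CLOSURE_TOL = 0.5


@dataclass
class ChemicalComposition:
    """Analyte panel of one feed, diet or excreta sample.

    All analyte concentrations are % of mass on the stated ``basis``;
    ``gross_energy`` is MJ/kg on that basis. ``amino_acids`` maps an
    amino-acid name to its % of mass and is carried through I/O untouched.
    """

    sample_id: str
    basis: Basis = Basis.DM
    dm_pct: float = 100.0
    gross_energy: Optional[float] = None
    cp: Optional[float] = None
    ndf: Optional[float] = None
    adf: Optional[float] = None
    ash: Optional[float] = None
    ee: Optional[float] = None
    starch: Optional[float] = None
    idf: Optional[float] = None
    sdf: Optional[float] = None
    tdf: Optional[float] = None
    ca: Optional[float] = None
    p: Optional[float] = None
    amino_acids: Dict[str, float] = field(default_factory=dict)
    extras: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dm_pct > 0:
            raise ValueError(f"{self.sample_id}: dm_pct must be > 0, got {self.dm_pct}")

    @property
    def hemicellulose(self) -> Optional[float]:
        """NDF − ADF, derived on demand so the table stays the single source."""
        if self.ndf is None or self.adf is None:
            return None
        return self.ndf - self.adf

    def validate(self) -> List[str]:
        """Return human-readable soft-invariant violations (empty if clean)."""
        issues: List[str] = []
        for name in ("dm_pct", "cp", "ndf", "adf", "ash", "ee", "starch",
                     "idf", "sdf", "tdf", "ca", "p"):
            v = getattr(self, name if name != "dm_pct" else "dm_pct")
            if v is not None and not 0 <= v <= 100:
                issues.append(f"{self.sample_id}: {name} = {v} outside [0, 100]")
        if self.idf is not None and self.sdf is not None and self.tdf is not None:
            if abs(self.tdf - (self.idf + self.sdf)) > TDF_CLOSURE_TOL:
                issues.append(
                    f"{self.sample_id}: TDF != IDF+SDF "
                    f"({self.tdf} vs {self.idf + self.sdf:.2f})"
                )
        if self.ndf is not None and self.adf is not None and self.ndf < self.adf:
            issues.append(f"{self.sample_id}: NDF ({self.ndf}) < ADF ({self.adf})")
        return issues


@dataclass
class DietFormulation:
    """Inclusion map of one diet, % as-fed, plus its substitution structure.

    ``substitution_rate`` is the as-fed fraction r of the basal diet replaced
    by the test ingredient; for the study diets it equals the barley
    inclusion, 0.289.
    """

    diet_id: str
    components: Dict[str, float]
    substitution_rate: float = 0.0
    basal_ref: Optional[str] = None

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(
                f"{self.diet_id}: inclusions sum to {total:.3f}, expected 100"
            )
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError(f"{self.diet_id}: substitution_rate outside [0, 1]")

    def inclusion(self, ingredient_id: str) -> float:
        return self.components.get(ingredient_id, 0.0)


@dataclass
class SowPeriod:
    """One sow on one diet for one balance period."""

    sow_id: str
    period: int
    diet_id: str
    bw_kg: float
    dm_intake_kg_d: float
    feed_ge_mj_kg_dm: float
    n_intake_g_d: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.bw_kg > 0:
            raise ValueError(f"{self.sow_id}: bw_kg must be > 0")
        if self.dm_intake_kg_d < 0:
            raise ValueError(f"{self.sow_id}: dm_intake_kg_d must be >= 0")

    @property
    def metabolic_bw(self) -> float:
        """Metabolic body weight, kg^0.75."""
        return self.bw_kg ** 0.75


@dataclass
class GasExchangeRecord:
    """One gas-analyser sample.

    Concentrations are differential volume fractions (inlet-corrected): O2
    depletion and CO2/CH4 enrichment of chamber exhaust relative to inlet
    air, so that concentration x flow integrates directly to consumption or
    production volume.
    """

    sow_id: str
    timestamp: datetime
    o2_conc: float
    co2_conc: float
    ch4_conc: float
    flow_l_min: float
    state: State = State.FED

    def __post_init__(self) -> None:
        for name in ("o2_conc", "co2_conc", "ch4_conc"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{self.sow_id} {self.timestamp}: {name} = {v} not a volume fraction")
        if self.flow_l_min < 0:
            raise ValueError(f"{self.sow_id} {self.timestamp}: negative flow")


class CollectionKind(str, Enum):
    FECES = "feces"
    URINE = "urine"


@dataclass
class CollectionRecord:
    """Total-collection record for one sow-period.

    For feces, ``mass_kg_d`` is fresh output with dry matter ``dm_pct`` and
    ``ge_mj_kg`` the gross energy per kg fecal DM. For urine the energy is
    recorded directly as ``ge_mj_d`` (bomb calorimetry of an aliquot scaled
    to daily volume).
    """

    sow_id: str
    period: int
    kind: CollectionKind
    mass_kg_d: float = 0.0
    ge_mj_kg: Optional[float] = None
    ge_mj_d: Optional[float] = None
    n_g_d: float = 0.0
    dm_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mass_kg_d", "n_g_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.sow_id}: {name} must be >= 0")

    def energy_mj_d(self) -> float:
        """Daily gross-energy flow of this excreta stream, MJ/d."""
        if self.kind is CollectionKind.URINE:
            if self.ge_mj_d is None:
                raise ValueError(f"{self.sow_id}: urine record lacks ge_mj_d")
            return self.ge_mj_d
        if self.ge_mj_kg is None or self.dm_pct is None:
            raise ValueError(f"{self.sow_id}: feces record lacks ge_mj_kg or dm_pct")
        return self.mass_kg_d * self.dm_pct / 100.0 * self.ge_mj_kg

    def dm_kg_d(self) -> float:
        if self.dm_pct is None:
            raise ValueError(f"{self.sow_id}: record lacks dm_pct")
        return self.mass_kg_d * self.dm_pct / 100.0


@dataclass
class CalorimetryDay:
    """Integrated gas exchange and heat production of one sow-day."""

    sow_id: str
    date: datetime
    state: State
    vo2_l: float
    vco2_l: float
    vch4_l: float
    urinary_n_g: float
    thp_kj: float
    rq: float

    def validate(self) -> List[str]:
        issues = []
        for name in ("vo2_l", "vco2_l", "vch4_l"):
            if getattr(self, name) < 0:
                issues.append(f"{self.sow_id} {self.date:%Y-%m-%d}: negative {name}")
        if self.vo2_l > 0 and not math.isclose(self.rq, self.vco2_l / self.vo2_l, rel_tol=1e-9):
            issues.append(f"{self.sow_id} {self.date:%Y-%m-%d}: rq inconsistent with volumes")
        return issues


@dataclass
class EnergyBalanceResult:
    """Digestibility, N balance and the full energy partition of one
    sow-period.

    Rates (``me_intake`` ... ``rel``) are kJ per kg metabolic body weight per
    day; energy densities are MJ per kg dietary DM; ratios are %.
    """

    sow_id: str
    period: int
    diet_id: str
    digestibility: Dict[str, float] = field(default_factory=dict)
    n_intake_g_d: float = 0.0
    n_feces_g_d: float = 0.0
    n_urine_g_d: float = 0.0
    n_retained_g_d: float = 0.0
    de_mj_kg_dm: float = 0.0
    me_mj_kg_dm: float = 0.0
    ne_mj_kg_dm: float = 0.0
    me_intake: float = 0.0
    thp: float = 0.0
    fhp: float = 0.0
    re: float = 0.0
    rep: float = 0.0
    rel: float = 0.0
    ue_pct_de: float = 0.0
    ch4_pct_de: float = 0.0
    me_de_pct: float = 0.0
    ne_me_pct: float = 0.0
    warnings: List[str] = field(default_factory=list)

    def validate(self) -> List[str]:
        issues = []
        if not math.isclose(
            self.n_retained_g_d,
            self.n_intake_g_d - self.n_feces_g_d - self.n_urine_g_d,
            abs_tol=1e-9,
        ):
            issues.append(f"{self.sow_id}/{self.period}: N balance does not close")
        if abs(self.re - (self.rep + self.rel)) > 1e-6:
            issues.append(f"{self.sow_id}/{self.period}: RE != REP + REL")
        if not self.de_mj_kg_dm >= self.me_mj_kg_dm >= self.ne_mj_kg_dm >= 0:
            issues.append(f"{self.sow_id}/{self.period}: DE >= ME >= NE >= 0 violated")
        if abs(self.ue_pct_de + self.ch4_pct_de + self.me_de_pct - 100.0) > 0.05:
            issues.append(f"{self.sow_id}/{self.period}: DE partition does not sum to 100")
        for analyte, d in self.digestibility.items():
            if d < 0 or d > 100:
                issues.append(
                    f"{self.sow_id}/{self.period}: digestibility[{analyte}] = {d:.2f} outside [0, 100]"
                )
        return issues


@dataclass
class IngredientEnergyValues:
    """Difference-method energy values of one test ingredient, MJ/kg DM."""

    ingredient_id: str
    de: float
    me: float
    ne: float
    me_de_pct: float
    ne_me_pct: float
    n_observations: int

    def validate(self) -> List[str]:
        issues = []
        if self.de < self.me:
            issues.append(f"{self.ingredient_id}: DE < ME")
        for name in ("me_de_pct", "ne_me_pct"):
            v = getattr(self, name)
            if not 0 < v <= 110:
                issues.append(f"{self.ingredient_id}: {name} = {v:.2f} outside (0, 110]")
        return issues


@dataclass
class RegressionModel:
    """A fitted prediction equation with its fit statistics."""

    response: str
    predictors: List[str]
    intercept: float
    coefficients: Dict[str, float]
    r2: float
    rmse: float
    p_value: float
    n: int
    term_p_values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.predictors):
            raise ValueError("coefficients must cover exactly the predictors")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def predict(self, values: Dict[str, float]) -> float:
        return self.intercept + sum(
            self.coefficients[p] * values[p] for p in self.predictors
        )

    def equation(self, digits: int = 2) -> str:
        terms = [f"{self.intercept:.{digits}f}"]
        for p in self.predictors:
            c = self.coefficients[p]
            terms.append(f"{'-' if c < 0 else '+'} {abs(c):.{digits}f} {p}")
        return f"{self.response} = " + " ".join(terms)


def mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)
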