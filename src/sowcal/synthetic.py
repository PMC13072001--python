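"""Simulate a complete sow calorimetry trial from known ground truth.

The generator emulates the study conditions: gestating sows of BW ~
N(213, 17.8) kg fed at 544 kJ ME/kg BW^0.75/d, a corn-soybean basal diet
(DE/ME/NE = 15.62/14.37/12.23 MJ/kg DM) and test diets in which a fraction
r = 0.289 of the basal is replaced by a test ingredient, fed-state RQ in
[0.93, 1.00], fasted RQ in [0.76, 0.83], fasting heat production near
360 kJ/kg^0.75/d, fecal N 8-10 g/d and urinary N 2.5-3.3 g/d. Gas traces
are emitted as differential concentrations at a configurable resolution so
the whole pipeline — integration, Brouwer heat, balance, difference method —
can be exercised by parameter recovery.

Gas volumes are constructed by inverting the Brouwer equation jointly with
the target RQ,

    VO2 = (THP + 5.99 UN + 2.17 VCH4) / (16.18 + 5.02 RQ),   VCO2 = RQ VO2,

so that at zero noise the analysis pipeline reproduces every truth exactly.
Noise multipliers are lognormal with mean exactly 1 (sigma^2 = ln(1+cv^2)),
keeping recovered quantities unbiased.

Randomness uses a single trial seed split into independent substreams
(ingredients / sows / noise), so enlarging the sow roster never perturbs the
ingredient draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_CONSTANTS, Constants
from .datamodel import (
    Basis,
    ChemicalComposition,
    CollectionKind,
    CollectionRecord,
    GasExchangeRecord,
    SowPeriod,
    State,
)

#: per-analyte uniform ranges of the ten-sample composition table (% DM)
COMPOSITION_RANGES: Dict[str, Tuple[float, float]] = {
    "cp": (9.29, 14.26),
    "ndf": (21.79, 39.54),
    "adf": (3.65, 6.07),
    "ash": (2.10, 3.62),
    "ee": (1.54, 2.34),
    "starch": (44.01, 57.71),
    "idf": (12.02, 17.35),
    "sdf": (4.77, 6.12),
    "dm": (88.70, 91.22),
}

#: basal-diet energy densities, MJ/kg DM (study control diet)
BASAL_ENERGY = {"de": 15.62, "me": 14.37, "ne": 12.23}


class GeneratorError(ValueError):
    """An infeasible combination of simulation targets."""


@dataclass
class NoiseSpec:
    """Coefficients of variation of the simulated measurement errors."""

    gas_cv: float = 0.02
    fecal_cv: float = 0.03
    urine_cv: float = 0.05
    ge_assay_cv: float = 0.01

    def __post_init__(self) -> None:
        for name in ("gas_cv", "fecal_cv", "urine_cv", "ge_assay_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def zero(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, 0.0)


@dataclass
class IngredientTruth:
    """True energy values and composition of one simulated ingredient."""

    ingredient_id: str
    de: float
    me: float
    ne: float
    composition: ChemicalComposition

    def __post_init__(self) -> None:
        if not self.de >= self.me >= self.ne:
            raise GeneratorError(
                f"{self.ingredient_id}: require DE >= ME >= NE, got "
                f"{self.de:.2f}/{self.me:.2f}/{self.ne:.2f}"
            )


@dataclass
class SowTruth:
    sow_id: str
    bw_kg: float
    fhp: float  # kJ/kg^0.75/d
    fed_rq: float
    fasted_rq: float


@dataclass
class TrialGroundTruth:
    """Everything the simulated trial is conditioned on."""

    ingredients: Dict[str, IngredientTruth]
    sows: Dict[str, SowTruth]
    noise: NoiseSpec
    seed: int
    substitution_rate: float = DEFAULT_CONSTANTS.substitution_rate_default
    basal_energy: Dict[str, float] = field(default_factory=lambda: dict(BASAL_ENERGY))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def sample_ingredients(
    n: int, seed: int | np.random.Generator
) -> List[IngredientTruth]:
    """Draw n synthetic ingredients bracketing the study barleys.

    Compositions are uniform within the observed per-analyte ranges with
    TDF = IDF + SDF enforced; true NE is uniform on [7.85, 11.85] MJ/kg DM,
    NE/ME on [0.62, 0.81] and ME/DE on [0.87, 0.99], bracketing the
    published ratio ranges.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: List[IngredientTruth] = []
    for i in range(n):
        draws = {k: float(rng.uniform(*COMPOSITION_RANGES[k])) for k in COMPOSITION_RANGES}
        comp = ChemicalComposition(
            sample_id=f"SynBarley-{i + 1}",
            basis=Basis.DM,
            dm_pct=draws["dm"],
            cp=draws["cp"],
            ndf=max(draws["ndf"], draws["adf"]),
            adf=draws["adf"],
            ash=draws["ash"],
            ee=draws["ee"],
            starch=draws["starch"],
            idf=draws["idf"],
            sdf=draws["sdf"],
            tdf=draws["idf"] + draws["sdf"],
        )
        ne = float(rng.uniform(7.85, 11.85))
        me = ne / float(rng.uniform(0.62, 0.81))
        de = me / float(rng.uniform(0.87, 0.99))
        out.append(IngredientTruth(comp.sample_id, de=de, me=me, ne=ne, composition=comp))
    return out


def sample_sows(n: int, seed: int | np.random.Generator) -> List[SowTruth]:
    """Draw n sows: BW ~ N(213, 17.8), FHP ~ N(360, 10) kJ/kg^0.75/d."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sows = []
    for i in range(n):
        sows.append(
            SowTruth(
                sow_id=f"S{i + 1:02d}",
                bw_kg=float(np.clip(rng.normal(213.0, 17.8), 150.0, 280.0)),
                fhp=float(rng.normal(360.0, 10.0)),
                fed_rq=float(rng.uniform(0.93, 1.00)),
                fasted_rq=float(rng.uniform(0.76, 0.83)),
            )
        )
    return sows


def diet_energy_truth(
    basal: Dict[str, float], ingredient: IngredientTruth, r: float
) -> Dict[str, float]:
    """Mixture energies of a test diet: e = (1-r) e_basal + r e_ingredient."""
    return {
        "de": (1 - r) * basal["de"] + r * ingredient.de,
        "me": (1 - r) * basal["me"] + r * ingredient.me,
        "ne": (1 - r) * basal["ne"] + r * ingredient.ne,
    }


@dataclass
class SowPeriodTruth:
    """Per-period latent values recorded for assertion in tests."""

    diet: Dict[str, float]
    thp: float
    re: float
    fhp: float
    dmi_kg_d: float
    feed_ge_mj_kg_dm: float
    n_retained_g_d: float


def simulate_sow_period(
    sow: SowTruth,
    diet_id: str,
    diet_energy: Dict[str, float],
    period: int,
    start: datetime,
    rng: np.random.Generator,
    noise: Optional[NoiseSpec] = None,
    fed_days: int = 3,
    resolution_min: int = 1,
    diet_cp_pct: float = 14.0,
    constants: Constants = DEFAULT_CONSTANTS,
) -> Tuple[List[GasExchangeRecord], List[CollectionRecord], SowPeriod, SowPeriodTruth]:
    """Simulate one sow on one diet: gas traces, collections, intake.

    The schedule is ``fed_days`` 24 h fed days starting at 08:00, then a
    fasting day whose 22:00-06:00 window supplies the FHP measurement.
    """
    noise = noise or NoiseSpec()
    if not diet_energy["de"] >= diet_energy["me"] >= diet_energy["ne"] > 0:
        raise GeneratorError(f"{diet_id}: diet energies must satisfy DE >= ME >= NE > 0")

    mbw = sow.bw_kg**0.75
    de, me, ne = diet_energy["de"], diet_energy["me"], diet_energy["ne"]

    # intake set so ME intake hits the 544 kJ/kg^0.75/d allowance exactly
    dmi = constants.feeding_level_kj_me_kg075 * mbw / (me * 1000.0)
    de_intake = de * dmi  # MJ/d
    ge_dig = float(rng.uniform(0.82, 0.88))
    feed_ge = de / ge_dig

    # DE -> ME losses: methane ~0.7-1.0% of DE, remainder to urine
    ch4_mj = float(rng.uniform(0.007, 0.010)) * de_intake
    ue_mj = (de - me) * dmi - ch4_mj
    if ue_mj <= 0:
        raise GeneratorError(
            f"{diet_id}: DE-ME gap too small for the drawn methane fraction "
            f"(ue_mj = {ue_mj:.3f})"
        )
    vch4_day = ch4_mj * 1000.0 / constants.ch4_energy_kj_per_l

    # nitrogen partition calibrated to the trial magnitudes
    n_intake = diet_cp_pct / 100.0 * dmi * 1000.0 / constants.n_to_protein
    n_feces = float(rng.uniform(8.0, 10.0))
    n_urine = float(rng.uniform(2.5, 3.3))
    n_retained = n_intake - n_feces - n_urine
    if n_retained <= 0:
        raise GeneratorError(f"{diet_id}: negative retained N ({n_retained:.1f} g/d)")

    # heat production from the energy identity NE = (RE + FHP) * mbw / dmi
    me_intake_rate = me * 1000.0 * dmi / mbw  # == feeding level
    ne_intake_rate = ne * 1000.0 * dmi / mbw
    re_rate = ne_intake_rate - sow.fhp
    thp_rate = me_intake_rate - re_rate
    thp_day = thp_rate * mbw
    if thp_day <= 0:
        raise GeneratorError(f"{diet_id}: implied THP <= 0 (fhp = {sow.fhp:.0f})")

    b = constants.brouwer
    gas: List[GasExchangeRecord] = []
    flow = 500.0  # chamber exhaust, L/min

    def trace(
        t0: datetime,
        minutes: int,
        vo2: float,
        vco2: float,
        vch4: float,
        state: State,
    ) -> None:
        ts = np.arange(0, minutes, resolution_min)
        span = float(ts[-1])  # trapezoid covers [0, span] of the window
        base = np.array([vo2, vco2, vch4]) / (flow * span)
        factors = _lognormal_factors(rng, noise.gas_cv, (ts.size, 3))
        for k, minute in enumerate(ts):
            gas.append(
                GasExchangeRecord(
                    sow_id=sow.sow_id,
                    timestamp=t0 + timedelta(minutes=float(minute)),
                    o2_conc=float(base[0] * factors[k, 0]),
                    co2_conc=float(base[1] * factors[k, 1]),
                    ch4_conc=float(base[2] * factors[k, 2]),
                    flow_l_min=flow,
                    state=state,
                )
            )

    for d in range(fed_days):
        rq = sow.fed_rq
        vo2 = (thp_day + b.un * n_urine + b.ch4 * vch4_day) / (b.o2 + b.co2 * rq)
        if vo2 <= 0:
            raise GeneratorError(f"{diet_id}: implied VO2 <= 0 on fed day {d + 1}")
        trace(start + timedelta(days=d), 1440, vo2, rq * vo2, vch4_day, State.FED)

    # fasting window: 22:00 on the day after the last fed day -> 06:00.
    # The inversion uses the period urine N, the same value the analysis
    # prorates into the window, so FHP round-trips exactly at zero noise.
    fast_start = start.replace(hour=22) + timedelta(days=fed_days)
    thp_fast_window = sow.fhp * mbw / constants.fasting_scale_to_day
    vch4_fast = 1.0  # residual hindgut fermentation, L per window
    un_window = (
        n_urine * constants.fasting_window_hours / 24.0
        if constants.include_un_in_fhp
        else 0.0
    )
    rqf = sow.fasted_rq
    vo2_fast = (thp_fast_window + b.un * un_window + b.ch4 * vch4_fast) / (
        b.o2 + b.co2 * rqf
    )
    if vo2_fast <= 0:
        raise GeneratorError(f"{diet_id}: implied fasting VO2 <= 0 (fhp = {sow.fhp:.0f})")
    trace(fast_start, 480, vo2_fast, rqf * vo2_fast, vch4_fast, State.FASTED)

    # total collections for the balance period
    fecal_ge_mj = (1.0 - ge_dig) * feed_ge * dmi
    fecal_ge_per_kg_dm = 17.5 * float(_lognormal_factors(rng, noise.ge_assay_cv, ()))
    fecal_dm = fecal_ge_mj / 17.5 * float(_lognormal_factors(rng, noise.fecal_cv, ()))
    feces = CollectionRecord(
        sow_id=sow.sow_id,
        period=period,
        kind=CollectionKind.FECES,
        mass_kg_d=fecal_dm / 0.25,
        ge_mj_kg=fecal_ge_per_kg_dm,
        n_g_d=n_feces * float(_lognormal_factors(rng, noise.fecal_cv, ())),
        dm_pct=25.0,
    )
    urine = CollectionRecord(
        sow_id=sow.sow_id,
        period=period,
        kind=CollectionKind.URINE,
        mass_kg_d=8.0,
        ge_mj_d=ue_mj * float(_lognormal_factors(rng, noise.urine_cv, ())),
        n_g_d=n_urine,
    )
    sp = SowPeriod(
        sow_id=sow.sow_id,
        period=period,
        diet_id=diet_id,
        bw_kg=sow.bw_kg,
        dm_intake_kg_d=dmi,
        feed_ge_mj_kg_dm=feed_ge * float(_lognormal_factors(rng, noise.ge_assay_cv, ())),
        n_intake_g_d=n_intake,
    )
    truth = SowPeriodTruth(
        diet=dict(diet_energy),
        thp=thp_rate,
        re=re_rate,
        fhp=sow.fhp,
        dmi_kg_d=dmi,
        feed_ge_mj_kg_dm=feed_ge,
        n_retained_g_d=n_retained,
    )
    return gas, [feces, urine], sp, truth


@dataclass
class TrialData:
    """Everything a simulated trial produced, in memory."""

    truth: TrialGroundTruth
    gas: List[GasExchangeRecord]
    collections: List[CollectionRecord]
    sow_periods: List[SowPeriod]
    period_truths: Dict[Tuple[str, int], SowPeriodTruth]
    assignments: Dict[str, str]  # diet_id -> ingredient_id ('' for basal)


def make_ground_truth(
    n_ingredients: int = 5,
    n_sows: int = 12,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    substitution_rate: float = DEFAULT_CONSTANTS.substitution_rate_default,
) -> TrialGroundTruth:
    """Assemble a :class:`TrialGroundTruth` from independent substreams."""
    ss = np.random.SeedSequence(seed)
    ing_seed, sow_seed, _ = ss.spawn(3)
    ingredients = sample_ingredients(n_ingredients, np.random.default_rng(ing_seed))
    sows = sample_sows(n_sows, np.random.default_rng(sow_seed))
    return TrialGroundTruth(
        ingredients={i.ingredient_id: i for i in ingredients},
        sows={s.sow_id: s for s in sows},
        noise=noise or NoiseSpec(),
        seed=seed,
        substitution_rate=substitution_rate,
    )


def simulate_trial(
    truth: TrialGroundTruth,
    sows_per_diet: int = 2,
    fed_days: int = 3,
    resolution_min: int = 1,
    start: Optional[datetime] = None,
    out_dir: Optional[Path | str] = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> TrialData:
    """Simulate the whole trial: basal group plus one group per ingredient.

    Sows are assigned to diets in roster order, one period each; the trial
    therefore needs ``(n_ingredients + 1) * sows_per_diet`` sows. With
    ``out_dir`` set, the four pipeline input CSVs and a ground-truth
    manifest YAML are written (byte-identical for identical seeds).
    """
    start = start or datetime(2024, 1, 1, 8, 0)
    diets = ["Basal"] + list(truth.ingredients)
    needed = len(diets) * sows_per_diet
    roster = list(truth.sows.values())
    if len(roster) < needed:
        raise GeneratorError(
            f"trial needs {needed} sows, ground truth has {len(roster)}"
        )
    noise_root = np.random.SeedSequence(truth.seed).spawn(3)[2]
    r = truth.substitution_rate

    gas: List[GasExchangeRecord] = []
    collections: List[CollectionRecord] = []
    sow_periods: List[SowPeriod] = []
    period_truths: Dict[Tuple[str, int], SowPeriodTruth] = {}
    assignments: Dict[str, str] = {}

    streams = noise_root.spawn(needed)
    idx = 0
    for diet_id in diets:
        if diet_id == "Basal":
            energy = dict(truth.basal_energy)
            assignments[diet_id] = ""
        else:
            energy = diet_energy_truth(truth.basal_energy, truth.ingredients[diet_id], r)
            assignments[diet_id] = diet_id
        for _ in range(sows_per_diet):
            sow = roster[idx]
            rng = np.random.default_rng(streams[idx])
            g, c, sp, pt = simulate_sow_period(
                sow,
                diet_id,
                energy,
                period=1,
                start=start,
                rng=rng,
                noise=truth.noise,
                fed_days=fed_days,
                resolution_min=resolution_min,
                constants=constants,
            )
            gas.extend(g)
            collections.extend(c)
            sow_periods.append(sp)
            period_truths[(sow.sow_id, 1)] = pt
            idx += 1

    data = TrialData(truth, gas, collections, sow_periods, period_truths, assignments)
    if out_dir is not None:
        write_trial(data, Path(out_dir))
    return data


def write_trial(data: TrialData, out_dir: Path) -> None:
    """Write the pipeline input CSVs plus a ground-truth manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "sow_id": g.sow_id,
                "timestamp": g.timestamp.isoformat(),
                "o2_conc": repr(g.o2_conc),
                "co2_conc": repr(g.co2_conc),
                "ch4_conc": repr(g.ch4_conc),
                "flow_l_min": g.flow_l_min,
                "state": g.state.value,
            }
            for g in data.gas
        ]
    ).to_csv(out_dir / "gas.csv", index=False)
    pd.DataFrame(
        [
            {
                "sow_id": c.sow_id,
                "period": c.period,
                "kind": c.kind.value,
                "mass_kg_d": c.mass_kg_d,
                "ge_mj_kg": c.ge_mj_kg,
                "ge_mj_d": c.ge_mj_d,
                "n_g_d": c.n_g_d,
                "dm_pct": c.dm_pct,
            }
            for c in data.collections
        ]
    ).to_csv(out_dir / "collections.csv", index=False)
    pd.DataFrame(
        [
            {
                "sow_id": s.sow_id,
                "period": s.period,
                "diet_id": s.diet_id,
                "bw_kg": s.bw_kg,
                "dm_intake_kg_d": s.dm_intake_kg_d,
                "feed_ge_mj_kg_dm": s.feed_ge_mj_kg_dm,
                "n_intake_g_d": s.n_intake_g_d,
            }
            for s in data.sow_periods
        ]
    ).to_csv(out_dir / "sow_periods.csv", index=False)
    manifest = {
        "seed": data.truth.seed,
        "substitution_rate": data.truth.substitution_rate,
        "basal_energy": {k: float(v) for k, v in data.truth.basal_energy.items()},
        "assignments": data.assignments,
        "noise": {
            "gas_cv": data.truth.noise.gas_cv,
            "fecal_cv": data.truth.noise.fecal_cv,
            "urine_cv": data.truth.noise.urine_cv,
            "ge_assay_cv": data.truth.noise.ge_assay_cv,
        },
        "ingredients": {
            k: {"de": v.de, "me": v.me, "ne": v.ne}
            for k, v in data.truth.ingredients.items()
        },
        "sows": {
            k: {
                "bw_kg": s.bw_kg,
                "fhp": s.fhp,
                "fed_rq": s.fed_rq,
                "fasted_rq": s.fasted_rq,
            }
            for k, s in data.truth.sows.items()
        },
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
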