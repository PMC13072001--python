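"""End-to-end orchestration: gas traces -> balance -> ingredient energies ->
prediction statistics.

`run_balance` consumes the three tabular inputs (gas time series, total
collections, sow-period intake table) and produces one
:class:`EnergyBalanceResult` per sow-period; `ingredient_values` applies the
difference method per matched sow pair; `run_pipeline` drives the whole
chain from a YAML config and writes tidy CSVs.

Measurement windows are derived from the data: each sow's fed records are
cut into consecutive 24 h blocks from the first fed timestamp, and the
fasting window spans the fasted-state records (nominally 22:00-06:00).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import io as sowcal_io
from .balance import diet_energy_values
from .calorimetry import (
    InsufficientDataError,
    fasting_heat_production,
    integrate_gas_day,
    make_calorimetry_day,
)
from .constants import DEFAULT_CONSTANTS, Constants
from .datamodel import (
    CalorimetryDay,
    CollectionKind,
    CollectionRecord,
    EnergyBalanceResult,
    GasExchangeRecord,
    IngredientEnergyValues,
    SowPeriod,
    State,
)
from .difference_method import ingredient_energy_per_sow, summarize_ingredients
from .stats import StepwiseConfig, ols_fit, pearson_matrix, stepwise_select


class PipelineError(RuntimeError):
    """A structured end-to-end failure naming the offending sow/day/file."""


def _fed_windows(records: Sequence[GasExchangeRecord]):
    fed = sorted((r for r in records if r.state is State.FED), key=lambda r: r.timestamp)
    if not fed:
        return []
    t0 = fed[0].timestamp
    last = fed[-1].timestamp
    windows = []
    k = 0
    while t0 + timedelta(hours=24 * k) <= last:
        windows.append((t0 + timedelta(hours=24 * k), t0 + timedelta(hours=24 * (k + 1))))
        k += 1
    return windows


def _fast_window(records: Sequence[GasExchangeRecord]):
    fasted = sorted(
        (r for r in records if r.state is State.FASTED), key=lambda r: r.timestamp
    )
    if len(fasted) < 2:
        return None
    step = min(
        (b.timestamp - a.timestamp for a, b in zip(fasted, fasted[1:])),
        default=timedelta(minutes=1),
    )
    return fasted[0].timestamp, fasted[-1].timestamp + step


def analyze_sow_period(
    sp: SowPeriod,
    gas: Sequence[GasExchangeRecord],
    feces: CollectionRecord,
    urine: CollectionRecord,
    constants: Constants = DEFAULT_CONSTANTS,
) -> EnergyBalanceResult:
    """Integrate one sow-period's gas data and run the full energy balance."""
    records = [g for g in gas if g.sow_id == sp.sow_id]
    if not records:
        raise PipelineError(f"no gas records for sow {sp.sow_id}")
    fed_days: List[CalorimetryDay] = []
    for window in _fed_windows(records):
        try:
            volumes = integrate_gas_day(records, window, constants.gap_warn_minutes)
        except InsufficientDataError as exc:
            raise PipelineError(
                f"sow {sp.sow_id}, fed day starting {window[0]}: {exc}"
            ) from exc
        fed_days.append(
            make_calorimetry_day(
                sp.sow_id, window[0], State.FED, volumes, urine.n_g_d, constants
            )
        )
    if not fed_days:
        raise PipelineError(f"sow {sp.sow_id}: no fed-state gas records")

    fast = _fast_window(records)
    if fast is None:
        raise PipelineError(f"sow {sp.sow_id}: no fasted-state gas records")
    try:
        fhp = fasting_heat_production(records, fast, urine.n_g_d, sp.bw_kg, constants)
    except InsufficientDataError as exc:
        raise PipelineError(f"sow {sp.sow_id}, fasting window: {exc}") from exc

    return diet_energy_values(sp, feces, urine, fed_days, fhp, constants)


def run_balance(
    sow_periods: Sequence[SowPeriod],
    gas: Sequence[GasExchangeRecord],
    collections: Sequence[CollectionRecord],
    constants: Constants = DEFAULT_CONSTANTS,
) -> List[EnergyBalanceResult]:
    """Energy balance for every sow-period in the trial."""
    by_key: Dict[Tuple[str, int, CollectionKind], CollectionRecord] = {}
    for c in collections:
        by_key[(c.sow_id, c.period, c.kind)] = c
    results = []
    for sp in sow_periods:
        try:
            feces = by_key[(sp.sow_id, sp.period, CollectionKind.FECES)]
            urine = by_key[(sp.sow_id, sp.period, CollectionKind.URINE)]
        except KeyError as exc:
            raise PipelineError(
                f"missing collection record for sow {sp.sow_id} period {sp.period}"
            ) from exc
        results.append(analyze_sow_period(sp, gas, feces, urine, constants))
    return results


def ingredient_values(
    results: Sequence[EnergyBalanceResult],
    substitution: Dict[str, str],
    r: float,
    assignments: Optional[Dict[str, str]] = None,
) -> List[IngredientEnergyValues]:
    """Difference-method ingredient values from per-sow diet results.

    ``substitution`` maps each test diet to its basal reference diet; the
    i-th sow on a test diet is paired with the i-th basal sow (cycling if
    group sizes differ). ``assignments`` optionally renames a test diet to
    its ingredient id.
    """
    by_diet: Dict[str, List[EnergyBalanceResult]] = defaultdict(list)
    for res in results:
        by_diet[res.diet_id].append(res)
    out = []
    for test_diet, basal_diet in substitution.items():
        if basal_diet not in by_diet:
            raise PipelineError(
                f"basal reference diet {basal_diet!r} for {test_diet!r} has no results"
            )
        if test_diet not in by_diet:
            raise PipelineError(f"test diet {test_diet!r} has no results")
        tests = by_diet[test_diet]
        basals = by_diet[basal_diet]
        pairs = [(t, basals[i % len(basals)]) for i, t in enumerate(tests)]
        ingredient_id = (assignments or {}).get(test_diet) or test_diet
        out.append(ingredient_energy_per_sow(pairs, r, ingredient_id=ingredient_id))
    return out


@dataclass
class PipelineReport:
    """Everything one end-to-end run produced."""

    per_sow: List[EnergyBalanceResult]
    per_ingredient: List[IngredientEnergyValues]
    ingredient_summary: Dict[str, Dict[str, Optional[float]]]
    warnings: List[str] = field(default_factory=list)

    def per_sow_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_sow:
            row = {
                "sow_id": r.sow_id, "period": r.period, "diet_id": r.diet_id,
                "de_mj_kg_dm": r.de_mj_kg_dm, "me_mj_kg_dm": r.me_mj_kg_dm,
                "ne_mj_kg_dm": r.ne_mj_kg_dm, "me_intake": r.me_intake,
                "thp": r.thp, "fhp": r.fhp, "re": r.re, "rep": r.rep,
                "rel": r.rel, "ue_pct_de": r.ue_pct_de,
                "ch4_pct_de": r.ch4_pct_de, "me_de_pct": r.me_de_pct,
                "ne_me_pct": r.ne_me_pct,
                "n_retained_g_d": r.n_retained_g_d,
            }
            for analyte, d in r.digestibility.items():
                row[f"dig_{analyte.lower()}"] = d
            rows.append(row)
        return pd.DataFrame(rows)

    def per_diet_frame(self) -> pd.DataFrame:
        df = self.per_sow_frame()
        return df.drop(columns=["sow_id", "period"]).groupby("diet_id").mean()

    def per_ingredient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ingredient_id": v.ingredient_id, "de_mj_kg_dm": v.de,
                    "me_mj_kg_dm": v.me, "ne_mj_kg_dm": v.ne,
                    "me_de_pct": v.me_de_pct, "ne_me_pct": v.ne_me_pct,
                    "n_observations": v.n_observations,
                }
                for v in self.per_ingredient
            ]
        )


def run_pipeline(config: Dict | str | Path, constants: Constants = DEFAULT_CONSTANTS) -> PipelineReport:
    """Execute calorimetry -> balance -> difference method from a config.

    The config (mapping or path to YAML) names the input files and the
    substitution structure::

        gas: gas.csv
        collections: collections.csv
        sow_periods: sow_periods.csv
        substitution_rate: 0.289
        basal_diet: Basal             # every other diet is a test diet
        out: results/                 # optional; write tidy CSVs there
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    for key in ("gas", "collections", "sow_periods"):
        if key not in config:
            raise PipelineError(f"config missing required key {key!r}")
    try:
        gas = sowcal_io.read_gas_csv(config["gas"])
    except (sowcal_io.FormatError, ValueError) as exc:
        raise PipelineError(f"gas file {config['gas']}: {exc}") from exc
    collections = sowcal_io.read_collection_csv(config["collections"])
    sow_periods = sowcal_io.read_sow_periods_csv(config["sow_periods"])

    results = run_balance(sow_periods, gas, collections, constants)

    basal = config.get("basal_diet", "Basal")
    r = float(config.get("substitution_rate", constants.substitution_rate_default))
    test_diets = sorted({sp.diet_id for sp in sow_periods} - {basal})
    substitution = {d: basal for d in test_diets}
    per_ingredient = ingredient_values(results, substitution, r) if test_diets else []
    summary = summarize_ingredients(per_ingredient) if per_ingredient else {}

    warnings_log = [w for res in results for w in res.warnings]
    report = PipelineReport(results, per_ingredient, summary, warnings_log)

    out = config.get("out")
    if out:
        out_dir = Path(out)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.per_sow_frame().to_csv(out_dir / "per_sow.csv", index=False)
        report.per_diet_frame().to_csv(out_dir / "per_diet.csv")
        if per_ingredient:
            report.per_ingredient_frame().to_csv(out_dir / "per_ingredient.csv", index=False)
    return report


def table_statistics(
    composition: Optional[pd.DataFrame] = None,
    energy: Optional[pd.DataFrame] = None,
    response: str = "ne_mj_kg_dm",
    candidates: Sequence[str] = ("cp", "ndf", "adf", "ash", "ee", "starch", "idf", "sdf", "tdf"),
    slentry: float = 0.20,
    slstay: float = 0.20,
):
    """Correlation matrix and stepwise prediction equations for an
    ingredient panel (defaults to the packaged ten-barley tables).

    Returns (CorrelationMatrix, ranked stepwise models, direct ADF+TDF fit).
    The 0.20 entry/stay thresholds are the package's analysis default for
    this panel; see the methods note for why the suppression structure of
    ADF/TDF requires a threshold above the single-variable entry p.
    """
    if composition is None:
        composition = sowcal_io.composition_frame(sowcal_io.load_barley_composition())
    if energy is None:
        energy = sowcal_io.load_barley_energy()
    merged = composition.join(
        energy[["de_mj_kg_dm", "me_mj_kg_dm", "ne_mj_kg_dm"]], how="inner"
    )
    corr_cols = [
        "cp", "ndf", "adf", "ash", "ee", "starch", "idf", "sdf", "tdf",
        "de_mj_kg_dm", "me_mj_kg_dm", "ne_mj_kg_dm",
    ]
    corr = pearson_matrix(merged[corr_cols], include_hemicellulose=True)
    cfg = StepwiseConfig(slentry=slentry, slstay=slstay, candidates=list(candidates))
    models = stepwise_select(merged[response], merged, cfg)
    direct = ols_fit(merged[response], merged[["adf", "tdf"]])
    return corr, models, direct
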