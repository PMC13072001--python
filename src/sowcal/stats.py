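"""Descriptive statistics, Pearson correlation with significance, and
SAS-style stepwise construction of energy prediction equations.

The stepwise search mirrors PROC REG's STEPWISE option: at each step the
candidate with the smallest partial-F p-value enters if it clears SLENTRY,
then terms whose partial-F p exceeds SLSTAY are removed (worst first). The
procedure is deterministic given the candidate order; ties break on list
order. Visited models are returned ranked by (significance of the overall F
at 0.05, R-squared descending, RMSE ascending) so the "best prediction
equation" convention — significant, largest R-squared, smallest RMSE — is
the head of the list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as scipy_stats

from .datamodel import DataQualityWarning, RegressionModel


@dataclass
class CorrelationMatrix:
    """Pearson correlation matrix with two-sided p-values."""

    variables: List[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self) -> pd.DataFrame:
        """Render r with significance stars (* p<0.05, ** p<0.01)."""
        def cell(i: str, j: str) -> str:
            rv, pv = self.r.loc[i, j], self.p.loc[i, j]
            if np.isnan(rv):
                return ""
            star = "**" if pv < 0.01 else "*" if pv < 0.05 else ""
            return f"{rv:.2f}{star}" if i != j else "1"
        return pd.DataFrame(
            {j: [cell(i, j) for i in self.variables] for j in self.variables},
            index=self.variables,
        ).T


@dataclass
class StepwiseConfig:
    """Entry/stay thresholds and candidate pool for stepwise selection."""

    slentry: float = 0.15
    slstay: float = 0.15
    candidates: List[str] = field(default_factory=list)
    max_terms: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("slentry", "slstay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def describe(values: Sequence[float]) -> Dict[str, float]:
    """Mean, n-1 SD, CV (%), min, max."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    m = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return {
        "mean": m,
        "sd": sd,
        "cv": 100.0 * sd / m if m != 0 else float("nan"),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def pearson_matrix(
    table: pd.DataFrame,
    include_hemicellulose: bool = False,
) -> CorrelationMatrix:
    """All-pairs Pearson correlations of a samples-by-analytes table.

    p-values come from t = r sqrt((n-2)/(1-r^2)) on n-2 df, two-sided.
    Zero-variance columns get NaN correlations with a warning rather than
    failing the whole matrix. With ``include_hemicellulose`` the derived
    column NDF - ADF is appended (it is never stored in composition tables).
    """
    df = table.copy()
    if include_hemicellulose:
        if not {"ndf", "adf"} <= set(df.columns):
            raise ValueError("hemicellulose needs both ndf and adf columns")
        df["hemicellulose"] = df["ndf"] - df["adf"]
    if df.isna().any().any():
        raise ValueError("missing values in correlation input")
    n = len(df)
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")

    variables = list(df.columns)
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    dead = [v for v, s in zip(variables, sd) if s == 0.0]
    if dead:
        warnings.warn(
            f"zero-variance columns reported as missing: {dead}",
            DataQualityWarning,
            stacklevel=2,
        )
    centered = x - x.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centered.T @ centered / (n - 1)
        r = cov / np.outer(sd, sd)
    np.fill_diagonal(r, 1.0)
    for i, v in enumerate(variables):
        if v in dead:
            r[i, :] = r[:, i] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * scipy_stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)

    return CorrelationMatrix(
        variables=variables,
        r=pd.DataFrame(r, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
        n=n,
    )


def ols_fit(y: pd.Series, X: pd.DataFrame) -> RegressionModel:
    """Least-squares fit with R^2, RMSE on n-k-1 df, and overall-F p.

    An empty ``X`` fits the intercept-only model (R^2 = 0, RMSE = SD of y).
    """
    n = len(y)
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={n}, k={k})")
    if k > 0:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy(float)]))
        if rank < k + 1:
            raise ValueError(
                f"collinear predictors among {list(X.columns)}: design rank {rank} < {k + 1}"
            )
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    sse = float(fit.ssr)
    rmse = float(np.sqrt(sse / (n - k - 1)))
    if k == 0:
        r2, p_overall = 0.0, 1.0
    else:
        r2 = float(fit.rsquared)
        p_overall = float(fit.f_pvalue)
    coef = {c: float(fit.params[c]) for c in X.columns}
    term_p = {c: float(fit.pvalues[c]) for c in X.columns}
    return RegressionModel(
        response=getattr(y, "name", None) or "y",
        predictors=list(X.columns),
        intercept=float(fit.params["const"]),
        coefficients=coef,
        r2=r2,
        rmse=rmse,
        p_value=p_overall,
        n=n,
        term_p_values=term_p,
    )


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _partial_f_p(y: np.ndarray, base: np.ndarray, added: np.ndarray) -> float:
    """p-value for adding one column to the base design (1, df_resid)."""
    n = y.size
    sse0 = _sse(y, base)
    full = np.column_stack([base, added])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        return 1.0
    sse1 = _sse(y, full)
    df = n - full.shape[1]
    if df <= 0 or sse1 <= 0:
        return 0.0 if sse0 > sse1 else 1.0
    f = (sse0 - sse1) / (sse1 / df)
    return float(scipy_stats.f.sf(f, 1, df))


def stepwise_select(
    y: pd.Series,
    table: pd.DataFrame,
    cfg: StepwiseConfig,
) -> List[RegressionModel]:
    """SAS-style stepwise selection; returns visited models, best first.

    Ranking key: significant overall F first, then R^2 descending, RMSE
    ascending. If no candidate enters, the intercept-only model is returned
    with a warning.
    """
    candidates = cfg.candidates or list(table.columns)
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValueError(f"candidates absent from table: {missing}")
    n = len(y)
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")

    yv = np.asarray(y, dtype=float)
    cols = {c: table[c].to_numpy(dtype=float) for c in candidates}
    ones = np.ones((n, 1))

    model: List[str] = []
    visited: List[List[str]] = []

    def design(names: Sequence[str]) -> np.ndarray:
        return np.column_stack([ones] + [cols[c][:, None] for c in names]) if names else ones

    while True:
        changed = False
        # entry
        remaining = [c for c in candidates if c not in model]
        if remaining and (cfg.max_terms is None or len(model) < cfg.max_terms):
            base = design(model)
            entry_p = {c: _partial_f_p(yv, base, cols[c][:, None]) for c in remaining}
            best = min(remaining, key=lambda c: (entry_p[c], candidates.index(c)))
            if entry_p[best] < cfg.slentry:
                model.append(best)
                visited.append(list(model))
                changed = True
        # removal (worst first, repeat until all stay)
        while model:
            stay_p = {}
            for c in model:
                others = [x for x in model if x != c]
                stay_p[c] = _partial_f_p(yv, design(others), cols[c][:, None])
            worst = max(model, key=lambda c: (stay_p[c], -candidates.index(c)))
            if stay_p[worst] > cfg.slstay:
                model.remove(worst)
                if model:
                    visited.append(list(model))
                changed = True
            else:
                break
        if not changed:
            break

    if not visited:
        warnings.warn(
            "no candidate cleared SLENTRY; returning intercept-only model",
            DataQualityWarning,
            stacklevel=2,
        )
        return [ols_fit(y, table[[]])]

    unique = []
    seen = set()
    for names in visited:
        key = tuple(names)
        if key not in seen:
            seen.add(key)
            unique.append(names)
    models = [ols_fit(y, table[list(names)]) for names in unique]
    models.sort(key=lambda m: (not m.significant, -m.r2, m.rmse))
    return models
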