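"""Linking landscape predictors to genetic responses by multimodel inference.

The analysis chain mirrors standard practice in landscape genetics with few
analysis units: (1) pick each predictor's *scale of effect* — the buffer
radius at which a simple linear model explains the response best (highest
R^2); (2) drop collinear predictors by iterative VIF filtering (threshold 5);
(3) fit Gaussian OLS candidate models plus an intercept-only null and rank
them by AICc with Akaike weights; (4) at the link level (five landscapes)
fall back on slope significance because n is too small for reliable AICc
ranking.

``k`` in AICc counts the intercept, the slopes and the residual variance.
No multiple-testing correction is applied across response variables (the
single-response tables are reported as-is, flagged accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScaleOfEffectResult",
    "scale_of_effect",
    "vif_filter",
    "fit_candidates",
    "link_significance",
    "LinkTestResult",
]


@dataclass
class ScaleOfEffectResult:
    response: str
    predictor: str
    r2_by_radius: dict[float, float]
    selected_radius: float


@dataclass
class LinkTestResult:
    slope: float
    p_value: float
    r2: float
    n: int
    small_n: bool


def _simple_r2(y: np.ndarray, x: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def scale_of_effect(
    response: pd.Series | np.ndarray,
    predictor_panel: pd.DataFrame,
    radii=None,
    response_name: str = "response",
    predictor_name: str = "predictor",
) -> ScaleOfEffectResult:
    """Radius at which a predictor best explains the response.

    ``predictor_panel`` has one column per radius (column labels are the
    radii in meters) and one row per analysis unit, aligned with
    ``response``.  Raw R^2 of the simple linear fit is the selection index;
    ties go to the smallest radius.  A constant predictor at some radius
    contributes R^2 = 0.
    """
    y = np.asarray(response, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 analysis units")
    cols = list(predictor_panel.columns) if radii is None else list(radii)
    r2 = {}
    for col in cols:
        x = np.asarray(predictor_panel[col], dtype=float)
        if x.size != y.size:
            raise ValueError("predictor and response lengths differ")
        r2[float(col)] = _simple_r2(y, x)
    best = max(sorted(r2), key=lambda rad: (r2[rad], -rad))
    return ScaleOfEffectResult(
        response=response_name,
        predictor=predictor_name,
        r2_by_radius=r2,
        selected_radius=best,
    )


def vif_filter(
    x: pd.DataFrame, threshold: float = 5.0
) -> tuple[list[str], list[dict[str, float]]]:
    """Iterative variance-inflation-factor elimination.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing predictor j on the others
    (with intercept).  While any VIF exceeds the threshold (strictly), the
    predictor with the largest VIF is dropped; ties break toward column
    declaration order.  Returns the retained column names and the per-step
    VIF tables.
    """
    cols = list(x.columns)
    if len(cols) < 2:
        return cols, []
    steps: list[dict[str, float]] = []
    while len(cols) >= 2:
        if len(x) <= len(cols):
            raise ValueError("need more units than predictors for VIF fits")
        vifs = {}
        for j, col in enumerate(cols):
            others = [c for c in cols if c != col]
            X = sm.add_constant(x[others].to_numpy(dtype=float))
            yj = x[col].to_numpy(dtype=float)
            res = sm.OLS(yj, X).fit()
            r2 = min(res.rsquared, 1.0)
            vifs[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        steps.append(dict(vifs))
        worst = max(vifs.values())
        if worst <= threshold:
            break
        drop = next(c for c in cols if vifs[c] == worst)
        cols.remove(drop)
    return cols, steps


def _aicc_ols(y: np.ndarray, X: np.ndarray | None) -> tuple[float, dict, int]:
    """AICc, coefficient dict and parameter count for a Gaussian OLS fit.

    ``X`` is the slope design (without intercept); ``None`` means the
    intercept-only null model.  k counts intercept + slopes + residual
    variance.
    """
    n = y.size
    design = sm.add_constant(X) if X is not None else np.ones((n, 1))
    res = sm.OLS(y, design).fit()
    k = design.shape[1] + 1
    if n - k - 1 <= 0:
        raise ValueError("n too small for AICc with this model")
    aic = -2.0 * res.llf + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    coefs = {f"b{i}": float(b) for i, b in enumerate(np.atleast_1d(res.params))}
    return float(aicc), coefs, k


def fit_candidates(
    response: pd.Series | np.ndarray,
    candidates: dict[str, pd.DataFrame | pd.Series | np.ndarray],
    include_null: bool = True,
) -> pd.DataFrame:
    """OLS candidate models ranked by AICc with Akaike weights.

    ``candidates`` maps model names to their predictor columns (a Series or
    single-column frame for simple regressions).  An intercept-only null
    model is added by default.  Output columns: AICc, dAICc, wAICc, n, k,
    plausible (dAICc < 2) and the fitted coefficients; the best model has
    dAICc = 0 and weights sum to 1.
    """
    y = np.asarray(response, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 analysis units")
    rows = []
    for name, xdata in candidates.items():
        X = np.asarray(xdata, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        try:
            aicc, coefs, k = _aicc_ols(y, X)
        except ValueError as err:
            warnings.warn(f"candidate {name!r} excluded: {err}")
            continue
        rows.append({"model": name, "AICc": aicc, "n": y.size, "k": k, "coefficients": coefs})
    if include_null:
        try:
            aicc, coefs, k = _aicc_ols(y, None)
            rows.append({"model": "null", "AICc": aicc, "n": y.size, "k": k, "coefficients": coefs})
        except ValueError as err:
            warnings.warn(f"null model excluded: {err}")
    if not rows:
        raise ValueError("no fittable candidate model")
    table = pd.DataFrame(rows)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    rel = np.exp(-table["dAICc"] / 2.0)
    table["wAICc"] = rel / rel.sum()
    table["plausible"] = table["dAICc"] < 2.0
    table = table.sort_values("AICc", kind="stable").reset_index(drop=True)
    return table[["model", "AICc", "dAICc", "wAICc", "n", "k", "plausible", "coefficients"]]


def link_significance(
    response: pd.Series | np.ndarray, predictor: pd.Series | np.ndarray
) -> LinkTestResult:
    """Slope t-test of a single-predictor OLS at the link level.

    With five landscapes AICc ranking is unstable, so model choice rests on
    slope significance; results with n < 8 carry a small-sample flag.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 landscapes")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinkTestResult(
        slope=float(res.params[1]),
        p_value=float(res.pvalues[1]),
        r2=float(res.rsquared),
        n=int(y.size),
        small_n=bool(y.size < 8),
    )
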