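"""Three-axis cumulative risk model.

Module average expression is residualized against nuisance covariates,
dichotomized at the median with direction-aware risk coding (an up-in-cases
module scores 1 above its median, a down-in-cases module scores 1 below),
and the per-sample count of risk-side modules (0..K) enters a logistic
model as a numeric additive predictor. The odds ratio for carrying k risk
modules is exp(k * beta); a likelihood-ratio test against the factor-coded
model measures departures from additivity (K - 1 extra df when all counts
are observed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .modules import residualize

__all__ = ["RiskModelResult", "residualize_modules", "dichotomize_and_count",
           "fit_additive_logistic", "additivity_lrt", "run_risk_model"]

RISK_NUISANCE = ("age_group", "sex", "site", "rin", "gc", "batch", "pc1", "pc2")


@dataclass
class RiskModelResult:
    indicators: pd.DataFrame      # samples x modules, 0/1
    count: pd.Series              # per-sample risk count 0..K
    beta: float                   # per-count log-odds
    se: float
    p_additive: float             # Wald p for the count coefficient
    odds_ratios: dict[int, tuple[float, float, float]]  # k -> (OR, lo, hi)
    fitted_by_count: dict[int, float]
    lrt_stat: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None


def residualize_modules(module_expr: pd.DataFrame, samples: pd.DataFrame,
                        nuisance: tuple[str, ...] = RISK_NUISANCE
                        ) -> pd.DataFrame:
    """OLS residuals of each module's expression against the nuisance design
    (intercept included; residuals mean-centred)."""
    v = residualize(module_expr.to_numpy(float),
                    samples.loc[module_expr.columns], nuisance)
    v = v - v.mean(axis=1, keepdims=True)
    return pd.DataFrame(v, index=module_expr.index, columns=module_expr.columns)


def dichotomize_and_count(corrected: pd.DataFrame,
                          directions: dict | pd.Series
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Direction-aware median dichotomy plus risk count.

    ``directions`` maps module label -> sign of its disease association
    (+1 up in cases, -1 down). Risk indicator is 1 strictly beyond the
    median on the risk side; ties at the median score 0.
    """
    ind = {}
    for mod in corrected.index:
        d = directions[mod]
        if d == 0:
            raise ValueError(
                f"module {mod}: direction 0; supply an explicit direction")
        vals = corrected.loc[mod]
        med = float(vals.median())
        if d > 0:
            ind[mod] = (vals > med).astype(int)
        else:
            ind[mod] = (vals < med).astype(int)
    indicators = pd.DataFrame(ind)
    count = indicators.sum(axis=1)
    count.name = "risk_count"
    return indicators, count


def fit_additive_logistic(count: pd.Series | np.ndarray,
                          status: pd.Series | np.ndarray,
                          k_max: int | None = None) -> RiskModelResult:
    """Logistic fit of disease status on the numeric risk count."""
    count = np.asarray(count, dtype=float)
    status = np.asarray(status, dtype=int)
    if len(set(status)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(count)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(status, X, family=sm.families.Binomial()).fit()
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError(f"logistic fit failed: {e}")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e3:
        raise ValueError("complete separation: count perfectly predicts status")
    k_max = k_max or int(count.max())
    ors = {}
    for k in range(1, k_max + 1):
        ors[k] = (float(np.exp(k * beta)),
                  float(np.exp(k * beta - 1.96 * k * se)),
                  float(np.exp(k * beta + 1.96 * k * se)))
    alpha = float(fit.params[0])
    fitted = {k: float(1.0 / (1.0 + np.exp(-(alpha + beta * k))))
              for k in sorted(set(count.astype(int)))}
    return RiskModelResult(
        indicators=None, count=pd.Series(count), beta=beta, se=se,
        p_additive=float(fit.pvalues[1]), odds_ratios=ors,
        fitted_by_count=fitted)


def additivity_lrt(count: pd.Series | np.ndarray,
                   status: pd.Series | np.ndarray
                   ) -> tuple[float | None, int, float | None]:
    """LRT of factor-coded vs numeric count logistic models.

    df = (#observed levels - 1) - 1; with fewer than 3 distinct counts the
    two models coincide and the test is skipped (df 0, stat/p None).
    """
    count = np.asarray(count, dtype=float)
    status = np.asarray(status, dtype=int)
    levels = sorted(set(count))
    df = (len(levels) - 1) - 1
    if df <= 0:
        warnings.warn("fewer than 3 observed count levels; "
                      "additivity test skipped")
        return None, 0, None
    for lev in levels:
        cls = set(status[count == lev])
        if len(cls) < 2:
            warnings.warn(f"count level {int(lev)} contains a single outcome "
                          "class; factor fit may separate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xn = sm.add_constant(count)
        ll_num = sm.GLM(status, Xn, family=sm.families.Binomial()).fit().llf
        F = np.column_stack([np.ones_like(count)] +
                            [(count == lev).astype(float)
                             for lev in levels[1:]])
        ll_fac = sm.GLM(status, F, family=sm.families.Binomial()).fit().llf
    stat = float(max(2.0 * (ll_fac - ll_num), 0.0))
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def run_risk_model(module_expr: pd.DataFrame, samples: pd.DataFrame,
                   module_de: pd.DataFrame,
                   modules: list | None = None,
                   k_axes: int = 3,
                   nuisance: tuple[str, ...] = RISK_NUISANCE
                   ) -> RiskModelResult:
    """End-to-end risk stage.

    Default module selection: the ``k_axes`` most significant modules by
    q-value in the module-DE table; directions come from the sign of their
    module-DE log2fc.
    """
    de = module_de.set_index("module")
    if modules is None:
        modules = list(de.sort_values(["q", "p"]).index[:k_axes])
    directions = {m: int(np.sign(de.loc[m, "log2fc"])) for m in modules}
    corrected = residualize_modules(module_expr.loc[modules], samples, nuisance)
    indicators, count = dichotomize_and_count(corrected, directions)
    status = samples.loc[count.index, "case"]
    res = fit_additive_logistic(count, status, k_max=len(modules))
    res.indicators = indicators
    res.count = count
    res.lrt_stat, res.lrt_df, res.lrt_p = additivity_lrt(count, status)
    return res
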