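"""Information criteria, Kolmogorov-Smirnov and Anderson-Darling statistics,
and the six-model comparison table.

Criteria follow the conventions that make the real-data benchmark tables
internally consistent:

    AIC  = 2k - 2*loglik
    BIC  = k*ln(n) - 2*loglik
    CAIC = AIC + 2k(k+1)/(n - k - 1)      (small-sample corrected AIC)
    HQIC = 2k*ln(ln n) - 2*loglik

K-S p-values come from the parameter-free one-sample Kolmogorov null
(scipy.stats.kstwo, exact at these sample sizes).  No adjustment is made
for the parameters having been estimated from the same data, so the
p-values are optimistic screening values, not calibrated test levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import LifetimeSample
from .estimation import FitConfig, FitResult, fit
from .families import FAMILY_ORDER, get_family

__all__ = [
    "information_criteria",
    "ks_statistic",
    "ks_pvalue",
    "ad_statistic",
    "GofReport",
    "gof_report",
    "compare_models",
]

_CLAMP = 1e-15


def information_criteria(loglik: float, k: int, n: int):
    """(AIC, BIC, CAIC, HQIC) from a maximized log-likelihood.

    CAIC requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"CAIC undefined for n={n} <= k+1={k + 1}")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n) - 2.0 * loglik
    caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    hqic = 2.0 * k * math.log(math.log(n)) - 2.0 * loglik
    return aic, bic, caic, hqic


def _fitted_F(data, cdf_fn):
    x = data.values if isinstance(data, LifetimeSample) else np.sort(np.asarray(data, float))
    return x.size, np.asarray(cdf_fn(x), dtype=float)


def ks_statistic(data, cdf_fn) -> float:
    """One-sample K-S statistic D = max_i max(i/n - F_i, F_i - (i-1)/n)."""
    n, F = _fitted_F(data, cdf_fn)
    i = np.arange(1, n + 1)
    d_plus = i / n - F
    d_minus = F - (i - 1) / n
    return float(max(d_plus.max(), d_minus.max()))


def ks_pvalue(d: float, n: int) -> float:
    """Two-sided p-value of the one-sample Kolmogorov null distribution."""
    return float(stats.kstwo.sf(d, n))


def ad_statistic(data, cdf_fn) -> float:
    """Anderson-Darling A^2 against a fully specified fitted CDF.

    F values numerically at 0 or 1 are clamped to [1e-15, 1 - 1e-15] with a
    warning (the statistic is infinite in exact arithmetic there).
    """
    n, F = _fitted_F(data, cdf_fn)
    if np.any(F <= 0) or np.any(F >= 1):
        warnings.warn("fitted CDF hit 0 or 1 at a data point; clamping for A-D")
    F = np.clip(F, _CLAMP, 1.0 - _CLAMP)
    i = np.arange(1, n + 1)
    s = np.sum((2 * i - 1) * (np.log(F) + np.log1p(-F[::-1])))
    return float(-n - s / n)


@dataclass
class GofReport:
    """Per-model goodness-of-fit summary row.

    ``L`` is the magnitude of the maximized log-likelihood (the positive
    number the benchmark tables print).
    """

    model: str
    L: float
    AIC: float
    BIC: float
    CAIC: float
    HQIC: float
    KS: float
    p_value: float
    AD: float
    converged: bool = True
    params: Optional[np.ndarray] = None

    def to_row(self) -> dict:
        d = asdict(self)
        d.pop("params")
        d.pop("converged")
        return d


def gof_report(data, fit_result: FitResult) -> GofReport:
    """Assemble the full GoF row for an MLE fit."""
    fam = get_family(fit_result.model)
    n = len(data)
    loglik = fit_result.loglik
    aic, bic, caic, hqic = information_criteria(loglik, fam.k, n)
    cdf_fn = lambda x: fam.cdf(x, fit_result.params)
    d = ks_statistic(data, cdf_fn)
    return GofReport(
        model=fit_result.model,
        L=-loglik,
        AIC=aic,
        BIC=bic,
        CAIC=caic,
        HQIC=hqic,
        KS=d,
        p_value=ks_pvalue(d, n),
        AD=ad_statistic(data, cdf_fn),
        converged=fit_result.converged,
        params=fit_result.params,
    )


@dataclass
class ComparisonTable:
    """Six-model GoF comparison: a DataFrame of criteria plus the fitted
    per-model reports and the best model under each criterion."""

    table: pd.DataFrame
    reports: dict
    best: dict

    def __getitem__(self, col):
        return self.table[col]

    def to_csv(self, path, float_format="%.6g"):
        self.table.to_csv(path, float_format=float_format)

    def __repr__(self):  # pragma: no cover - cosmetic
        return repr(self.table)


def compare_models(data, models: Sequence[str] = FAMILY_ORDER,
                   config: Optional[FitConfig] = None) -> ComparisonTable:
    """Fit each family by MLE and tabulate L, AIC, BIC, CAIC, HQIC, K-S
    (+p), A-D; rows in the canonical order; per-model failures are recorded
    as NaN rows rather than aborting the table.
    """
    config = config or FitConfig()
    rows = []
    fitted = {}
    for name in models:
        try:
            fr = fit(data, name, "mle", config)
            rep = gof_report(data, fr)
            fitted[name] = rep
            rows.append(rep.to_row())
        except Exception as exc:  # noqa: BLE001 - table must survive one bad model
            warnings.warn(f"fit failed for {name}: {exc}")
            rows.append({"model": name, "L": np.nan, "AIC": np.nan, "BIC": np.nan,
                         "CAIC": np.nan, "HQIC": np.nan, "KS": np.nan,
                         "p_value": np.nan, "AD": np.nan})
    df = pd.DataFrame(rows).set_index("model")
    best = {c: df[c].idxmin() for c in ("AIC", "BIC", "CAIC", "HQIC", "KS", "AD")}
    if df["p_value"].notna().any():
        best["p_value"] = df["p_value"].idxmax()
    return ComparisonTable(table=df, reports=fitted, best=best)
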