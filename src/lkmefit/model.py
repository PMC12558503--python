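"""Model/Results surface for fitting lifetime families to samples.

Follows the familiar two-object pattern: build a :class:`LifetimeModel`
from data (an array, a :class:`~lkmefit.distribution.LifetimeSample`, a
DataFrame column, or a packaged dataset), call ``fit`` and work with the
returned :class:`LifetimeResults` — estimated parameters, the achieved
objective, information criteria and distance diagnostics, and a printable
``summary()``.

Example
-------
>>> import lkmefit
>>> model = lkmefit.LifetimeModel.from_dataset("service_time")
>>> res = model.fit(seed=7)
>>> round(res.aic, 2)                                    # doctest: +SKIP
208.3
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distribution import LifetimeSample, LkmeParams
from .estimation import METHODS, FitConfig, FitResult, fit as _fit
from .families import FAMILY_ORDER, Family, get_family
from . import gof as _gof
from . import datasets as _datasets

__all__ = ["LifetimeModel", "LifetimeResults", "compare_models"]


class LifetimeModel:
    """A parametric lifetime model attached to a univariate sample.

    Parameters
    ----------
    data : array-like, LifetimeSample or DataFrame
        Positive event times.  DataFrames use ``column`` (default: first).
    family : str
        One of ``lkme``, ``lomax``, ``kme``, ``kmge``, ``kmilbe``, ``aptgl``.
    """

    def __init__(self, data, family: str = "lkme", column=None, name=None):
        if isinstance(data, LifetimeSample):
            self.sample = data
        elif isinstance(data, pd.DataFrame):
            col = column if column is not None else data.columns[0]
            self.sample = LifetimeSample(data[col].dropna().to_numpy(),
                                         name=name or str(col))
        else:
            self.sample = LifetimeSample(data, name=name or "data")
        self.family: Family = family if isinstance(family, Family) else get_family(family)

    @classmethod
    def from_dataset(cls, key: str, family: str = "lkme") -> "LifetimeModel":
        """Build a model on one of the packaged benchmark datasets."""
        return cls(_datasets.load_dataset(key), family=family)

    @classmethod
    def from_file(cls, path, family: str = "lkme", column=None) -> "LifetimeModel":
        return cls(_datasets.read_sample(path, column=column), family=family)

    @property
    def endog(self) -> np.ndarray:
        return self.sample.values

    @property
    def nobs(self) -> int:
        return self.sample.n

    def loglike(self, params) -> float:
        """Log-likelihood at an arbitrary parameter vector."""
        from .estimation import neg_log_likelihood

        return -neg_log_likelihood(params, self.sample, self.family)

    def fit(self, method: str = "mle", *, seed: int = 0, n_starts: int = 40,
            start_params=None, config: Optional[FitConfig] = None) -> "LifetimeResults":
        """Fit by one of mle, pe, lse, wls, cvm (multi-start, deterministic
        for a given seed).  ``start_params`` pins a single start instead."""
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        cfg = config or FitConfig(n_starts=n_starts, seed=seed,
                                  x0=None if start_params is None else np.asarray(start_params))
        return LifetimeResults(self, _fit(self.sample, self.family, method, cfg))


class LifetimeResults:
    """Estimates and diagnostics from a LifetimeModel fit."""

    def __init__(self, model: LifetimeModel, raw: FitResult):
        self.model = model
        self._raw = raw
        self.params = raw.params
        self.method = raw.method
        self.converged = raw.converged
        self.objective = raw.objective

    # ---- parameter views -------------------------------------------
    @property
    def param_names(self):
        return self.model.family.param_names

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, map(float, self.params)))

    @property
    def lkme_params(self) -> LkmeParams:
        if self.model.family.name != "lkme":
            raise AttributeError("lkme_params only available for the lkme family")
        return LkmeParams(*self.params)

    @property
    def identifiable_compound(self) -> float:
        """beta/theta**alpha for LKME fits — the ridge-invariant rate."""
        return self.lkme_params.compound

    # ---- likelihood-based diagnostics ------------------------------
    @property
    def loglike(self) -> float:
        if self.method == "mle":
            return self.objective
        return self.model.loglike(self.params)

    @property
    def aic(self) -> float:
        return self._ic[0]

    @property
    def bic(self) -> float:
        return self._ic[1]

    @property
    def caic(self) -> float:
        return self._ic[2]

    @property
    def hqic(self) -> float:
        return self._ic[3]

    @property
    def _ic(self):
        return _gof.information_criteria(self.loglike, self.model.family.k,
                                         self.model.nobs)

    # ---- distance diagnostics --------------------------------------
    def _cdf_fn(self):
        fam, p = self.model.family, self.params
        return lambda x: fam.cdf(x, p)

    @property
    def ks_statistic(self) -> float:
        return _gof.ks_statistic(self.model.sample, self._cdf_fn())

    @property
    def ks_pvalue(self) -> float:
        return _gof.ks_pvalue(self.ks_statistic, self.model.nobs)

    @property
    def ad_statistic(self) -> float:
        return _gof.ad_statistic(self.model.sample, self._cdf_fn())

    def gof_report(self) -> "_gof.GofReport":
        if self.method != "mle":
            raise ValueError("GoF report is defined for mle fits")
        return _gof.gof_report(self.model.sample, self._raw)

    # ---- evaluation ------------------------------------------------
    def predict_cdf(self, x):
        return self.model.family.cdf(x, self.params)

    def predict_pdf(self, x):
        return self.model.family.pdf(x, self.params)

    def curves(self, n_grid: int = 200) -> pd.DataFrame:
        """(x, fitted pdf, fitted cdf, ecdf) grid for external plotting."""
        xs = self.model.endog
        grid = np.linspace(0.0, xs.max() * 1.05, n_grid)
        ecdf_x = np.searchsorted(xs, grid, side="right") / xs.size
        return pd.DataFrame({
            "x": grid,
            "pdf": np.asarray(self.predict_pdf(grid)),
            "cdf": np.asarray(self.predict_cdf(grid)),
            "ecdf": ecdf_x,
        })

    def to_dict(self) -> dict:
        out = {
            "model": self.model.family.name,
            "method": self.method,
            "n": self.model.nobs,
            "params": self.params_dict(),
            "objective": float(self.objective),
            "loglike": float(self.loglike),
            "converged": bool(self.converged),
            "n_starts": self._raw.n_starts,
        }
        if self.model.family.name == "lkme":
            out["compound_beta_over_theta_alpha"] = float(self.identifiable_compound)
        return out

    def summary(self) -> str:
        fam = self.model.family
        lines = [
            f"{'Lifetime fit results':^60}",
            "=" * 60,
            f"family: {fam.name:<12} method: {self.method:<6} "
            f"n: {self.model.nobs:<6} converged: {self.converged}",
            f"data:   {self.model.sample.name}",
            "-" * 60,
        ]
        for nm, v in self.params_dict().items():
            lines.append(f"  {nm:<10} {v:>14.6g}")
        if fam.name == "lkme":
            lines.append(f"  {'beta/theta^alpha':<16} {self.identifiable_compound:>8.6g}"
                         "   (identifiable compound)")
        lines.append("-" * 60)
        if self.method == "mle":
            lines.append(f"  loglik {self.loglike:>12.4f}   AIC  {self.aic:>10.4f}"
                         f"   BIC  {self.bic:>10.4f}")
            lines.append(f"  CAIC  {self.caic:>13.4f}   HQIC {self.hqic:>10.4f}")
        else:
            lines.append(f"  objective ({self.method}) {self.objective:>12.6g}")
        lines.append(f"  K-S   {self.ks_statistic:>13.4f}   p    {self.ks_pvalue:>10.4f}"
                     f"   A-D  {self.ad_statistic:>10.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"<LifetimeResults {self.model.family.name}/{self.method} "
                f"objective={self.objective:.6g}>")


def compare_models(data, models: Sequence[str] = FAMILY_ORDER, *,
                   seed: int = 0, n_starts: int = 40,
                   config: Optional[FitConfig] = None) -> "_gof.ComparisonTable":
    """Fit every family by MLE and return the GoF comparison table."""
    if not isinstance(data, LifetimeSample):
        data = LifetimeSample(data)
    cfg = config or FitConfig(n_starts=n_starts, seed=seed)
    return _gof.compare_models(data, models, cfg)
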