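"""Closed-form evaluation of the Lomax Kavya-Manoharan exponential (LKME) law.

The LKME distribution arises by pushing the Kavya-Manoharan exponential
baseline through the Lomax-type generator argument ``z = (x + lam) / theta``
raised to the shape ``alpha``.  With ``t = exp(-beta * z**alpha)`` the
distribution function on ``x >= -lam`` is

    F(x) = e/(e-1) * [1 - exp(-(1 - t))],
    S(x) = (exp(t) - 1)/(e - 1),
    f(x) = alpha*beta/(theta*(e-1)) * z**(alpha-1) * t * exp(t).

``alpha`` controls the shape (density can be inverted-J, right- or
left-skewed), ``beta`` is a rate-like shape, ``theta`` a scale in data units
and ``lam`` a location shift; the support is ``x >= -lam``.

The pair ``(beta, theta)`` is not separately identifiable: for any s > 0 the
parameter vectors ``(alpha, beta*s**alpha, theta*s, lam)`` and
``(alpha, beta, theta, lam)`` define the same distribution, because the two
enter only through the compound ``beta / theta**alpha``.  Evaluation code is
exact on this ridge; the consequences for fitting live in
:mod:`lkmefit.estimation`.

All functions are vectorized over ``x`` / ``p`` and take an
:class:`LkmeParams` (or anything unpackable into four floats).
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "LkmeParams",
    "LifetimeSample",
    "cdf",
    "pdf",
    "log_pdf",
    "survival",
    "hazard",
    "quantile",
    "median",
    "sample",
    "identifiable_compound",
]

_E = math.e
_EM1 = math.e - 1.0
_LOG_EM1 = math.log(_EM1)


class LkmeParams(NamedTuple):
    """Parameter vector (alpha, beta, theta, lam) of the LKME distribution.

    alpha, beta, theta must be strictly positive; lam shifts the support to
    ``x >= -lam`` and may be any real as long as the data it is paired with
    stay inside the support.
    """

    alpha: float
    beta: float
    theta: float
    lam: float

    def validate(self) -> "LkmeParams":
        a, b, t, lam = map(float, self)
        if not (a > 0 and b > 0 and t > 0):
            raise ValueError(
                f"alpha, beta, theta must be > 0, got ({a}, {b}, {t})"
            )
        if not all(map(math.isfinite, (a, b, t, lam))):
            raise ValueError("parameters must be finite")
        return LkmeParams(a, b, t, lam)

    @property
    def compound(self) -> float:
        """The identifiable rate compound beta / theta**alpha."""
        return self.beta / self.theta**self.alpha


class LifetimeSample:
    """A validated univariate sample of event times.

    Values are stored sorted ascending; a provenance ``name`` travels with
    the sample so reports can label their inputs.
    """

    def __init__(self, values, name: str = "sample"):
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("sample must contain at least one observation")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample contains non-finite values")
        self.values = np.sort(arr)
        self.name = str(name)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LifetimeSample(name={self.name!r}, n={self.n})"


def _z(x, params: LkmeParams):
    a, b, t, lam = params
    return (np.asarray(x, dtype=float) + lam) / t


def cdf(x, params: LkmeParams):
    """Distribution function F(x); 0 below the support bound ``-lam``."""
    params = LkmeParams(*params).validate()
    z = _z(x, params)
    zc = np.clip(z, 0.0, None)
    # u = 1 - exp(-beta z^alpha) in [0, 1]
    u = -np.expm1(-params.beta * zc**params.alpha)
    out = (_E / _EM1) * (-np.expm1(-u))
    out = np.where(z < 0, 0.0, out)
    return out if out.ndim else float(out)

def survival(x, params: LkmeParams):
    """S(x) = (exp(exp(-beta z^alpha)) - 1)/(e - 1); 1 below the support."""
    params = LkmeParams(*params).validate()
    z = _z(x, params)
    zc = np.clip(z, 0.0, None)
    t = np.exp(-params.beta * zc**params.alpha)
    out = np.expm1(t) / _EM1
    out = np.where(z < 0, 1.0, out)
    return out if out.ndim else float(out)


def log_pdf(x, params: LkmeParams):
    """log f(x); -inf outside the support (so optimizers can reject).

    At the boundary x = -lam the density limit is 0 for alpha > 1 (log ->
    -inf), alpha*beta*e/(theta*(e-1)) for alpha = 1, and +inf for alpha < 1;
    the log follows those limits.
    """
    params = LkmeParams(*params).validate()
    a, b, th, _ = params
    z = _z(x, params)
    zc = np.clip(z, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        logz = np.log(zc)
        bza = b * zc**a
        shape_term = (a - 1.0) * logz
        # alpha == 1 kills the z^{alpha-1} factor exactly, even at z = 0
        if a == 1.0:
            shape_term = np.zeros_like(zc)
        out = (
            math.log(a)
            + math.log(b)
            - math.log(th)
            - _LOG_EM1
            + shape_term
            - bza
            + np.exp(-bza)
        )
    out = np.where(z < 0, -np.inf, out)
    return out if out.ndim else float(out)


def pdf(x, params: LkmeParams):
    """Density f(x) >= 0; 0 outside the support, +inf at -lam when alpha<1."""
    out = np.exp(log_pdf(x, params))
    return out if np.ndim(out) else float(out)


def hazard(x, params: LkmeParams):
    """Hazard rate H(x) = f(x)/S(x), computed in log space.

    For large x both f and S underflow; the ratio stays finite (it tends to
    (alpha*beta/theta) z^{alpha-1}), so log S falls back to its asymptote
    log t - log(e-1) when exp(t)-1 underflows.
    """
    params = LkmeParams(*params).validate()
    z = _z(x, params)
    zc = np.clip(z, 0.0, None)
    bza = params.beta * zc**params.alpha
    t = np.exp(-bza)
    with np.errstate(divide="ignore"):
        log_sf = np.where(t > 0, np.log(np.expm1(np.clip(t, 1e-300, None))), -bza)
        log_sf = log_sf - _LOG_EM1
        out = np.exp(log_pdf(x, params) - log_sf)
    out = np.where(z < 0, 0.0, out)
    return out if out.ndim else float(out)


def quantile(p, params: LkmeParams):
    """Inverse distribution function on (0, 1).

    x_p = theta * [-(1/beta) ln(1 + ln(1 - ((e-1)/e) p))]^{1/alpha} - lam.
    p = 0 maps to -lam and p = 1 to +inf (closed-interval endpoints are
    honoured rather than rejected); p outside [0, 1] raises.
    """
    params = LkmeParams(*params).validate()
    a, b, th, lam = params
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.log1p(-(_EM1 / _E) * p)      # ln(1 - ((e-1)/e) p) in (-1, 0]
        inner = np.log1p(q)                  # -> -inf as p -> 1
        out = th * (-inner / b) ** (1.0 / a) - lam
    out = np.where(p == 1.0, np.inf, out)
    return out if out.ndim else float(out)


def median(params: LkmeParams) -> float:
    """The distribution median, quantile(0.5)."""
    return float(quantile(0.5, params))


def sample(params: LkmeParams, n: int, seed, name: str = "lkme-sample") -> LifetimeSample:
    """Draw n i.i.d. variates by inverse-transform sampling.

    ``p`` is drawn Uniform(0,1) from a seeded Generator and pushed through
    the quantile function; the same seed always reproduces the same sample.
    ``seed`` may be an int or a numpy SeedSequence/Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = LkmeParams(*params).validate()
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=int(n))
    return LifetimeSample(quantile(u, params), name=name)


def identifiable_compound(params: LkmeParams) -> float:
    """beta / theta**alpha — the only way (beta, theta) enter the law."""
    return LkmeParams(*params).compound
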