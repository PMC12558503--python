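"""Parametric lifetime families behind one fitting/GoF interface.

Six families share the interface: the four-parameter LKME itself and the
five comparison distributions used in the real-data benchmark — Lomax, the
Kavya-Manoharan exponential (KME), the KM generalized exponential (KMGE),
the KM inverse length-biased exponential (KMILBE) and the alpha power
transformed generalized Lomax (APTGL).

Each family packages its name, parameter count, parameter names, cdf and
log-pdf over a flat parameter vector, a support check, and a seeded
generator of optimizer start points.  The KM transform shared by KME, KMGE
and KMILBE maps a baseline CDF G to e/(e-1)*(1 - exp(-G)), with density
e/(e-1)*g*exp(-G).

A note on KMILBE: its baseline is the *inverse* length-biased exponential,
G(x) = (1 + theta/x) * exp(-theta/x), which rises from 0 at the origin to 1
at infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import distribution as lkme

__all__ = ["Family", "get_family", "FAMILY_ORDER", "FAMILIES"]

_E = math.e
_EM1 = math.e - 1.0
_LOG_E_EM1 = 1.0 - math.log(_EM1)  # log(e/(e-1))


@dataclass(frozen=True)
class Family:
    """A parametric lifetime model: name, dimension and function surface."""

    name: str
    k: int
    param_names: tuple
    cdf: Callable
    log_pdf: Callable
    start_points: Callable  # (x: ndarray, n_starts, rng) -> ndarray (n_starts, k)
    bounds: Callable        # (x: ndarray) -> list of (lo, hi) in optimization space
    description: str = ""

    def pdf(self, x, params):
        return np.exp(self.log_pdf(x, params))

    def valid(self, params) -> bool:
        p = np.asarray(params, dtype=float)
        return p.size == self.k and bool(np.all(np.isfinite(p)))


def _km_log_pdf(logg, G):
    # log of e/(e-1) * g * exp(-G)
    return _LOG_E_EM1 + logg - G


def _km_cdf(G):
    return (_E / _EM1) * (-np.expm1(-np.asarray(G, dtype=float)))


# ---------------------------------------------------------------- LKME

def _lkme_cdf(x, params):
    return lkme.cdf(x, lkme.LkmeParams(*params))


def _lkme_log_pdf(x, params):
    return lkme.log_pdf(x, lkme.LkmeParams(*params))


def lkme_lambda_lower(x) -> float:
    """Data-driven lower bound for the LKME location: -min(x) + eps with
    eps = 1e-6 * range(x), keeping the support edge an epsilon-gap away from
    the smallest observation (the likelihood is unbounded at the edge when
    alpha < 1)."""
    x = np.asarray(x, dtype=float)
    eps = 1e-6 * max(float(np.ptp(x)), 1e-12)
    return -float(np.min(x)) + eps


def _lkme_starts(x, n_starts, rng):
    """Quasi-random start box scaled to the sample: alpha in [0.3, 8],
    beta in [0.01, 20], theta in [0.1, 10] x IQR, lam in
    [lambda_lower, median]."""
    x = np.asarray(x, dtype=float)
    iqr = max(np.subtract(*np.percentile(x, [75, 25])), 1e-3 * np.median(x), 1e-6)
    starts = np.empty((n_starts, 4))
    starts[:, 0] = np.exp(rng.uniform(np.log(0.3), np.log(8.0), n_starts))
    starts[:, 1] = np.exp(rng.uniform(np.log(0.01), np.log(20.0), n_starts))
    starts[:, 2] = np.exp(rng.uniform(np.log(0.1 * iqr), np.log(10.0 * iqr), n_starts))
    starts[:, 3] = rng.uniform(lkme_lambda_lower(x), np.median(x), n_starts)
    # one deterministic anchor: moment-ish guess at the sample scale
    starts[0] = (1.5, 1.0, np.median(x), 0.0)
    return starts


def _lkme_bounds(x):
    return [(1e-3, 50.0), (1e-6, 1e4), (1e-6, 1e4),
            (lkme_lambda_lower(x), float(np.max(x)))]


# ---------------------------------------------------------------- Lomax

def _lomax_cdf(x, params):
    th, lam = params
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, 0.0, -np.expm1(-th * np.log1p(np.clip(x, 0, None) / lam)))


def _lomax_log_pdf(x, params):
    th, lam = params
    x = np.asarray(x, dtype=float)
    out = math.log(th) - math.log(lam) - (th + 1.0) * np.log1p(np.clip(x, 0, None) / lam)
    return np.where(x < 0, -np.inf, out)


def _lomax_starts(x, n_starts, rng):
    m = float(np.mean(x))
    starts = np.empty((n_starts, 2))
    starts[:, 0] = np.exp(rng.uniform(np.log(0.2), np.log(50.0), n_starts))
    starts[:, 1] = np.exp(rng.uniform(np.log(0.05 * m), np.log(50.0 * m), n_starts))
    starts[0] = (2.0, m)
    return starts


def _lomax_bounds(x):
    hi = 1e6 * float(np.mean(x))
    return [(1e-3, 1e4), (1e-6, hi)]


# ---------------------------------------------------------------- KME

def _kme_cdf(x, params):
    (beta,) = params
    x = np.asarray(x, dtype=float)
    G = -np.expm1(-beta * np.clip(x, 0, None))
    return np.where(x < 0, 0.0, _km_cdf(G))


def _kme_log_pdf(x, params):
    (beta,) = params
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 0, None)
    G = -np.expm1(-beta * xc)
    out = _km_log_pdf(math.log(beta) - beta * xc, G)
    return np.where(x < 0, -np.inf, out)


def _kme_starts(x, n_starts, rng):
    m = float(np.mean(x))
    starts = np.exp(rng.uniform(np.log(0.05 / m), np.log(20.0 / m), (n_starts, 1)))
    starts[0, 0] = 1.0 / m
    return starts


def _kme_bounds(x):
    return [(1e-8, 1e6)]


# ---------------------------------------------------------------- KMGE

def _kmge_cdf(x, params):
    th, lam = params
    x = np.asarray(x, dtype=float)
    G = (-np.expm1(-lam * np.clip(x, 0, None))) ** th
    return np.where(x < 0, 0.0, _km_cdf(G))


def _kmge_log_pdf(x, params):
    th, lam = params
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 1e-300, None)
    u = -np.expm1(-lam * xc)  # in (0, 1)
    with np.errstate(divide="ignore"):
        logg = math.log(th) + math.log(lam) + (th - 1.0) * np.log(u) - lam * xc
    out = _km_log_pdf(logg, u**th)
    return np.where(x <= 0, -np.inf, out)


def _kmge_starts(x, n_starts, rng):
    m = float(np.mean(x))
    starts = np.empty((n_starts, 2))
    starts[:, 0] = np.exp(rng.uniform(np.log(0.2), np.log(50.0), n_starts))
    starts[:, 1] = np.exp(rng.uniform(np.log(0.05 / m), np.log(20.0 / m), n_starts))
    starts[0] = (1.0, 1.0 / m)
    return starts


def _kmge_bounds(x):
    return [(1e-3, 1e4), (1e-8, 1e6)]


# ---------------------------------------------------------------- KMILBE

def _kmilbe_G(x, theta):
    xc = np.clip(np.asarray(x, dtype=float), 1e-300, None)
    v = theta / xc
    return (1.0 + v) * np.exp(-v)


def _kmilbe_cdf(x, params):
    (th,) = params
    x = np.asarray(x, dtype=float)
    return np.where(x <= 0, 0.0, _km_cdf(_kmilbe_G(x, th)))


def _kmilbe_log_pdf(x, params):
    # g(x) = theta^2 / x^3 * exp(-theta/x)
    (th,) = params
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 1e-300, None)
    logg = 2.0 * math.log(th) - 3.0 * np.log(xc) - th / xc
    out = _km_log_pdf(logg, _kmilbe_G(x, th))
    return np.where(x <= 0, -np.inf, out)


def _kmilbe_starts(x, n_starts, rng):
    m = float(np.mean(x))
    starts = np.exp(rng.uniform(np.log(0.05 * m), np.log(20.0 * m), (n_starts, 1)))
    starts[0, 0] = m
    return starts


def _kmilbe_bounds(x):
    return [(1e-8, 1e8)]


# ---------------------------------------------------------------- APTGL

def _aptgl_W(x, beta, th, lam):
    xc = np.clip(np.asarray(x, dtype=float), 0, None)
    base = -np.expm1(-th * np.log1p(xc / lam))  # Lomax CDF, in [0, 1)
    return base**beta


def _aptgl_cdf(x, params):
    a, b, th, lam = params
    x = np.asarray(x, dtype=float)
    W = _aptgl_W(x, b, th, lam)
    L = math.log(a)
    if abs(L) < 1e-12:
        out = W
    else:
        out = np.expm1(W * L) / math.expm1(L)
    return np.where(x < 0, 0.0, out)


def _aptgl_log_pdf(x, params):
    # f = (ln a / (a - 1)) * a^W * W'(x), continuous limit W'(x) at a -> 1
    a, b, th, lam = params
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 1e-300, None)
    base = -np.expm1(-th * np.log1p(xc / lam))
    base = np.clip(base, 1e-300, 1.0)
    log_wprime = (
        math.log(b)
        + (b - 1.0) * np.log(base)
        + math.log(th)
        - math.log(lam)
        - (th + 1.0) * np.log1p(xc / lam)
    )
    L = math.log(a)
    if abs(L) < 1e-12:
        log_front = 0.0
        Wl = 0.0
    else:
        log_front = math.log(L / math.expm1(L))
        Wl = base**b * L
    out = log_front + Wl + log_wprime
    return np.where(x <= 0, -np.inf, out)


def _aptgl_starts(x, n_starts, rng):
    m = float(np.mean(x))
    starts = np.empty((n_starts, 4))
    starts[:, 0] = np.exp(rng.uniform(np.log(0.05), np.log(50.0), n_starts))
    starts[:, 1] = np.exp(rng.uniform(np.log(0.2), np.log(20.0), n_starts))
    starts[:, 2] = np.exp(rng.uniform(np.log(0.2), np.log(50.0), n_starts))
    starts[:, 3] = np.exp(rng.uniform(np.log(0.05 * m), np.log(50.0 * m), n_starts))
    starts[0] = (1.0, 1.0, 2.0, m)
    return starts


def _aptgl_bounds(x):
    hi = 1e6 * float(np.mean(x))
    return [(1e-4, 1e4), (1e-3, 1e3), (1e-3, 1e4), (1e-6, hi)]


FAMILIES = {
    "lkme": Family(
        "lkme", 4, ("alpha", "beta", "theta", "lambda"),
        _lkme_cdf, _lkme_log_pdf, _lkme_starts, _lkme_bounds,
        "Lomax Kavya-Manoharan exponential",
    ),
    "lomax": Family(
        "lomax", 2, ("theta", "lambda"),
        _lomax_cdf, _lomax_log_pdf, _lomax_starts, _lomax_bounds,
        "Lomax (Pareto II)",
    ),
    "kme": Family(
        "kme", 1, ("beta",),
        _kme_cdf, _kme_log_pdf, _kme_starts, _kme_bounds,
        "Kavya-Manoharan exponential",
    ),
    "kmge": Family(
        "kmge", 2, ("theta", "lambda"),
        _kmge_cdf, _kmge_log_pdf, _kmge_starts, _kmge_bounds,
        "Kavya-Manoharan generalized exponential",
    ),
    "kmilbe": Family(
        "kmilbe", 1, ("theta",),
        _kmilbe_cdf, _kmilbe_log_pdf, _kmilbe_starts, _kmilbe_bounds,
        "Kavya-Manoharan inverse length-biased exponential",
    ),
    "aptgl": Family(
        "aptgl", 4, ("alpha", "beta", "theta", "lambda"),
        _aptgl_cdf, _aptgl_log_pdf, _aptgl_starts, _aptgl_bounds,
        "alpha power transformed generalized Lomax",
    ),
}

#: Presentation order used by the comparison tables.
FAMILY_ORDER = ("lkme", "lomax", "kme", "kmge", "kmilbe", "aptgl")


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; available: {', '.join(FAMILY_ORDER)}"
        ) from None
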