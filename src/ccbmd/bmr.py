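"""Benchmark-response definitions and benchmark-dose inversion.

Because epidemiological populations carry background exposure, the benchmark
dose is measured from the referent group's exposure midpoint d_ref rather
than from zero dose.

Dichotomous track — extra risk:
    BMR_D = (f(BMD) - f(d_ref)) / (1 - f(d_ref))

Continuous track — relative change in the central tendency of the OR, with
g(d) = exp(m(d)) for a model m on the log-OR scale:
    BMR_C = (g(BMD) - g(d_ref)) / g(d_ref)

The two definitions are tied together before any fitting by equating the
implied incidence change, using the referent incidence rate f_ref computed
from the effective counts (cases / subjects in the referent group) and the
fact that the OR at the referent is identically 1:

    BMR_C + 1 = (BMR_D·(1 - f_ref) + f_ref) / f_ref

BMD inversion is done by bracketed root finding on [d_ref, 50·d_max]
(expanded once by 10x before a draw is declared unattainable); the
quantal-linear and linear models admit closed forms,
BMD = d_ref - log(1 - BMR_D)/β and BMD = d_ref + log(1 + BMR_C)/b, which
serve as independent oracles for the root finder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datamodel import DatasetError
from .models import CONTINUOUS_MODELS, DICHOTOMOUS_MODELS, eval_model

__all__ = [
    "BmrSpec",
    "convert_bmr",
    "bmd_from_theta",
    "bmd_draws",
    "bmd_quantal_linear_closed",
    "bmd_linear_closed",
]

TRACKS = ("dichotomous_extra_risk", "continuous_relative_change")


@dataclass(frozen=True)
class BmrSpec:
    """A benchmark-response level on one track, anchored at the referent dose."""

    track: str
    value: float
    reference_dose: float

    def __post_init__(self) -> None:
        if self.track not in TRACKS:
            raise DatasetError(f"unknown BMR track {self.track!r}")
        if not 0 < self.value < 1:
            raise DatasetError(f"BMR value must lie in (0, 1), got {self.value}")
        if self.reference_dose < 0:
            raise DatasetError("reference dose must be non-negative")


def convert_bmr(bmr_d: float, f_ref: float) -> float:
    """Continuous-track BMR equivalent to a dichotomous extra-risk BMR.

    ``f_ref`` is the referent-group incidence rate, effective cases divided by
    subjects; e.g. BMR_D = 0.1% with f_ref = 18/128 gives BMR_C ≈ 0.6%.
    """
    if not 0 < f_ref < 1:
        raise DatasetError(f"referent incidence must lie in (0, 1), got {f_ref}")
    if not 0 < bmr_d < 1:
        raise DatasetError(f"BMR_D must lie in (0, 1), got {bmr_d}")
    return (bmr_d * (1.0 - f_ref) + f_ref) / f_ref - 1.0


def bmd_quantal_linear_closed(beta: float, d_ref: float, bmr_d: float) -> float:
    """Closed-form quantal-linear BMD: d_ref - log(1 - BMR_D)/β."""
    return d_ref - math.log1p(-bmr_d) / beta


def bmd_linear_closed(b: float, d_ref: float, bmr_c: float) -> float:
    """Closed-form linear (log-OR) BMD: d_ref + log(1 + BMR_C)/b."""
    return d_ref + math.log1p(bmr_c) / b


def _target_shift(name: str, theta, bmr: BmrSpec):
    """Residual function d -> response(d) - target; its root is the BMD."""
    d_ref = bmr.reference_dose
    if name in DICHOTOMOUS_MODELS:
        if bmr.track != "dichotomous_extra_risk":
            raise DatasetError(f"model {name!r} needs a dichotomous extra-risk BMR")
        f_ref = float(eval_model(name, theta, d_ref)[0])
        target = f_ref + bmr.value * (1.0 - f_ref)

        def resid(d):
            return float(eval_model(name, theta, d)[0]) - target

    elif name in CONTINUOUS_MODELS:
        if bmr.track != "continuous_relative_change":
            raise DatasetError(f"model {name!r} needs a continuous relative-change BMR")
        m_ref = float(eval_model(name, theta, d_ref)[0])
        shift = math.log1p(bmr.value)

        def resid(d):
            return float(eval_model(name, theta, d)[0]) - m_ref - shift

    else:
        raise DatasetError(f"unknown model {name!r}")
    return resid


def bmd_from_theta(
    name: str, theta, bmr: BmrSpec, d_max: float, xtol: float = 1e-12
) -> float:
    """Benchmark dose for one parameter vector by bracketed root finding.

    The model is assumed nondecreasing in dose over the bracket
    [d_ref, 50·d_max]; if the response change is not reached there the bracket
    expands once to 500·d_max, after which NaN is returned (unattainable).
    """
    theta = np.asarray(theta, dtype=float)
    resid = _target_shift(name, theta, bmr)
    lo = bmr.reference_dose
    if name == "dichotomous_hill" and lo <= 0:
        raise DatasetError("dichotomous Hill needs a positive reference dose")
    r_lo = resid(lo)
    if r_lo > 0:  # already past the target at the reference (degenerate)
        return lo
    for hi in (50.0 * d_max, 500.0 * d_max):
        if hi <= lo:
            continue
        if resid(hi) >= 0.0:
            return float(brentq(resid, lo, hi, xtol=xtol * max(1.0, d_max)))
    return math.nan


def bmd_draws(name: str, thetas: np.ndarray, bmr: BmrSpec, d_max: float) -> np.ndarray:
    """Vectorized BMD over a stack of posterior draws (NaN where unattainable).

    Uses bisection broadcast across draws; relies on the fitted models being
    nondecreasing in dose (slope parameters are constrained non-negative).
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    d_ref = bmr.reference_dose
    if name in DICHOTOMOUS_MODELS:
        f_ref = eval_model(name, thetas, d_ref)[:, 0]
        target = f_ref + bmr.value * (1.0 - f_ref)
    else:
        m_ref = eval_model(name, thetas, d_ref)[:, 0]
        target = m_ref + math.log1p(bmr.value)

    k = thetas.shape[0]
    lo = np.full(k, d_ref, dtype=float)
    hi = np.full(k, 500.0 * d_max, dtype=float)

    def f_pair(d):
        # response of draw j at its own dose d[j]
        # d shape (k,): response of draw j at dose d[j]
        th = thetas
        if name == "quantal_linear":
            g, beta = th[:, 0], th[:, 1]
            return g + (1 - g) * (-np.expm1(-beta * d))
        if name == "dichotomous_hill":
            g, v, a, b = th[:, 0], th[:, 1], th[:, 2], th[:, 3]
            with np.errstate(divide="ignore"):
                ld = np.log(d)
            return g + (v - v * g) / (1 + np.exp(-a - b * ld))
        if name == "linear":
            a, b = th[:, 0], th[:, 1]
            return a + b * d
        a, v, kk, p = th[:, 0], th[:, 1], th[:, 2], th[:, 3]
        return a + v * d**p / (kk**p + d**p)

    attainable = f_pair(hi) >= target
    out = np.full(k, np.nan)
    lo_b = lo.copy()
    hi_b = hi.copy()
    for _ in range(80):
        mid = 0.5 * (lo_b + hi_b)
        below = f_pair(mid) < target
        lo_b = np.where(below, mid, lo_b)
        hi_b = np.where(below, hi_b, mid)
    out[attainable] = 0.5 * (lo_b + hi_b)[attainable]
    return out
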