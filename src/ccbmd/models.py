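"""Dose-response models and log-likelihoods for the two modeling tracks.

Dichotomous track (effective counts): the group response probability follows

    quantal-linear    f(d) = g + (1 - g)·(1 - exp(-β·d)),      0 < g < 1, β >= 0
    dichotomous Hill  f(d) = g + v·(1 - g)/(1 + exp(-a - b·log d)),
                      0 < g < 1, 0 < v <= 1, b > 0

and the data likelihood is binomial per group, with the binomial coefficient
extended to real-valued counts through the Gamma function so that non-integer
effective counts are admissible:

    log P = Σ_i [ log C(n_i, y_i) + y_i·log f(d_i) + (n_i - y_i)·log(1 - f(d_i)) ]

Continuous track (log odds ratios): the group mean log-OR follows

    linear  m(d) = a + b·d
    Hill    m(d) = a + v·d^p / (k^p + d^p),                    k > 0, p >= 1

with a constant within-group SD γ across groups, and a normal summary-data
likelihood built from each group's mean ȳ'_i and SD s'_i on the log scale:

    log L = Σ_i [ -(n_i/2)·log(2πγ²) - ((n_i - 1)·s'_i² + n_i·(ȳ'_i - m(d_i))²) / (2γ²) ]

The referent group enters with s'_0 = 0, i.e. only through its mean term.

All evaluators broadcast over a trailing parameter axis, so a whole ensemble of
parameter vectors (shape (..., p)) is scored in one call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datamodel import DatasetError

__all__ = [
    "DICHOTOMOUS_MODELS",
    "CONTINUOUS_MODELS",
    "PARAM_NAMES",
    "DichotomousInput",
    "eval_model",
    "log_binom_coeff",
    "loglik_dichotomous",
    "loglik_continuous",
]

DICHOTOMOUS_MODELS = ("quantal_linear", "dichotomous_hill")
CONTINUOUS_MODELS = ("linear", "hill")

#: model parameter layouts, in the order used throughout the package
PARAM_NAMES = {
    "quantal_linear": ("g", "beta"),
    "dichotomous_hill": ("g", "v", "a", "b"),
    "linear": ("a", "b"),
    "hill": ("a", "v", "k", "power"),
}


@dataclass
class DichotomousInput:
    """Model-ready arrays for the dichotomous likelihood (index 0 = referent)."""

    doses: np.ndarray
    n: np.ndarray  # subjects per group, may be real-valued
    y: np.ndarray  # responders per group, may be real-valued
    study_id: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.doses.shape == self.n.shape == self.y.shape):
            raise DatasetError("dichotomous input arrays must share one shape")
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise DatasetError("responders must satisfy 0 <= y <= n")

    @property
    def n_groups(self) -> int:
        return int(self.doses.shape[0])


def _unpack(theta: np.ndarray, k: int) -> list[np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != k:
        raise DatasetError(f"expected {k} parameters, got shape {theta.shape}")
    return [theta[..., j, None] for j in range(k)]


def eval_model(name: str, theta, d) -> np.ndarray:
    """Evaluate a dose-response model at doses ``d`` (probability or log-OR).

    ``theta`` may be a single vector or an array of vectors with the parameter
    axis last; the result has shape ``theta.shape[:-1] + d.shape``.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if name == "quantal_linear":
        g, beta = _unpack(theta, 2)
        out = g + (1.0 - g) * (-np.expm1(-beta * d))
    elif name == "dichotomous_hill":
        g, v, a, b = _unpack(theta, 4)
        if np.any(d <= 0):
            raise DatasetError("dichotomous Hill needs strictly positive doses")
        out = g + (v - v * g) / (1.0 + np.exp(-a - b * np.log(d)))
    elif name == "linear":
        a, b = _unpack(theta, 2)
        out = a + b * d
    elif name == "hill":
        a, v, k, p = _unpack(theta, 4)
        out = a + v * d**p / (k**p + d**p)
    else:
        raise DatasetError(f"unknown model {name!r}")
    return out


def log_binom_coeff(n, y) -> np.ndarray:
    """log C(n, y) extended to real arguments via the Gamma function."""
    n = np.asarray(n, dtype=float)
    y = np.asarray(y, dtype=float)
    return gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)


def loglik_dichotomous(name: str, theta, data: DichotomousInput) -> np.ndarray:
    """Gamma-extended binomial log-likelihood of effective counts.

    Returns -inf where the model probability hits 0 or 1 against a non-zero
    opposing count.  Broadcasts over a stack of parameter vectors.
    """
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    f = eval_model(name, np.atleast_2d(theta), data.doses)  # (m, G)
    y = data.y
    n = data.n
    const = np.sum(log_binom_coeff(n, y))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(f), 0.0) + np.where(
            n - y > 0, (n - y) * np.log1p(-f), 0.0
        )
    ll = const + np.sum(term, axis=-1)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return float(ll[0]) if single else ll


def loglik_continuous(name: str, theta, gamma, data) -> np.ndarray:
    """Normal summary-statistics log-likelihood of log-OR means and SDs.

    ``gamma`` is the constant within-group SD on the log scale (scalar or a
    stack matching ``theta``'s leading shape).  The referent group has
    s' = 0 and contributes only its mean residual.
    """
    theta = np.asarray(theta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    single = theta.ndim == 1
    if np.any(gamma <= 0):
        if single:
            raise DatasetError("gamma must be strictly positive")
    m = eval_model(name, np.atleast_2d(theta), data.doses)  # (k, G)
    g2 = np.atleast_1d(gamma)[..., None] ** 2  # (k, 1)
    n = data.n
    resid = (data.n - 1.0) * data.sd_log**2 + n * (data.mean_log - m) ** 2
    ll = np.sum(-(n / 2.0) * np.log(2.0 * math.pi * g2) - resid / (2.0 * g2), axis=-1)
    ll = np.where(np.atleast_1d(gamma) <= 0, -np.inf, ll)
    return float(ll[0]) if single else ll
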