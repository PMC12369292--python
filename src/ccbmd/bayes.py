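"""Bayesian fitting of either likelihood by ensemble MCMC, and posterior
summarization into benchmark-dose estimates.

Doses are rescaled internally by the maximum observed dose so that slope-type
parameters are O(1) regardless of whether a study spans 0.04-0.6 µg/L or
26-1080 µg/L; draws are transformed back to the original dose scale before
they leave this module.

Default priors (weakly informative, defined on the rescaled dose axis, all
overridable through ``PriorSet``):

    background g           ~ Uniform(0, 1)
    slopes β', b'          ~ HalfNormal(5)          (nondecreasing curves)
    Hill asymptote v       ~ Uniform(0, 1]          (dichotomous)
    Hill amplitude v       ~ HalfNormal(5)          (continuous, log-OR units)
    Hill location a        ~ Normal(0, 10)
    Hill half-max k'       ~ HalfNormal(2)
    Hill power             ~ Uniform(1, 18)
    intercept a            ~ Normal(0, 10)
    within-group SD γ      ~ HalfCauchy(1)

Sampling uses an affine-invariant ensemble sampler; each walker is treated as
one chain for split-R̂ and effective-sample-size diagnostics.  Non-convergence
is reported as a warning on the fit, never as an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import emcee
import numpy as np

from .bmr import BmrSpec, bmd_draws
from .datamodel import DatasetError
from .models import (
    CONTINUOUS_MODELS,
    DICHOTOMOUS_MODELS,
    PARAM_NAMES,
    DichotomousInput,
    loglik_continuous,
    loglik_dichotomous,
)
from .or_summaries import ContinuousInput

__all__ = ["SamplerConfig", "PriorSet", "PosteriorFit", "BmdEstimate", "fit", "summarize_bmd"]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; ``iterations`` are per-chain steps, ``warmup`` discarded."""

    chains: int = 4
    iterations: int = 10_000
    warmup: Optional[int] = None
    seed: int = 0
    rhat_threshold: float = 1.05
    min_ess: float = 400.0

    @property
    def n_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise DatasetError("need at least 2 chains for split-R-hat")
        if self.n_warmup >= self.iterations:
            raise DatasetError("warmup must be shorter than iterations")


@dataclass(frozen=True)
class PriorSet:
    """Scales of the default priors (see module docstring); all overridable."""

    slope_scale: float = 5.0
    intercept_scale: float = 10.0
    hill_k_scale: float = 2.0
    hill_power_max: float = 18.0
    amplitude_scale: float = 5.0
    gamma_scale: float = 1.0


@dataclass
class PosteriorFit:
    """Retained posterior draws (original dose scale) plus diagnostics."""

    model: str
    track: str
    param_names: tuple
    draws: np.ndarray  # (n_draws, n_params), back-transformed
    rhat: dict
    ess: dict
    dose_scale: float
    d_max: float
    d_ref: float
    seed: int
    chains: int
    converged: bool
    study_id: str = ""
    priors: Optional[PriorSet] = None

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[0])

    def theta_draws(self) -> np.ndarray:
        """Model parameters only (the nuisance γ column dropped if present)."""
        if self.param_names[-1] == "gamma":
            return self.draws[:, :-1]
        return self.draws


@dataclass
class BmdEstimate:
    """Posterior benchmark-dose summary at one BMR."""

    bmd: float
    bmdl: float
    bmdu: float
    bmr: BmrSpec
    level: float
    n_draws: int
    n_unattainable: int
    reliable: bool

    def __post_init__(self) -> None:
        if not (self.bmdl <= self.bmd <= self.bmdu):
            raise DatasetError("BMD bounds out of order")


def _log_halfnormal(x, scale):
    return np.where(x < 0, -np.inf, -0.5 * (x / scale) ** 2)


def _log_halfcauchy(x, scale):
    return np.where(x <= 0, -np.inf, -np.log1p((x / scale) ** 2))


def _log_normal(x, scale):
    return -0.5 * (x / scale) ** 2


def log_prior(name: str, theta: np.ndarray, priors: PriorSet) -> np.ndarray:
    """Joint log prior density (up to constants) on the rescaled-dose scale.

    ``theta`` includes the trailing γ column for continuous models.
    """
    theta = np.atleast_2d(theta)
    if name == "quantal_linear":
        g, beta = theta[:, 0], theta[:, 1]
        lp = np.where((g > 0) & (g < 1), 0.0, -np.inf)
        lp = lp + _log_halfnormal(beta, priors.slope_scale)
    elif name == "dichotomous_hill":
        g, v, a, b = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
        lp = np.where((g > 0) & (g < 1) & (v > 0) & (v <= 1), 0.0, -np.inf)
        lp = lp + _log_normal(a, priors.intercept_scale)
        lp = lp + np.where(b > 0, _log_halfnormal(b, priors.slope_scale), -np.inf)
    elif name == "linear":
        a, b, gam = theta[:, 0], theta[:, 1], theta[:, 2]
        lp = _log_normal(a, priors.intercept_scale)
        lp = lp + _log_halfnormal(b, priors.slope_scale)
        lp = lp + _log_halfcauchy(gam, priors.gamma_scale)
    elif name == "hill":
        a, v, k, p, gam = (theta[:, j] for j in range(5))
        lp = _log_normal(a, priors.intercept_scale)
        lp = lp + _log_halfnormal(v, priors.amplitude_scale)
        lp = lp + np.where(k > 0, _log_halfnormal(k, priors.hill_k_scale), -np.inf)
        lp = lp + np.where((p >= 1) & (p <= priors.hill_power_max), 0.0, -np.inf)
        lp = lp + _log_halfcauchy(gam, priors.gamma_scale)
    else:
        raise DatasetError(f"unknown model {name!r}")
    return lp


def _sample_prior(name: str, rng: np.random.Generator, n: int, priors: PriorSet):
    """Moderate over-dispersed draws from the priors, used to seed walkers."""
    if name == "quantal_linear":
        return np.column_stack(
            [rng.uniform(0.01, 0.99, n), np.abs(rng.normal(0, 1.0, n)) + 0.05]
        )
    if name == "dichotomous_hill":
        return np.column_stack(
            [
                rng.uniform(0.01, 0.99, n),
                rng.uniform(0.05, 1.0, n),
                rng.normal(0, 2.0, n),
                np.abs(rng.normal(0, 1.0, n)) + 0.05,
            ]
        )
    if name == "linear":
        return np.column_stack(
            [
                rng.normal(0, 0.5, n),
                np.abs(rng.normal(0, 1.0, n)) + 0.05,
                np.abs(rng.normal(0, 0.5, n)) + 0.05,
            ]
        )
    if name == "hill":
        return np.column_stack(
            [
                rng.normal(0, 0.5, n),
                np.abs(rng.normal(0, 1.0, n)) + 0.05,
                np.abs(rng.normal(0, 1.0, n)) + 0.05,
                rng.uniform(1.0, 5.0, n),
                np.abs(rng.normal(0, 0.5, n)) + 0.05,
            ]
        )
    raise DatasetError(f"unknown model {name!r}")


def _back_transform(name: str, draws: np.ndarray, scale: float) -> np.ndarray:
    """Map draws from the rescaled-dose parametrization to original doses."""
    out = draws.copy()
    if name == "quantal_linear":
        out[:, 1] /= scale
    elif name == "dichotomous_hill":
        # a' + b·log(d/scale) = (a' - b·log scale) + b·log d
        out[:, 2] = out[:, 2] - out[:, 3] * math.log(scale)
    elif name == "linear":
        out[:, 1] /= scale
    elif name == "hill":
        out[:, 2] *= scale
    return out


def fit(
    data,
    model: str,
    priors: Optional[PriorSet] = None,
    cfg: Optional[SamplerConfig] = None,
) -> PosteriorFit:
    """Sample the posterior of one model on one dataset's model-ready input.

    ``data`` is a :class:`DichotomousInput` for the quantal-linear /
    dichotomous-Hill models or a :class:`ContinuousInput` for the linear /
    Hill (log-OR) models.
    """
    priors = priors or PriorSet()
    cfg = cfg or SamplerConfig()
    if isinstance(data, DichotomousInput):
        if model not in DICHOTOMOUS_MODELS:
            raise DatasetError(f"{model!r} is not a dichotomous model")
        track = "dichotomous"
    elif isinstance(data, ContinuousInput):
        if model not in CONTINUOUS_MODELS:
            raise DatasetError(f"{model!r} is not a continuous model")
        track = "continuous"
    else:
        raise DatasetError(f"unsupported input type {type(data).__name__}")

    scale = float(np.max(data.doses))
    if scale <= 0:
        raise DatasetError("need at least one positive dose")
    scaled = _rescale_input(data, scale)

    names = PARAM_NAMES[model] + (("gamma",) if track == "continuous" else ())
    ndim = len(names)

    if track == "dichotomous":

        def log_prob(theta):
            return log_prior(model, theta, priors) + loglik_dichotomous(
                model, theta, scaled
            )

    else:

        def log_prob(theta):
            lp = log_prior(model, theta, priors)
            ll = np.full_like(lp, -np.inf)
            ok = np.isfinite(lp)
            if np.any(ok):
                th = np.atleast_2d(theta)[ok]
                ll[ok] = loglik_continuous(model, th[:, :-1], th[:, -1], scaled)
            return lp + ll

    nwalkers = max(cfg.chains, 4 * ndim)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(cfg.seed)

    # seed walkers at prior draws with finite posterior density
    p0 = np.empty((nwalkers, ndim))
    filled = 0
    for _ in range(200):
        cand = _sample_prior(model, rng, nwalkers, priors)
        lp = log_prob(cand)
        good = np.isfinite(lp)
        take = min(nwalkers - filled, int(good.sum()))
        p0[filled : filled + take] = cand[good][:take]
        filled += take
        if filled == nwalkers:
            break
    if filled < nwalkers:
        raise DatasetError("could not find walkers with finite posterior density")

    # differential-evolution move mixture: mixes far better than the default
    # stretch move on the correlated Hill-type posteriors
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(cfg.seed).get_state()
    sampler.run_mcmc(p0, cfg.iterations, progress=False)

    chain = sampler.get_chain(discard=cfg.n_warmup)  # (steps, walkers, ndim)
    by_chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)

    rhat, ess = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, nm in enumerate(names):
            rhat[nm] = float(az.rhat(by_chain[:, :, j]))
            ess[nm] = float(az.ess(by_chain[:, :, j]))
    converged = all(
        r <= cfg.rhat_threshold for r in rhat.values() if np.isfinite(r)
    ) and all(e >= cfg.min_ess for e in ess.values() if np.isfinite(e))
    if not converged:
        warnings.warn(
            f"{model} on {getattr(data, 'study_id', '')!r}: MCMC diagnostics below "
            f"target (max R-hat {max(rhat.values()):.3f}, min ESS {min(ess.values()):.0f})",
            RuntimeWarning,
            stacklevel=2,
        )

    flat = chain.reshape(-1, ndim)
    if track == "continuous":
        theta = _back_transform(model, flat[:, :-1], scale)
        flat = np.column_stack([theta, flat[:, -1]])
    else:
        flat = _back_transform(model, flat, scale)

    return PosteriorFit(
        model=model,
        track=track,
        param_names=names,
        draws=flat,
        rhat=rhat,
        ess=ess,
        dose_scale=scale,
        d_max=float(np.max(data.doses)),
        d_ref=float(data.doses[0]),
        seed=cfg.seed,
        chains=nwalkers,
        converged=converged,
        study_id=getattr(data, "study_id", ""),
        priors=priors,
    )


def _rescale_input(data, scale: float):
    if isinstance(data, DichotomousInput):
        return DichotomousInput(
            doses=data.doses / scale, n=data.n, y=data.y, study_id=data.study_id
        )
    return ContinuousInput(
        doses=data.doses / scale,
        n=data.n,
        mean_log=data.mean_log,
        sd_log=data.sd_log,
        study_id=data.study_id,
    )


def summarize_bmd(
    fit_result: PosteriorFit, bmr: BmrSpec, level: float = 0.95
) -> BmdEstimate:
    """Draw-wise BMD inversion and posterior summary.

    BMD is the posterior median; BMDL/BMDU are the one-sided lower and upper
    credible bounds at ``level`` (5th/95th percentiles for the default 0.95).
    Draws whose BMR is unattainable below the search bracket cap are excluded;
    the estimate is flagged unreliable when they exceed half of all draws.
    """
    if fit_result.n_draws < 1000:
        raise DatasetError("need at least 1000 retained draws to summarize a BMD")
    thetas = fit_result.theta_draws()
    vals = bmd_draws(fit_result.model, thetas, bmr, fit_result.d_max)
    ok = np.isfinite(vals)
    n_bad = int((~ok).sum())
    if ok.sum() == 0:
        raise DatasetError("BMR unattainable for every posterior draw")
    good = vals[ok]
    bmd = float(np.median(good))
    bmdl = float(np.quantile(good, 1.0 - level))
    bmdu = float(np.quantile(good, level))
    return BmdEstimate(
        bmd=bmd,
        bmdl=bmdl,
        bmdu=bmdu,
        bmr=bmr,
        level=level,
        n_draws=int(ok.sum()),
        n_unattainable=n_bad,
        reliable=n_bad <= 0.5 * vals.size,
    )
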