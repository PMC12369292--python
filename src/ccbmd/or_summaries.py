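"""Odds-ratio arithmetic and lognormal summaries for the continuous track.

A 2x2 table with cells (a_i, b_i) in the exposed group and (a_0, b_0) in the
referent gives the odds ratio OR_i = (a_i/b_i)/(a_0/b_0), whose log has the
Woolf standard error sqrt(1/a_i + 1/b_i + 1/a_0 + 1/b_0).

For continuous-data dose-response modeling, a reported OR with its confidence
interval is treated as the median and quantiles of a lognormal distribution:
the group mean on the log scale is log(OR) and the log-scale SD is
log(OR_U/OR_L)/(2·z), where z is the standard-normal quantile matching the
CI level (z_0.975 for a 95% CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .datamodel import CaseControlDataset, DatasetError

__all__ = [
    "LognormalSummary",
    "ContinuousInput",
    "or_from_counts",
    "se_log_or",
    "lognormal_from_ci",
    "continuous_input",
]


@dataclass(frozen=True)
class LognormalSummary:
    """Per-group lognormal summary of an odds ratio: mean and SD on log scale."""

    mean_log: float
    sd_log: float
    n: float

    def __post_init__(self) -> None:
        if self.sd_log < 0:
            raise DatasetError("sd_log must be non-negative")


@dataclass
class ContinuousInput:
    """Model-ready arrays for the continuous (log-OR) likelihood.

    Index 0 is the referent, with mean_log = 0 and sd_log = 0 by convention
    (its odds ratio is identically 1 with no sampling interval reported).
    """

    doses: np.ndarray
    n: np.ndarray
    mean_log: np.ndarray
    sd_log: np.ndarray
    study_id: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.mean_log = np.asarray(self.mean_log, dtype=float)
        self.sd_log = np.asarray(self.sd_log, dtype=float)
        G = self.doses.shape[0]
        if not (self.n.shape[0] == self.mean_log.shape[0] == self.sd_log.shape[0] == G):
            raise DatasetError("continuous input arrays must share one length")

    @property
    def n_groups(self) -> int:
        return int(self.doses.shape[0])


def or_from_counts(a_i: float, b_i: float, a_0: float, b_0: float) -> float:
    """Odds ratio of an exposed group against the referent 2x2 cells."""
    if min(a_i, b_i, a_0, b_0) <= 0:
        raise ZeroDivisionError("odds ratio undefined with a zero or negative cell")
    return (a_i / b_i) / (a_0 / b_0)


def se_log_or(a_i: float, b_i: float, a_0: float, b_0: float) -> float:
    """Woolf standard error of the log odds ratio."""
    if min(a_i, b_i, a_0, b_0) <= 0:
        raise ZeroDivisionError("SE of log OR infinite with a zero cell")
    return math.sqrt(1 / a_i + 1 / b_i + 1 / a_0 + 1 / b_0)


def lognormal_from_ci(
    or_point: float, or_low: float, or_high: float, ci_level: float = 0.95, n: float = 0
) -> LognormalSummary:
    """Convert a reported OR and CI into lognormal log-scale mean and SD."""
    if not 0 < or_low <= or_point <= or_high:
        raise DatasetError(
            f"invalid OR/CI triple ({or_point}, {or_low}, {or_high}): "
            "need 0 < low <= point <= high"
        )
    if not 0 < ci_level < 1:
        raise DatasetError(f"ci_level must be in (0, 1), got {ci_level}")
    z = norm.ppf(0.5 * (1 + ci_level))
    return LognormalSummary(
        mean_log=math.log(or_point),
        sd_log=math.log(or_high / or_low) / (2 * z),
        n=n,
    )


def continuous_input(ds: CaseControlDataset) -> ContinuousInput:
    """Assemble the four model inputs (dose, n, log-OR mean, log-OR SD) per group."""
    doses, ns, means, sds = [], [], [], []
    for i, g in enumerate(ds.groups):
        if g.adjusted_midpoint is None:
            raise DatasetError(
                f"{ds.study_id}: adjusted midpoints not computed (run adjust_dataset)"
            )
        doses.append(g.adjusted_midpoint)
        ns.append(g.n_subjects_effective)
        if i == 0:
            means.append(0.0)
            sds.append(0.0)
        else:
            if not g.has_ci:
                raise DatasetError(f"{ds.study_id}: group {g.label!r} lacks an OR CI")
            s = lognormal_from_ci(g.or_point, g.or_low, g.or_high, g.ci_level)
            means.append(s.mean_log)
            sds.append(s.sd_log)
    return ContinuousInput(
        doses=doses, n=ns, mean_log=means, sd_log=sds, study_id=ds.study_id
    )
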