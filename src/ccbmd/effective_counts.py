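"""Effective-count reconstruction from adjusted odds ratios.

Published case-control tables report confounder-adjusted ORs alongside raw 2x2
counts; the adjusted OR no longer matches the crude OR of the raw cells.  The
"effective counts" are synthetic cells that (a) keep each group's subject
total, and (b) make the crude OR of the synthetic cells equal the adjusted OR.

Step 1 estimates the referent cells (A0, B0) by a grid search: each candidate
A0 in 1..N0 implies exposed cells via the OR-equivalence propagation below
(applied at the mean adjusted OR, with the pooled non-referent subject total),
and hence a Woolf CI around the mean OR; the candidate whose implied CI best
matches the mean reported CI bounds (least sum of squared differences) wins.
The matching objective generically has two local minima in A0 — a low- and a
high-incidence root of the CI-width equation; the search returns the
low-incidence root (smallest local minimizer), the epidemiologically sensible
branch for a case-control referent group.

Step 2 propagates deterministically to each treatment group i: with
q = OR_i·(A0/B0), the cells A_i = N_i·q/(1+q) and B_i = N_i − A_i are the
unique solution of {A_i + B_i = N_i, (A_i/B_i)/(A0/B0) = OR_i}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.stats import norm

from .datamodel import CaseControlDataset, DatasetError, TotalsSummary, totals_summary

__all__ = [
    "EffectiveCountsResult",
    "propagate_group",
    "wang_objective",
    "wang_referent",
    "effective_dataset",
    "dichotomous_input",
]


@dataclass
class EffectiveCountsResult:
    """Referent and per-group effective counts with the search objective value."""

    referent_cases: float
    referent_noncases: float
    effective_cases: list
    effective_noncases: list
    objective_value: float


def propagate_group(
    a0e: float, b0e: float, or_i: float, n_i: float
) -> tuple[float, float]:
    """Effective (cases, non-cases) of a treatment group from the referent cells.

    Solves A + B = n_i together with (A/B)/(a0e/b0e) = or_i, giving
    A = n_i·q/(1+q) with q = or_i·(a0e/b0e).
    """
    if min(a0e, b0e, or_i, n_i) <= 0:
        raise DatasetError("propagate_group needs strictly positive inputs")
    q = or_i * a0e / b0e
    a_ie = n_i * q / (1 + q)
    return a_ie, n_i - a_ie


def wang_objective(
    a0e: float, totals: TotalsSummary, ci_level: float = 0.95
) -> float:
    """Sum-of-squares discrepancy between the implied and the reported mean CI.

    Candidate referent cells (a0e, N0−a0e), combined with the mean adjusted OR
    and the pooled non-referent subject total, imply a Woolf standard error and
    hence CI bounds around the mean OR; the objective is the squared distance
    of those implied bounds from the reported mean CI bounds.  Infeasible
    candidates (any implied cell <= 0) score +inf.
    """
    b0e = totals.n_referent - a0e
    n_exposed = totals.n_total - totals.n_referent
    if a0e <= 0 or b0e <= 0 or n_exposed <= 0:
        return math.inf
    q = totals.mean_or * a0e / b0e
    a1 = n_exposed * q / (1 + q)
    b1 = n_exposed - a1
    if a1 <= 0 or b1 <= 0:
        return math.inf
    z = norm.ppf(0.5 * (1 + ci_level))
    se = math.sqrt(1 / a1 + 1 / b1 + 1 / a0e + 1 / b0e)
    implied_low = totals.mean_or * math.exp(-z * se)
    implied_high = totals.mean_or * math.exp(z * se)
    return (implied_low - totals.mean_or_low) ** 2 + (
        implied_high - totals.mean_or_high
    ) ** 2


def wang_referent(
    totals: TotalsSummary,
    referent_raw: Optional[tuple[float, float]] = None,
    objective: Optional[Callable[[float, TotalsSummary], float]] = None,
    step: float = 1.0,
) -> tuple[float, float, float]:
    """Grid search for the referent effective counts (a0e, b0e).

    Evaluates the objective on the grid a0e = step, 2·step, ..., N0 and returns
    the smallest local minimizer (ties broken toward smaller a0e).  When the
    objective is flat to machine precision (e.g. a single OR = 1 group carries
    no information), the raw referent counts are returned unchanged.
    """
    obj = objective or wang_objective
    n0 = totals.n_referent
    grid = np.arange(step, n0 + 0.5 * step, step)
    if grid.size == 0:
        raise DatasetError("empty referent search grid")
    values = np.array([obj(float(a), totals) for a in grid])
    if not np.any(np.isfinite(values)):
        raise DatasetError("referent search objective non-finite everywhere")
    finite = values[np.isfinite(values)]
    if referent_raw is not None and np.ptp(finite) < 1e-12:
        # flat objective: no information to move away from the raw counts
        a0 = float(referent_raw[0])
        return a0, n0 - a0, float(finite[0])
    # smallest local minimizer (strictly better than the next point, no worse
    # than the previous one)
    k = len(values)
    for i in range(k):
        left_ok = i == 0 or values[i] <= values[i - 1]
        right_ok = i == k - 1 or values[i] < values[i + 1]
        if left_ok and right_ok and math.isfinite(values[i]):
            a0 = float(grid[i])
            return a0, n0 - a0, float(values[i])
    i = int(np.argmin(values))  # pragma: no cover - monotone fallback
    a0 = float(grid[i])
    return a0, n0 - a0, float(values[i])


def _round_pair(a: float, n: float) -> tuple[float, float]:
    """Nearest-integer rounding of (cases, non-cases) preserving the group total."""
    a_r = float(round(a))
    return a_r, n - a_r


def effective_dataset(
    ds: CaseControlDataset,
    rounding: str = "gamma_real",
    referent: Optional[tuple[float, float]] = None,
    objective: Optional[Callable] = None,
) -> CaseControlDataset:
    """Populate effective counts for every group of a dataset.

    The referent cells come from ``referent`` when given (e.g. published
    values), otherwise from the grid search.  ``rounding`` is ``"gamma_real"``
    (keep real-valued counts; the Gamma-extended likelihood absorbs them) or
    ``"nearest_integer"``.
    """
    if rounding not in ("gamma_real", "nearest_integer"):
        raise DatasetError(f"unknown rounding mode {rounding!r}")
    out = ds.copy()
    if referent is None:
        tot = totals_summary(ds)
        a0, b0, _ = wang_referent(
            tot, referent_raw=(ds.referent.raw_cases, ds.referent.raw_noncases),
            objective=objective,
        )
    else:
        a0, b0 = float(referent[0]), float(referent[1])
    for i, g in enumerate(out.groups):
        n_eff = g.n_subjects_effective if g.n_subjects_effective is not None else g.n_subjects
        if i == 0:
            a, b = a0, b0
        else:
            a, b = propagate_group(a0, b0, g.or_point, n_eff)
        if rounding == "nearest_integer":
            a, b = _round_pair(a, n_eff)
        g.effective_cases, g.effective_noncases = a, b
        g.n_subjects_effective = n_eff
    return out


def dichotomous_input(ds: CaseControlDataset):
    """Model-ready arrays (dose, effective n, effective cases) for a dataset."""
    from .models import DichotomousInput

    doses, ns, ys = [], [], []
    for g in ds.groups:
        if g.adjusted_midpoint is None:
            raise DatasetError(
                f"{ds.study_id}: adjusted midpoints not computed (run adjust_dataset)"
            )
        if g.effective_cases is None:
            raise DatasetError(
                f"{ds.study_id}: effective counts not computed (run effective_dataset)"
            )
        doses.append(g.adjusted_midpoint)
        ns.append(g.n_subjects_effective)
        ys.append(g.effective_cases)
    return DichotomousInput(doses=doses, n=ns, y=ys, study_id=ds.study_id)
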