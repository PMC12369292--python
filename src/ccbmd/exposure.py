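"""Point-exposure (adjusted midpoint) computation from reported dose intervals.

Published studies report exposure as concentration ranges, often open-ended in
the lowest ("<x") and highest (">x") groups.  Dose-response modeling needs one
point dose per group, and comparisons across study populations need a common
water-consumption basis, so each midpoint is scaled by the study water-intake
rate ω relative to a 2 L/day baseline ω̂:

    first group, open below :  d = (1/2)·upper·(ω/ω̂)
    interior / closed       :  d = (1/2)·(lower+upper)·(ω/ω̂)
    last group, open above  :  d = (3/2)·lower·(ω/ω̂)
    median reported         :  d = median·(ω/ω̂)

A closed first or last group uses the interior formula; the open-ended rules
apply only where a bound is genuinely missing.

Two published tables use a different midpoint dialect (the Pu bladder lowest
group, and the Mostafa lung groups 2-3, whose printed midpoints span from the
previous group's upper bound); ``adjust_dataset(..., use_printed=True)``
keeps any midpoint already stored on the group instead of recomputing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import CaseControlDataset, DatasetError, DoseInterval

__all__ = ["IntakeAdjustment", "adjusted_midpoint", "adjust_dataset"]


@dataclass(frozen=True)
class IntakeAdjustment:
    """Water-intake scaling: study rate ω and baseline rate ω̂, both in L/day."""

    omega: float
    omega_hat: float = 2.0

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.omega_hat <= 0:
            raise DatasetError("water intake rates must be strictly positive")

    @property
    def ratio(self) -> float:
        return self.omega / self.omega_hat


def adjusted_midpoint(
    interval: DoseInterval, position: str, adj: IntakeAdjustment
) -> float:
    """Adjusted point exposure (µg/L) for one dose group.

    ``position`` is one of ``"first"``, ``"interior"``, ``"last"``; open-ended
    intervals are only admissible in the first (open below) or last (open
    above) position.
    """
    if position not in ("first", "interior", "last"):
        raise ValueError(f"position must be first/interior/last, got {position!r}")
    r = adj.ratio
    if interval.median is not None and interval.lower is None and interval.upper is None:
        return interval.median * r
    if interval.closed:
        return 0.5 * (interval.lower + interval.upper) * r
    if interval.open_below:
        if position != "first":
            raise DatasetError("open-below interval outside the first position")
        return 0.5 * interval.upper * r
    if interval.open_above:
        if position != "last":
            raise DatasetError("open-above interval outside the last position")
        return 1.5 * interval.lower * r
    raise DatasetError("interval has no usable bound")  # pragma: no cover


def adjust_dataset(
    ds: CaseControlDataset, use_printed: bool = False
) -> CaseControlDataset:
    """Populate ``adjusted_midpoint`` for every group of a dataset.

    With ``use_printed=True``, groups that already carry a midpoint (e.g. from
    a published table whose dialect deviates from the interval rules) keep it.
    """
    out = ds.copy()
    adj = IntakeAdjustment(ds.water_intake_rate, ds.baseline_intake_rate)
    last = len(out.groups) - 1
    for i, g in enumerate(out.groups):
        if use_printed and g.adjusted_midpoint is not None:
            continue
        position = "first" if i == 0 else ("last" if i == last else "interior")
        g.adjusted_midpoint = adjusted_midpoint(g.interval, position, adj)
    return out
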