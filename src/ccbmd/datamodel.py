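"""Domain types and table I/O for case-control dose-response summary data.

A published case-control study reports, per exposure group, a concentration
range (often open-ended at the extremes), a confounder-adjusted odds ratio
with its confidence interval, and raw case/non-case counts.  The types here
hold one such table, with group 0 always the referent (lowest-exposure)
group against which the odds ratios are expressed.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "DoseInterval",
    "ExposureGroup",
    "CaseControlDataset",
    "TotalsSummary",
    "parse_interval",
    "read_dataset",
    "write_dataset",
    "totals_summary",
]


class DatasetError(ValueError):
    """Raised when a table violates the case-control schema invariants."""


@dataclass(frozen=True)
class DoseInterval:
    """A reported exposure-concentration interval in µg/L.

    Any of the bounds may be absent: the lowest group is often reported as
    "<x" (open below) and the highest as ">x" (open above).  Studies that
    report a single median concentration per group use ``median`` instead.
    """

    lower: Optional[float] = None
    upper: Optional[float] = None
    median: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None and self.median is None:
            raise DatasetError("dose interval needs a lower, upper or median value")
        for name in ("lower", "upper", "median"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise DatasetError(f"dose interval {name} must be finite and >= 0")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise DatasetError(f"inverted dose interval [{self.lower}, {self.upper}]")

    @property
    def open_below(self) -> bool:
        return self.lower is None and self.upper is not None

    @property
    def open_above(self) -> bool:
        return self.upper is None and self.lower is not None

    @property
    def closed(self) -> bool:
        return self.lower is not None and self.upper is not None


_INTERVAL_RE = re.compile(
    r"""^\s*(?:
        (?P<op><=?|>=?|≤|≥)\s*(?P<bound>[\d.]+)      # open-ended:  <x  >=x  ≤x
      | (?P<lo>[\d.]+)\s*[-–—]\s*(?P<hi>[\d.]+)      # closed:      a-b  a–b
      | (?P<med>[\d.]+)                              # bare number: median
    )\s*$""",
    re.VERBOSE,
)


def parse_interval(text: str) -> DoseInterval:
    """Parse an exposure-range string such as ``"15.5-42.5"``, ``"<26"`` or ``">=800"``.

    ``<x`` and ``≤x`` both yield an open-below interval with upper bound x;
    ``>x`` and ``≥x`` both yield an open-above interval with lower bound x.
    A bare number is read as a group median concentration.
    """
    m = _INTERVAL_RE.match(text)
    if not m:
        raise DatasetError(f"cannot parse exposure interval {text!r}")
    if m.group("op"):
        bound = float(m.group("bound"))
        if m.group("op") in ("<", "<=", "≤"):
            return DoseInterval(upper=bound)
        return DoseInterval(lower=bound)
    if m.group("lo"):
        return DoseInterval(lower=float(m.group("lo")), upper=float(m.group("hi")))
    return DoseInterval(median=float(m.group("med")))


@dataclass
class ExposureGroup:
    """One dose group: interval, counts and the adjusted odds ratio.

    ``raw_*`` counts are the published 2x2 cells; ``effective_*`` counts are
    real-valued cells reconstructed so that their crude odds ratio equals the
    confounder-adjusted one.  The referent group has ``or_point == 1`` and no
    confidence interval.
    """

    interval: DoseInterval
    raw_cases: float
    raw_noncases: float
    n_subjects: float
    or_point: float = 1.0
    or_low: Optional[float] = None
    or_high: Optional[float] = None
    ci_level: float = 0.95
    adjusted_midpoint: Optional[float] = None
    effective_cases: Optional[float] = None
    effective_noncases: Optional[float] = None
    n_subjects_effective: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.raw_cases + self.raw_noncases != self.n_subjects:
            raise DatasetError(
                f"group {self.label!r}: cases {self.raw_cases} + non-cases "
                f"{self.raw_noncases} != subjects {self.n_subjects}"
            )
        if self.n_subjects_effective is None:
            self.n_subjects_effective = self.n_subjects
        if self.effective_cases is not None and self.effective_noncases is not None:
            tot = self.effective_cases + self.effective_noncases
            if abs(tot - self.n_subjects_effective) > 1e-6:
                raise DatasetError(
                    f"group {self.label!r}: effective counts sum {tot} != "
                    f"effective subjects {self.n_subjects_effective}"
                )
        if self.or_low is not None and self.or_high is not None:
            if not (0 < self.or_low <= self.or_point <= self.or_high):
                raise DatasetError(
                    f"group {self.label!r}: OR {self.or_point} outside CI "
                    f"({self.or_low}, {self.or_high})"
                )

    @property
    def has_ci(self) -> bool:
        return self.or_low is not None and self.or_high is not None


@dataclass
class CaseControlDataset:
    """An ordered case-control dose-response table; group 0 is the referent."""

    study_id: str
    endpoint: str  # {"bladder", "lung", "other"}
    location: str
    water_intake_rate: float  # L/day
    groups: list[ExposureGroup] = field(default_factory=list)
    baseline_intake_rate: float = 2.0  # L/day, US default

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise DatasetError(
                f"{self.study_id}: need at least 2 exposure groups, got {len(self.groups)}"
            )
        if self.water_intake_rate <= 0 or self.baseline_intake_rate <= 0:
            raise DatasetError(f"{self.study_id}: water intake rates must be positive")
        ref = self.groups[0]
        if ref.or_point != 1.0 or ref.has_ci:
            raise DatasetError(
                f"{self.study_id}: group 0 must be the referent (OR = 1, no CI)"
            )

    @property
    def referent(self) -> ExposureGroup:
        return self.groups[0]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def copy(self) -> "CaseControlDataset":
        return replace(
            self, groups=[replace(g, interval=g.interval) for g in self.groups]
        )


@dataclass(frozen=True)
class TotalsSummary:
    """Totals and mean odds-ratio summaries that drive the referent-count search.

    The means run over the non-referent groups only (the referent has no CI).
    """

    n_referent: float
    n_total: float
    mean_or: float
    mean_or_low: float
    mean_or_high: float

    def __post_init__(self) -> None:
        if self.n_referent > self.n_total:
            raise DatasetError("referent group larger than the whole study")


def totals_summary(ds: CaseControlDataset, use_effective_n: bool = True) -> TotalsSummary:
    """Summarize a dataset into the quantities used by the referent-count search.

    ``use_effective_n`` counts subjects with the effective totals where a study
    prints a deviating effective group size; otherwise raw totals are used.
    """
    non_ref = ds.groups[1:]
    missing = [g.label for g in non_ref if not g.has_ci]
    if missing:
        raise DatasetError(f"{ds.study_id}: groups without OR CI: {missing}")
    ns = [
        (g.n_subjects_effective if use_effective_n else g.n_subjects) for g in ds.groups
    ]
    return TotalsSummary(
        n_referent=ds.referent.n_subjects,
        n_total=float(sum(ns)),
        mean_or=float(sum(g.or_point for g in non_ref) / len(non_ref)),
        mean_or_low=float(sum(g.or_low for g in non_ref) / len(non_ref)),
        mean_or_high=float(sum(g.or_high for g in non_ref) / len(non_ref)),
    )


#: canonical column order for the on-disk schema
_COLUMNS = [
    "group_label",
    "dose_low",
    "dose_high",
    "dose_median",
    "or",
    "or_low",
    "or_high",
    "cases",
    "noncases",
    "n",
]


def _interval_from_row(row: pd.Series) -> DoseInterval:
    label = str(row.get("group_label", "") or "")
    lo = row.get("dose_low")
    hi = row.get("dose_high")
    med = row.get("dose_median")
    lo = None if pd.isna(lo) else float(lo)
    hi = None if pd.isna(hi) else float(hi)
    med = None if pd.isna(med) else float(med)
    if lo is None and hi is None and med is None:
        return parse_interval(label)
    return DoseInterval(lower=lo, upper=hi, median=med)


def read_dataset(
    table,
    *,
    study_id: str = "unnamed",
    endpoint: str = "other",
    location: str = "",
    water_intake_rate: float = 2.0,
    baseline_intake_rate: float = 2.0,
    sep: Optional[str] = None,
) -> CaseControlDataset:
    """Read one dose-response table (CSV/TSV path, file object or DataFrame).

    The first row must be the referent group (OR omitted or equal to 1 with no
    CI).  Exposure intervals come either from numeric ``dose_low``/``dose_high``/
    ``dose_median`` columns or, failing those, parsed from ``group_label``
    strings such as ``"<26"``, ``"15.5-42.5"`` or ``">=800"``.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep=sep, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("cases", "noncases", "n"):
        if col not in df.columns:
            raise DatasetError(f"missing required column {col!r}")
    groups = []
    for idx, row in df.reset_index(drop=True).iterrows():
        or_point = row.get("or")
        or_point = 1.0 if pd.isna(or_point) else float(or_point)
        or_low = row.get("or_low")
        or_high = row.get("or_high")
        or_low = None if pd.isna(or_low) else float(or_low)
        or_high = None if pd.isna(or_high) else float(or_high)
        if idx == 0:
            if or_point != 1.0 or or_low is not None:
                raise DatasetError(
                    "first row must be the referent group (OR = 1, no CI)"
                )
        groups.append(
            ExposureGroup(
                interval=_interval_from_row(row),
                raw_cases=float(row["cases"]),
                raw_noncases=float(row["noncases"]),
                n_subjects=float(row["n"]),
                or_point=or_point,
                or_low=or_low,
                or_high=or_high,
                label=str(row.get("group_label", idx)),
            )
        )
    return CaseControlDataset(
        study_id=study_id,
        endpoint=endpoint,
        location=location,
        water_intake_rate=water_intake_rate,
        baseline_intake_rate=baseline_intake_rate,
        groups=groups,
    )


def to_frame(ds: CaseControlDataset) -> pd.DataFrame:
    """Render a dataset back to the on-disk schema (plus computed columns)."""
    rows = []
    for g in ds.groups:
        rows.append(
            {
                "group_label": g.label,
                "dose_low": g.interval.lower,
                "dose_high": g.interval.upper,
                "dose_median": g.interval.median,
                "or": g.or_point,
                "or_low": g.or_low,
                "or_high": g.or_high,
                "cases": g.raw_cases,
                "noncases": g.raw_noncases,
                "n": g.n_subjects,
                "adjusted_midpoint": g.adjusted_midpoint,
                "effective_cases": g.effective_cases,
                "effective_noncases": g.effective_noncases,
                "n_effective": g.n_subjects_effective,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(ds: CaseControlDataset, path_or_buf=None, sep: str = ",") -> Optional[str]:
    """Write a dataset as delimited text; returns the text when no path given."""
    df = to_frame(ds)
    if path_or_buf is None:
        buf = io.StringIO()
        df.to_csv(buf, sep=sep, index=False)
        return buf.getvalue()
    df.to_csv(path_or_buf, sep=sep, index=False)
    return None
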