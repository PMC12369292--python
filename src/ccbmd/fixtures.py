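"""Packaged case-control fixtures: inorganic arsenic in drinking water versus
bladder cancer (5 studies) and lung cancer (5 studies).

Each fixture carries the published per-group exposure ranges, study water-intake
rates, adjusted odds ratios with 95% CIs, raw counts, and the published
effective counts and adjusted exposure midpoints.  The Mostafa lung table
prints a raw subject total (1879) that differs from its effective total (576)
in the second dose group; the fixture stores both verbatim.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datamodel import CaseControlDataset, DatasetError, ExposureGroup, _interval_from_row

__all__ = ["load_fixture", "FIXTURE_STUDIES"]

FIXTURE_STUDIES = {
    "bladder": ["Ferreccio2000", "Kurttio1999", "Pu2007", "Steinmaus2013", "Wu2013"],
    "lung": ["Ferreccio1998", "Ferreccio2000", "Mostafa2008", "Smith2009", "Steinmaus2013"],
}


def _fixture_frame(endpoint: str) -> pd.DataFrame:
    ref = resources.files("ccbmd.data").joinpath(f"{endpoint}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_fixture(endpoint: str) -> list[CaseControlDataset]:
    """Load the packaged datasets for one endpoint ('bladder' or 'lung')."""
    if endpoint not in FIXTURE_STUDIES:
        raise DatasetError(f"unknown endpoint {endpoint!r}; expected 'bladder' or 'lung'")
    df = _fixture_frame(endpoint)
    out = []
    for study in FIXTURE_STUDIES[endpoint]:
        sub = df[df["study_id"] == study]
        groups = []
        for _, row in sub.iterrows():
            or_low = None if pd.isna(row["or_low"]) else float(row["or_low"])
            or_high = None if pd.isna(row["or_high"]) else float(row["or_high"])
            groups.append(
                ExposureGroup(
                    interval=_interval_from_row(row),
                    raw_cases=float(row["cases_raw"]),
                    raw_noncases=float(row["noncases_raw"]),
                    n_subjects=float(row["n_raw"]),
                    or_point=float(row["or"]),
                    or_low=or_low,
                    or_high=or_high,
                    adjusted_midpoint=float(row["midpoint"]),
                    effective_cases=float(row["cases_eff"]),
                    effective_noncases=float(row["noncases_eff"]),
                    n_subjects_effective=float(row["n_eff"]),
                    label=str(row["group_label"]),
                )
            )
        out.append(
            CaseControlDataset(
                study_id=study,
                endpoint=endpoint,
                location=str(sub["location"].iloc[0]),
                water_intake_rate=float(sub["water_intake"].iloc[0]),
                groups=groups,
            )
        )
    return out
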