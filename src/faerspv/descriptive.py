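"""Baseline descriptive summaries per endpoint stratum.

Medians and IQRs are computed over non-missing values only, with linear
interpolation between order statistics (the numpy default). Every
categorical breakdown carries an explicit "unknown" row, and within a
breakdown the percentages sum to 100 up to rounding. Seriousness follows
the regulatory convention: a report is serious iff it carries at least one
outcome code; for a single outcome (death, hospitalization, ...) "yes"
means the code is present, "no" means other outcome codes are present but
not this one, and "unknown" means the report has no outcome records.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort


@dataclass
class DescriptiveSummary:
    endpoint: str
    n: int
    age_median: float
    age_q1: float
    age_q3: float
    weight_median: float
    weight_q1: float
    weight_q3: float
    breakdowns: Mapping[str, Mapping[str, tuple[int, float]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"endpoint": self.endpoint, "characteristic": "total",
                 "category": "n", "count": self.n, "percent": 100.0}]
        for stat, value in (("age_median", self.age_median),
                            ("age_q1", self.age_q1), ("age_q3", self.age_q3),
                            ("weight_median", self.weight_median),
                            ("weight_q1", self.weight_q1),
                            ("weight_q3", self.weight_q3)):
            rows.append({"endpoint": self.endpoint, "characteristic": stat,
                         "category": "", "count": np.nan, "percent": value})
        for name, table in self.breakdowns.items():
            for category, (count, pct) in table.items():
                rows.append({"endpoint": self.endpoint, "characteristic": name,
                             "category": category, "count": count, "percent": pct})
        return pd.DataFrame(rows)


def _quantiles(values: pd.Series) -> tuple[float, float, float]:
    known = values.dropna().to_numpy(dtype=float)
    if known.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(known, [25, 50, 75])
    return (med, q1, q3)


def _breakdown(labels: pd.Series, order: list[str]) -> dict[str, tuple[int, float]]:
    n = len(labels)
    out = {}
    for category in order:
        count = int((labels == category).sum())
        out[category] = (count, 100.0 * count / n if n else np.nan)
    return out


def descriptive_summary(cohort: AnalysisCohort, endpoint: str) -> DescriptiveSummary:
    """Table-1-style characteristics of the endpoint-positive stratum."""
    mask = cohort.endpoints[endpoint].to_numpy()
    sub = cohort.cases.loc[mask]
    n = len(sub)
    if n == 0:
        return DescriptiveSummary(endpoint=endpoint, n=0,
                                  age_median=np.nan, age_q1=np.nan, age_q3=np.nan,
                                  weight_median=np.nan, weight_q1=np.nan,
                                  weight_q3=np.nan, breakdowns={})
    age_med, age_q1, age_q3 = _quantiles(sub["age_years"])
    wt_med, wt_q1, wt_q3 = _quantiles(sub["weight_kg"])

    region = np.where(sub["reporter_country"] == "US", "united-states",
                      np.where(sub["reporter_country"] == "unknown",
                               "unknown", "other"))
    breakdowns = {
        "sex": _breakdown(sub["sex"], ["male", "female", "unknown"]),
        "region": _breakdown(pd.Series(region, index=sub.index),
                             ["united-states", "other", "unknown"]),
        "seriousness": _breakdown(
            pd.Series(np.where(sub["has_outcome"], "serious", "no"), index=sub.index),
            ["serious", "no"]),
    }
    for code in ("hospitalization", "death", "disability", "life-threatening"):
        status = np.where(sub[f"outcome_{code}"], "yes",
                          np.where(sub["has_outcome"], "no", "unknown"))
        breakdowns[code] = _breakdown(pd.Series(status, index=sub.index),
                                      ["yes", "no", "unknown"])
    return DescriptiveSummary(endpoint=endpoint, n=n,
                              age_median=age_med, age_q1=age_q1, age_q3=age_q3,
                              weight_median=wt_med, weight_q1=wt_q1,
                              weight_q3=wt_q3, breakdowns=breakdowns)
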