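"""Pairwise drug-versus-drug contrasts within an endpoint.

Two kinds of contrast, both reported as odds ratios with Woolf 95% CIs:

* constituent ratio — does drug i's report set contain a higher share of
  the endpoint than drug j's? OR = (a_i/c_i)/(a_j/c_j) from the drugs'
  (a, c) contingency cells;
* severity — among endpoint-positive reports of each drug with known
  outcomes, the odds of a severe outcome (death or life-threatening)
  versus a non-severe one.

A zero cell triggers the Haldane–Anscombe correction (+0.5 on all four
cells), keeping the OR finite and preserving reciprocity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort
from .signals import ContingencyTable, Z95


@dataclass(frozen=True)
class PairwiseOR:
    endpoint: str
    drug_i: str
    drug_j: str
    kind: str                       # "constituent-ratio" or "severity"
    or_value: float
    ci_low: float
    ci_high: float
    cells: tuple[int, int, int, int]  # (x_i, y_i, x_j, y_j) before correction
    corrected: bool

    @property
    def estimable(self) -> bool:
        return not math.isnan(self.or_value)

    @property
    def significant(self) -> bool:
        """CI excludes 1 (either direction)."""
        return self.estimable and (self.ci_low > 1.0 or self.ci_high < 1.0)


def _woolf_or(endpoint: str, drug_i: str, drug_j: str, kind: str,
              x_i: int, y_i: int, x_j: int, y_j: int) -> PairwiseOR:
    """OR of (x vs y) for drug i against drug j with Haldane fallback."""
    cells = (x_i, y_i, x_j, y_j)
    corrected = min(cells) == 0
    f = [c + 0.5 for c in cells] if corrected else list(map(float, cells))
    or_value = (f[0] * f[3]) / (f[1] * f[2])
    se = math.sqrt(sum(1.0 / c for c in f))
    return PairwiseOR(endpoint=endpoint, drug_i=drug_i, drug_j=drug_j,
                      kind=kind, or_value=or_value,
                      ci_low=or_value * math.exp(-Z95 * se),
                      ci_high=or_value * math.exp(Z95 * se),
                      cells=cells, corrected=corrected)


def constituent_ratio_or(endpoint: str, drug_i: str, drug_j: str,
                         table_i: ContingencyTable, table_j: ContingencyTable,
                         ) -> PairwiseOR:
    """Event-composition contrast from the two drugs' (a, c) cells."""
    return _woolf_or(endpoint, drug_i, drug_j, "constituent-ratio",
                     table_i.a, table_i.c, table_j.a, table_j.c)


def _severity_cells(cohort: AnalysisCohort, endpoint: str, drug: str) -> tuple[int, int]:
    """(severe, non-severe) among the drug's endpoint-positive reports with
    at least one outcome record; outcome-unknown reports are excluded."""
    mask = (cohort.exposure[drug].to_numpy()
            & cohort.endpoints[endpoint].to_numpy()
            & cohort.cases["has_outcome"].to_numpy())
    severe = cohort.cases["severity"].to_numpy() == "severe"
    n_severe = int((mask & severe).sum())
    return n_severe, int(mask.sum()) - n_severe


def severity_or(endpoint: str, drug_i: str, drug_j: str,
                cohort: AnalysisCohort) -> PairwiseOR:
    """Severe-versus-non-severe outcome contrast between two drugs.

    Not estimable (NaN) when either drug has no endpoint report with a
    known outcome.
    """
    sev_i, non_i = _severity_cells(cohort, endpoint, drug_i)
    sev_j, non_j = _severity_cells(cohort, endpoint, drug_j)
    if sev_i + non_i == 0 or sev_j + non_j == 0:
        return PairwiseOR(endpoint, drug_i, drug_j, "severity",
                          math.nan, math.nan, math.nan,
                          (sev_i, non_i, sev_j, non_j), corrected=False)
    return _woolf_or(endpoint, drug_i, drug_j, "severity",
                     sev_i, non_i, sev_j, non_j)


def all_pairs(endpoint: str, drugs: Sequence[str], kind: str,
              tables: Optional[dict[tuple[str, str], ContingencyTable]] = None,
              cohort: Optional[AnalysisCohort] = None) -> list[PairwiseOR]:
    """Full k x k contrast set (unit diagonal, reciprocal off-diagonal)."""
    if len(drugs) < 2:
        raise ValueError("need at least two drugs for pairwise contrasts")
    results = []
    for drug_i in drugs:
        for drug_j in drugs:
            if kind == "constituent-ratio":
                if tables is None:
                    raise ValueError("constituent-ratio contrasts need tables")
                results.append(constituent_ratio_or(
                    endpoint, drug_i, drug_j,
                    tables[(drug_i, endpoint)], tables[(drug_j, endpoint)]))
            elif kind == "severity":
                if cohort is None:
                    raise ValueError("severity contrasts need a cohort")
                results.append(severity_or(endpoint, drug_i, drug_j, cohort))
            else:
                raise ValueError(f"unknown contrast kind {kind!r}")
    return results


def pairs_frame(results: Iterable[PairwiseOR]) -> pd.DataFrame:
    """Long-format frame, one row per ordered pair."""
    return pd.DataFrame([{
        "endpoint": r.endpoint, "drug_i": r.drug_i, "drug_j": r.drug_j,
        "kind": r.kind, "or": r.or_value, "low": r.ci_low, "high": r.ci_high,
        "corrected": r.corrected, "significant": r.significant,
    } for r in results])


def or_matrix(results: Iterable[PairwiseOR]) -> pd.DataFrame:
    """Square OR matrix (rows = drug_i, columns = drug_j) for one endpoint
    and kind, mirroring the published comparison grids."""
    frame = pairs_frame(results)
    kinds, endpoints = frame["kind"].unique(), frame["endpoint"].unique()
    if len(kinds) != 1 or len(endpoints) != 1:
        raise ValueError("or_matrix expects a single endpoint and kind")
    return frame.pivot(index="drug_i", columns="drug_j", values="or")
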