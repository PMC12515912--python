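"""Disproportionality statistics on drug x event 2x2 tables.

For each (drug, endpoint) pair within the cohort the cells are

    a  drug of interest with the event of interest
    b  all other drugs with the event
    c  drug of interest with all other events
    d  all other drugs with all other events

with N = a+b+c+d the cohort grand total, identical for every table from
one cohort. Four signal statistics are computed:

* PRR = [a/(a+c)] / [b/(b+d)], 95% CI exp(ln PRR +- 1.96*sqrt(1/a -
  1/(a+c) + 1/b - 1/(b+d))) — not estimable when a=0 or b=0;
* ROR = ad/bc, Woolf 95% CI exp(ln ROR +- 1.96*sqrt(1/a+1/b+1/c+1/d)) —
  not estimable on any zero cell (no continuity correction here);
* Yates-corrected chi-square N*(max(0, |ad-bc| - N/2))^2 /
  [(a+b)(c+d)(a+c)(b+d)];
* the BCPNN information component in the single-shrinkage form
  IC = log2((a+0.5)/(E+0.5)) with E = (a+b)(a+c)/N, and the asymmetric
  credibility bounds
  IC025 = IC - 3.3*(a+0.5)^-1/2 - 2*(a+0.5)^-3/2,
  IC975 = IC + 2.4*(a+0.5)^-1/2 - 0.5*(a+0.5)^-3/2.

Signal criteria: PRR signal iff a >= 3, PRR >= 2 and chi-square >= 4
(the Evans criterion); ROR signal iff a >= 3 and the lower CI bound
exceeds 1; IC signal iff IC025 > 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort

Z95 = 1.96
#: minimum case count entering the PRR and ROR signal criteria
MIN_CASES = 3


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


class Estimate(NamedTuple):
    """A point estimate with interval bounds; NaN triple when not estimable."""
    value: float
    low: float
    high: float

    @property
    def estimable(self) -> bool:
        return not math.isnan(self.value)


_NOT_ESTIMABLE = Estimate(math.nan, math.nan, math.nan)


def compute_prr(t: ContingencyTable) -> Estimate:
    """Proportional reporting ratio with Woolf-type 95% CI."""
    if t.a == 0 or t.b == 0:
        return _NOT_ESTIMABLE
    prr = (t.a / (t.a + t.c)) / (t.b / (t.b + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.c) + 1 / t.b - 1 / (t.b + t.d))
    return Estimate(prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))


def compute_ror(t: ContingencyTable) -> Estimate:
    """Reporting odds ratio with Woolf 95% CI; zero cells -> not estimable."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return _NOT_ESTIMABLE
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return Estimate(ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def compute_chi2(t: ContingencyTable) -> float:
    """Yates continuity-corrected chi-square, clamped at zero.

    Not estimable (NaN) when any margin is zero.
    """
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        return math.nan
    diff = abs(t.a * t.d - t.b * t.c) - t.n / 2
    if diff < 0:
        return 0.0
    return t.n * diff * diff / math.prod(margins)


def compute_ic(t: ContingencyTable) -> Estimate:
    """Information component with asymmetric 95% credibility bounds.

    The +0.5 shrinkage keeps every cell finite, so the IC is defined for
    all tables, including a = 0.
    """
    shrunk = t.a + 0.5
    ic = math.log2(shrunk / (t.expected_a + 0.5))
    ic025 = ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
    ic975 = ic + 2.4 * shrunk ** -0.5 - 0.5 * shrunk ** -1.5
    return Estimate(ic, ic025, ic975)


@dataclass(frozen=True)
class SignalResult:
    drug: str
    endpoint: str
    table: ContingencyTable
    prr: Estimate
    chi2: float
    ror: Estimate
    ic: Estimate
    prr_signal: bool
    ror_signal: bool
    ic_signal: bool

    @property
    def any_signal(self) -> bool:
        return self.prr_signal or self.ror_signal or self.ic_signal


def flag_signals(t: ContingencyTable, prr: Estimate, chi2: float,
                 ror: Estimate, ic: Estimate) -> tuple[bool, bool, bool]:
    """Apply the three signal criteria; non-estimable metrics never flag."""
    prr_signal = (t.a >= MIN_CASES and prr.estimable and prr.value >= 2.0
                  and not math.isnan(chi2) and chi2 >= 4.0)
    ror_signal = t.a >= MIN_CASES and ror.estimable and ror.low > 1.0
    ic_signal = ic.low > 0.0
    return prr_signal, ror_signal, ic_signal


def evaluate_table(drug: str, endpoint: str, t: ContingencyTable) -> SignalResult:
    """Full disproportionality stack plus signal flags for one pair."""
    prr, ror, ic = compute_prr(t), compute_ror(t), compute_ic(t)
    chi2 = compute_chi2(t)
    prr_s, ror_s, ic_s = flag_signals(t, prr, chi2, ror, ic)
    return SignalResult(drug=drug, endpoint=endpoint, table=t, prr=prr,
                        chi2=chi2, ror=ror, ic=ic, prr_signal=prr_s,
                        ror_signal=ror_s, ic_signal=ic_s)


def make_tables(cohort: AnalysisCohort,
                drugs: Optional[Sequence[str]] = None,
                endpoints: Optional[Sequence[str]] = None,
                ) -> dict[tuple[str, str], ContingencyTable]:
    """One 2x2 table per drug x endpoint over the cohort grand total.

    For a fixed endpoint the event margin a+b is the endpoint's total
    report count regardless of drug, and every table sums to cohort.n.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    drugs = list(drugs if drugs is not None else cohort.drugs)
    endpoints = list(endpoints if endpoints is not None else cohort.endpoint_names)
    n = cohort.n
    tables: dict[tuple[str, str], ContingencyTable] = {}
    for endpoint in endpoints:
        event = cohort.endpoints[endpoint].to_numpy()
        n_event = int(event.sum())
        for drug in drugs:
            exposed = cohort.exposure[drug].to_numpy()
            a = int((exposed & event).sum())
            c = int(exposed.sum()) - a
            b = n_event - a
            tables[(drug, endpoint)] = ContingencyTable(a, b, c, n - a - b - c)
    return tables


def evaluate_all(tables: dict[tuple[str, str], ContingencyTable]) -> list[SignalResult]:
    return [evaluate_table(drug, endpoint, t)
            for (drug, endpoint), t in tables.items()]


def results_frame(results: Iterable[SignalResult], rounded: bool = False) -> pd.DataFrame:
    """Tidy frame, one row per drug x endpoint.

    ``rounded=True`` applies the report convention: ratios and IC bounds
    to 2 decimals, chi-square to 3; internal values stay full precision.
    """
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "endpoint": r.endpoint,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "prr": r.prr.value, "prr_low": r.prr.low, "prr_high": r.prr.high,
            "chi2": r.chi2,
            "ror": r.ror.value, "ror_low": r.ror.low, "ror_high": r.ror.high,
            "ic": r.ic.value, "ic025": r.ic.low, "ic975": r.ic.high,
            "prr_signal": r.prr_signal, "ror_signal": r.ror_signal,
            "ic_signal": r.ic_signal, "any_signal": r.any_signal,
        })
    frame = pd.DataFrame(rows)
    if rounded and not frame.empty:
        two = ["prr", "prr_low", "prr_high", "ror", "ror_low", "ror_high",
               "ic", "ic025", "ic975"]
        frame[two] = frame[two].round(2)
        frame["chi2"] = frame["chi2"].round(3)
    return frame


def signal_matrix(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Drugs x endpoints matrix of {"signal", "no-signal"} by any-metric flag."""
    frame = pd.DataFrame([(r.drug, r.endpoint, r.any_signal) for r in results],
                         columns=["drug", "endpoint", "any"])
    mat = frame.pivot(index="drug", columns="endpoint", values="any")
    return mat.map(lambda v: "signal" if v else "no-signal")


def load_counts_csv(path: Path | str) -> dict[tuple[str, str], ContingencyTable]:
    """Read pre-tabulated (endpoint, drug, a, b, c, d) rows.

    This is the entry point for running the statistical core on published
    contingency cells without any raw report data.
    """
    frame = pd.read_csv(path)
    required = {"endpoint", "drug", "a", "b", "c", "d"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return {(str(r.drug), str(r.endpoint)): ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
            for r in frame.itertuples(index=False)}
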