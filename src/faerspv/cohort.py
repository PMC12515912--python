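"""Cohort construction: indication filter, drug exposure, endpoint flags.

The analysis cohort is every deduplicated report carrying a depression/MDD
indication. Within it, exposure to a study drug means a suspect-role
(primary or secondary) mention that maps to one of the dictionary
generics; concomitant and interacting mentions do not count. Endpoint
flags are set by any reaction PT falling in the endpoint's term group, and
a report can flag several endpoints. The cohort size N is the grand total
of every downstream 2x2 table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .dictionaries import (DEFAULT_INDICATION_TERMS, DrugDictionary,
                           EndpointDictionary, normalize_drug_name)
from .records import CaseData, SUSPECT_ROLES

logger = logging.getLogger(__name__)

SEVERE_CODES = frozenset({"death", "life-threatening"})
SEVERITY_LEVELS = ("severe", "serious-non-severe", "non-serious")


def severity_category(outcomes: Iterable[str],
                      severe_codes: frozenset[str] = SEVERE_CODES) -> str:
    """Collapse a report's outcome codes to a three-level severity.

    severe: any outcome with potential progression to a fatal outcome
    (death or life-threatening by default); serious-non-severe: any other
    serious outcome code; non-serious: no outcome codes at all.
    """
    codes = set(outcomes)
    if codes & severe_codes:
        return "severe"
    if codes:
        return "serious-non-severe"
    return "non-serious"


@dataclass
class AnalysisCohort:
    """Case-level analysis table plus boolean exposure/endpoint matrices.

    ``cases`` carries demographics and derived severity; ``exposure`` and
    ``endpoints`` are boolean frames aligned to ``cases`` (one column per
    generic / endpoint). ``has_outcome`` marks reports with at least one
    outcome record; reports without any are outcome-unknown for the
    severity contrasts.
    """
    cases: pd.DataFrame
    exposure: pd.DataFrame
    endpoints: pd.DataFrame
    drugs: tuple[str, ...]
    endpoint_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.cases)

    def endpoint_total(self, endpoint: str) -> int:
        return int(self.endpoints[endpoint].sum())


def build_cohort(cases: CaseData,
                 drugs: DrugDictionary,
                 endpoints: EndpointDictionary,
                 indication_terms: Iterable[str] = DEFAULT_INDICATION_TERMS,
                 ) -> AnalysisCohort:
    """Filter to the indication cohort and derive exposure/endpoint flags.

    Raises ``ValueError`` on an empty dictionary (guarded in the
    dictionary constructors as well) and keeps every indication-positive
    case, exposed to a study drug or not: unexposed cases form the
    comparator margin (cells b and d) of the contingency tables.
    """
    indication_terms = frozenset(t.casefold().strip() for t in indication_terms)
    if not indication_terms:
        raise ValueError("indication term set is empty")

    indi_pts = cases.indi["indi_pt"].str.casefold().str.strip()
    cohort_ids = pd.Index(
        cases.indi.loc[indi_pts.isin(indication_terms), "primary_id"].unique())
    demo = cases.demo[cases.demo["primary_id"].isin(cohort_ids)]
    demo = demo.sort_values("primary_id", kind="stable").reset_index(drop=True)
    index = pd.Index(demo["primary_id"])

    # exposure: suspect-role mentions mapped through the drug dictionary
    drug_rows = cases.drug[cases.drug["primary_id"].isin(index)
                           & cases.drug["role_code"].isin(SUSPECT_ROLES)]
    mapped = (drug_rows["verbatim_name"].map(normalize_drug_name)
              .map(drugs.to_lookup_table()))
    exposure = pd.DataFrame(False, index=index, columns=list(drugs.generics))
    hits = drug_rows.assign(generic=mapped).dropna(subset=["generic"])
    if not hits.empty:
        flat = hits.groupby(["primary_id", "generic"]).size().unstack(fill_value=0) > 0
        exposure.update(flat)
        exposure = exposure.astype(bool)

    # endpoint flags from reaction PTs
    reac_rows = cases.reac[cases.reac["primary_id"].isin(index)]
    ep_of_pt = (reac_rows["pt"].str.casefold().str.strip()
                .map(endpoints.to_lookup_table()))
    flags = pd.DataFrame(False, index=index, columns=list(endpoints.endpoints))
    ep_hits = reac_rows.assign(endpoint=ep_of_pt).dropna(subset=["endpoint"])
    if not ep_hits.empty:
        flat = ep_hits.groupby(["primary_id", "endpoint"]).size().unstack(fill_value=0) > 0
        flags.update(flat)
        flags = flags.astype(bool)

    # severity from outcome codes
    outc_rows = cases.outc[cases.outc["primary_id"].isin(index)]
    by_case = outc_rows.groupby("primary_id")["outcome_code"]
    severe_ids = set(outc_rows.loc[outc_rows["outcome_code"].isin(SEVERE_CODES),
                                   "primary_id"])
    any_outcome_ids = set(outc_rows["primary_id"])
    severity = np.where(index.isin(severe_ids), "severe",
                        np.where(index.isin(any_outcome_ids),
                                 "serious-non-severe", "non-serious"))
    outcome_flags = {}
    counts = by_case.value_counts().unstack(fill_value=0) if not outc_rows.empty else None
    case_table = demo.assign(
        severity=pd.Categorical(severity, categories=SEVERITY_LEVELS),
        has_outcome=index.isin(any_outcome_ids),
    )
    for code in ("death", "life-threatening", "hospitalization", "disability"):
        if counts is not None and code in counts.columns:
            positive = set(counts.index[counts[code] > 0])
        else:
            positive = set()
        case_table[f"outcome_{code}"] = index.isin(positive)

    logger.info("cohort: %d of %d cases carry the indication filter",
                len(demo), cases.n_cases)
    return AnalysisCohort(cases=case_table, exposure=exposure, endpoints=flags,
                          drugs=tuple(drugs.generics),
                          endpoint_names=tuple(endpoints.endpoints))
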