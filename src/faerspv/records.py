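"""Core record types for spontaneous adverse-event reports.

Tables are carried as pandas DataFrames with a fixed canonical column set
(one frame per FAERS-style table: DEMO, DRUG, REAC, OUTC, INDI); the
dataclasses below give a typed per-report view used by small tests and by
code that inspects individual cases.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd

#: canonical columns of each table after parsing
DEMO_COLUMNS = [
    "primary_id", "case_id", "event_date", "age_years", "weight_kg",
    "sex", "reporter_country", "fda_receipt_date",
]
DRUG_COLUMNS = ["primary_id", "drug_seq", "verbatim_name", "role_code"]
REAC_COLUMNS = ["primary_id", "pt"]
OUTC_COLUMNS = ["primary_id", "outcome_code"]
INDI_COLUMNS = ["primary_id", "indi_pt"]

#: drug role codes: primary suspect, secondary suspect, concomitant, interacting
ROLE_CODES = frozenset({"ps", "ss", "c", "i"})
SUSPECT_ROLES = frozenset({"ps", "ss"})

#: serious-outcome codes (FAERS OUTC_COD vocabulary, spelled out)
OUTCOME_CODES = frozenset({
    "death", "life-threatening", "hospitalization", "disability",
    "congenital-anomaly", "required-intervention", "other-serious",
})
SEX_CATEGORIES = frozenset({"male", "female", "unknown"})


@dataclass(frozen=True)
class DemoRecord:
    primary_id: str
    case_id: str
    fda_receipt_date: str          # yyyymmdd
    event_date: Optional[str] = None
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    sex: str = "unknown"
    reporter_country: str = "unknown"


@dataclass(frozen=True)
class DrugMention:
    primary_id: str
    drug_seq: int
    verbatim_name: str
    role_code: str                 # one of ROLE_CODES


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated safety report (the winning version of a case)."""
    case_id: str
    demo: DemoRecord
    drugs: tuple[DrugMention, ...]
    reaction_pts: frozenset[str]
    outcome_codes: frozenset[str]
    indication_pts: frozenset[str]


@dataclass
class QuarterBundle:
    """One quarterly extract: five linked tables keyed by primary_id."""
    quarter_label: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame

    def validate(self) -> None:
        ids = set(self.demo["primary_id"])
        for name in ("drug", "reac", "outc", "indi"):
            frame = getattr(self, name)
            orphans = set(frame["primary_id"]) - ids
            if orphans:
                raise ValueError(
                    f"{self.quarter_label}/{name}: {len(orphans)} primary_id(s) "
                    f"missing from demo (e.g. {sorted(orphans)[:3]})"
                )


@dataclass
class CaseData:
    """Deduplicated case-level tables: demo has exactly one row per case_id."""
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    n_dropped_versions: int = 0

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    def iter_reports(self) -> Iterator[CaseReport]:
        """Typed per-case view (convenient for small data; the pipeline
        itself stays columnar)."""
        drug_g = self.drug.groupby("primary_id")
        reac_g = self.reac.groupby("primary_id")["pt"]
        outc_g = self.outc.groupby("primary_id")["outcome_code"]
        indi_g = self.indi.groupby("primary_id")["indi_pt"]
        for row in self.demo.itertuples(index=False):
            pid = row.primary_id
            mentions: tuple[DrugMention, ...] = ()
            if pid in drug_g.groups:
                sub = drug_g.get_group(pid)
                mentions = tuple(
                    DrugMention(pid, int(s), str(n), str(r))
                    for s, n, r in zip(sub["drug_seq"], sub["verbatim_name"], sub["role_code"])
                )
            yield CaseReport(
                case_id=row.case_id,
                demo=DemoRecord(
                    primary_id=pid, case_id=row.case_id,
                    fda_receipt_date=row.fda_receipt_date,
                    event_date=row.event_date if pd.notna(row.event_date) else None,
                    age_years=row.age_years if pd.notna(row.age_years) else None,
                    weight_kg=row.weight_kg if pd.notna(row.weight_kg) else None,
                    sex=row.sex, reporter_country=row.reporter_country,
                ),
                drugs=mentions,
                reaction_pts=frozenset(reac_g.get_group(pid)) if pid in reac_g.groups else frozenset(),
                outcome_codes=frozenset(outc_g.get_group(pid)) if pid in outc_g.groups else frozenset(),
                indication_pts=frozenset(indi_g.get_group(pid)) if pid in indi_g.groups else frozenset(),
            )
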