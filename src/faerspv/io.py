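"""Reading and writing FAERS-style quarterly extract tables.

The quarterly ASCII extracts are "$"-delimited text with one header row per
table (DEMO, DRUG, REAC, OUTC, INDI); the same tables are also accepted as
plain CSV. Files are decoded as Latin-1 with replacement of undecodable
bytes, since the public extracts are not valid UTF-8. Rows that cannot be
parsed are routed to a rejects log (file, line number, reason) instead of
aborting the run; a missing mandatory column is a hard failure.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    CaseData, DEMO_COLUMNS, DRUG_COLUMNS, INDI_COLUMNS, OUTC_COLUMNS,
    QuarterBundle, REAC_COLUMNS,
)

logger = logging.getLogger(__name__)

# age-unit code -> factor converting to years; unknown codes -> missing age
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (24.0 * 365.25),
}
WEIGHT_UNIT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}
SEX_MAP = {"M": "male", "F": "female"}
ROLE_MAP = {"PS": "ps", "SS": "ss", "C": "c", "I": "i"}
OUTCOME_MAP = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital-anomaly",
    "RI": "required-intervention",
    "OT": "other-serious",
}
_ROLE_INV = {v: k for k, v in ROLE_MAP.items()}
_OUTCOME_INV = {v: k for k, v in OUTCOME_MAP.items()}
_SEX_INV = {"male": "M", "female": "F", "unknown": ""}

TABLE_NAMES = ("demo", "drug", "reac", "outc", "indi")


@dataclass(frozen=True)
class SchemaProfile:
    """Maps the canonical record fields onto one dialect's column names.

    Quarter-to-quarter column drift is absorbed here: a profile declares,
    per table, which raw header name carries each canonical field. Raw
    columns not named by the profile are ignored.
    """
    delimiter: str
    demo: Mapping[str, str]
    drug: Mapping[str, str]
    reac: Mapping[str, str]
    outc: Mapping[str, str]
    indi: Mapping[str, str]

    def columns(self, table: str) -> Mapping[str, str]:
        return getattr(self, table)


_DEFAULT_COLUMNS = dict(
    demo={
        "primary_id": "primaryid", "case_id": "caseid", "event_date": "event_dt",
        "age": "age", "age_unit": "age_cod", "weight": "wt", "weight_unit": "wt_cod",
        "sex": "sex", "reporter_country": "occr_country", "fda_receipt_date": "fda_dt",
    },
    drug={
        "primary_id": "primaryid", "drug_seq": "drug_seq",
        "verbatim_name": "drugname", "role_code": "role_cod",
    },
    reac={"primary_id": "primaryid", "pt": "pt"},
    outc={"primary_id": "primaryid", "outcome_code": "outc_cod"},
    indi={"primary_id": "primaryid", "indi_pt": "indi_pt"},
)

ASCII_PROFILE = SchemaProfile(delimiter="$", **_DEFAULT_COLUMNS)
CSV_PROFILE = SchemaProfile(delimiter=",", **_DEFAULT_COLUMNS)


class RejectLog:
    """Accumulates skipped rows as (file, line_number, reason)."""

    def __init__(self) -> None:
        self.records: list[tuple[str, int, str]] = []

    def add(self, file: str, line_number: int, reason: str) -> None:
        self.records.append((file, line_number, reason))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["file", "line_number", "reason"])

    def write_csv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, index=False)


def _read_raw(path: Path, delimiter: str, wanted: Mapping[str, str],
              mandatory: Sequence[str], rejects: RejectLog) -> pd.DataFrame:
    """Read one delimited table into a frame of string columns keyed by
    canonical field name, with a _lineno column for the rejects log."""
    fname = str(path)
    with open(path, encoding="latin-1", errors="replace", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{fname}: empty file (no header row)")
        header = [h.strip().lower() for h in header]
        index = {name: i for i, name in enumerate(header)}
        for canon in mandatory:
            raw = wanted[canon]
            if raw not in index:
                raise ValueError(f"{fname}: mandatory column {raw!r} missing")
        present = {canon: index[raw] for canon, raw in wanted.items() if raw in index}
        ncols = len(header)
        rows: list[list] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncols:
                rejects.add(fname, lineno, f"expected {ncols} fields, got {len(row)}")
                continue
            rows.append([row[i].strip() for i in present.values()] + [lineno])
    frame = pd.DataFrame(rows, columns=list(present) + ["_lineno"])
    for canon in wanted:
        if canon not in frame.columns:
            frame[canon] = ""
    return frame


def _drop_invalid(frame: pd.DataFrame, bad: pd.Series, fname: str,
                  reason: str, rejects: RejectLog) -> pd.DataFrame:
    for lineno in frame.loc[bad, "_lineno"]:
        rejects.add(fname, int(lineno), reason)
    return frame.loc[~bad]


def _parse_demo(raw: pd.DataFrame, fname: str, rejects: RejectLog) -> pd.DataFrame:
    raw = _drop_invalid(raw, (raw["primary_id"] == "") | (raw["case_id"] == ""),
                        fname, "missing primary_id or case_id", rejects)
    age = pd.to_numeric(raw["age"], errors="coerce")
    factor = raw["age_unit"].str.upper().map(AGE_UNIT_TO_YEARS)
    age_years = age * factor
    # implausible ages are treated as missing, not rejected
    age_years = age_years.where((age_years > 0) & (age_years < 120))
    wt = pd.to_numeric(raw["weight"], errors="coerce")
    wfactor = raw["weight_unit"].str.upper().map(WEIGHT_UNIT_TO_KG).fillna(1.0)
    weight_kg = (wt * wfactor).where(lambda s: s > 0)
    out = pd.DataFrame({
        "primary_id": raw["primary_id"],
        "case_id": raw["case_id"],
        "event_date": raw["event_date"].replace("", pd.NA),
        "age_years": age_years,
        "weight_kg": weight_kg,
        "sex": raw["sex"].str.upper().map(SEX_MAP).fillna("unknown"),
        "reporter_country": raw["reporter_country"].replace("", "unknown"),
        "fda_receipt_date": raw["fda_receipt_date"],
    })
    return out.reset_index(drop=True)


def _parse_drug(raw: pd.DataFrame, fname: str, rejects: RejectLog) -> pd.DataFrame:
    raw = _drop_invalid(raw, raw["primary_id"] == "", fname, "missing primary_id", rejects)
    seq = pd.to_numeric(raw["drug_seq"], errors="coerce")
    raw = _drop_invalid(raw.assign(_seq=seq), seq.isna(), fname,
                        "unparseable drug_seq", rejects)
    role = raw["role_code"].str.upper().map(ROLE_MAP)
    raw = _drop_invalid(raw.assign(_role=role), role.isna(), fname,
                        "invalid role code", rejects)
    return pd.DataFrame({
        "primary_id": raw["primary_id"],
        "drug_seq": raw["_seq"].astype(int),
        "verbatim_name": raw["verbatim_name"],
        "role_code": raw["_role"],
    }).reset_index(drop=True)


def _parse_reac(raw: pd.DataFrame, fname: str, rejects: RejectLog) -> pd.DataFrame:
    raw = _drop_invalid(raw, (raw["primary_id"] == "") | (raw["pt"] == ""),
                        fname, "missing primary_id or blank PT", rejects)
    return raw[["primary_id", "pt"]].reset_index(drop=True)


def _parse_outc(raw: pd.DataFrame, fname: str, rejects: RejectLog) -> pd.DataFrame:
    raw = _drop_invalid(raw, raw["primary_id"] == "", fname, "missing primary_id", rejects)
    code = raw["outcome_code"].str.upper().map(OUTCOME_MAP)
    raw = _drop_invalid(raw.assign(_code=code), code.isna(), fname,
                        "invalid outcome code", rejects)
    return pd.DataFrame({"primary_id": raw["primary_id"],
                         "outcome_code": raw["_code"]}).reset_index(drop=True)


def _parse_indi(raw: pd.DataFrame, fname: str, rejects: RejectLog) -> pd.DataFrame:
    raw = _drop_invalid(raw, (raw["primary_id"] == "") | (raw["indi_pt"] == ""),
                        fname, "missing primary_id or blank indication PT", rejects)
    return raw[["primary_id", "indi_pt"]].reset_index(drop=True)


_PARSERS = {"demo": _parse_demo, "drug": _parse_drug, "reac": _parse_reac,
            "outc": _parse_outc, "indi": _parse_indi}
_MANDATORY = {
    "demo": ("primary_id", "case_id", "fda_receipt_date"),
    "drug": ("primary_id", "verbatim_name", "role_code"),
    "reac": ("primary_id", "pt"),
    "outc": ("primary_id", "outcome_code"),
    "indi": ("primary_id", "indi_pt"),
}
_CANONICAL = {"demo": DEMO_COLUMNS, "drug": DRUG_COLUMNS, "reac": REAC_COLUMNS,
              "outc": OUTC_COLUMNS, "indi": INDI_COLUMNS}


def parse_quarter(paths: Mapping[str, Path | str], quarter_label: str,
                  profile: SchemaProfile = ASCII_PROFILE,
                  rejects: Optional[RejectLog] = None) -> QuarterBundle:
    """Parse one quarter's tables into a :class:`QuarterBundle`.

    ``paths`` maps table name ("demo", "drug", "reac", "outc", "indi") to a
    file location. A missing DEMO path is a hard failure; any other missing
    table yields an empty frame with a warning. Row counts per table are
    logged; unparseable rows go to ``rejects``.
    """
    if rejects is None:
        rejects = RejectLog()
    if "demo" not in paths:
        raise ValueError(f"{quarter_label}: no DEMO table given")
    frames = {}
    for table in TABLE_NAMES:
        if table not in paths:
            logger.warning("%s: no %s table; treating as empty", quarter_label, table.upper())
            frames[table] = pd.DataFrame(columns=_CANONICAL[table])
            continue
        raw = _read_raw(Path(paths[table]), profile.delimiter,
                        profile.columns(table), _MANDATORY[table], rejects)
        parsed = _PARSERS[table](raw, str(paths[table]), rejects)
        if parsed.empty and table != "demo":
            logger.warning("%s: %s table is empty", quarter_label, table.upper())
        logger.info("%s/%s: %d rows parsed, %d rejected so far",
                    quarter_label, table.upper(), len(parsed), len(rejects))
        frames[table] = parsed
    bundle = QuarterBundle(quarter_label=quarter_label, **frames)
    bundle.validate()
    return bundle


def deduplicate(bundles: Iterable[QuarterBundle]) -> CaseData:
    """Collapse multi-version cases to one winning report per case_id.

    FAERS re-publishes a case whenever a follow-up arrives; the winner is
    the version with the latest FDA receipt date, ties broken by the
    largest primary_id (numeric where possible). The number of dropped
    versions is kept for the audit trail.
    """
    bundles = list(bundles)
    if not bundles:
        return CaseData(*[pd.DataFrame(columns=_CANONICAL[t]) for t in TABLE_NAMES])
    demo = pd.concat([b.demo for b in bundles], ignore_index=True)
    pid_num = pd.to_numeric(demo["primary_id"], errors="coerce")
    order = demo.assign(_pid_num=pid_num).sort_values(
        ["fda_receipt_date", "_pid_num", "primary_id"], kind="stable")
    winners = order.drop_duplicates("case_id", keep="last").drop(columns="_pid_num")
    n_dropped = len(demo) - len(winners)
    keep = set(winners["primary_id"])
    parts = {}
    for table in ("drug", "reac", "outc", "indi"):
        cat = pd.concat([getattr(b, table) for b in bundles], ignore_index=True)
        parts[table] = cat[cat["primary_id"].isin(keep)].reset_index(drop=True)
    logger.info("deduplicate: %d demo rows -> %d cases (%d versions dropped)",
                len(demo), len(winners), n_dropped)
    return CaseData(demo=winners.reset_index(drop=True),
                    n_dropped_versions=n_dropped, **parts)


def _fmt(value) -> str:
    if pd.isna(value):
        return ""
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_quarter(bundle: QuarterBundle, outdir: Path | str,
                  profile: SchemaProfile = ASCII_PROFILE) -> dict[str, Path]:
    """Write a bundle back to per-table delimited files (inverse of
    :func:`parse_quarter`: ages in years with unit YR, weights in KG)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    label = bundle.quarter_label
    paths: dict[str, Path] = {}

    def _write(table: str, header: list[str], rows: Iterable[list[str]]) -> None:
        path = outdir / f"{table.upper()}{label}.txt"
        with open(path, "w", encoding="latin-1", newline="") as fh:
            writer = csv.writer(fh, delimiter=profile.delimiter, lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)
        paths[table] = path

    cols = profile.columns("demo")
    _write("demo",
           [cols[c] for c in ("primary_id", "case_id", "event_date", "age",
                              "age_unit", "weight", "weight_unit", "sex",
                              "reporter_country", "fda_receipt_date")],
           ([_fmt(r.primary_id), _fmt(r.case_id), _fmt(r.event_date),
             _fmt(r.age_years), "YR" if pd.notna(r.age_years) else "",
             _fmt(r.weight_kg), "KG" if pd.notna(r.weight_kg) else "",
             _SEX_INV.get(r.sex, ""), "" if r.reporter_country == "unknown" else r.reporter_country,
             _fmt(r.fda_receipt_date)]
            for r in bundle.demo.itertuples(index=False)))
    cols = profile.columns("drug")
    _write("drug", [cols[c] for c in ("primary_id", "drug_seq", "verbatim_name", "role_code")],
           ([_fmt(r.primary_id), _fmt(r.drug_seq), r.verbatim_name, _ROLE_INV[r.role_code]]
            for r in bundle.drug.itertuples(index=False)))
    cols = profile.columns("reac")
    _write("reac", [cols["primary_id"], cols["pt"]],
           ([_fmt(r.primary_id), r.pt] for r in bundle.reac.itertuples(index=False)))
    cols = profile.columns("outc")
    _write("outc", [cols["primary_id"], cols["outcome_code"]],
           ([_fmt(r.primary_id), _OUTCOME_INV[r.outcome_code]]
            for r in bundle.outc.itertuples(index=False)))
    cols = profile.columns("indi")
    _write("indi", [cols["primary_id"], cols["indi_pt"]],
           ([_fmt(r.primary_id), r.indi_pt] for r in bundle.indi.itertuples(index=False)))
    return paths


def quarter_paths(directory: Path | str, quarter_label: str) -> dict[str, Path]:
    """Locate the five table files for one quarter under ``directory``."""
    directory = Path(directory)
    found = {}
    for table in TABLE_NAMES:
        for suffix in (".txt", ".csv"):
            path = directory / f"{table.upper()}{quarter_label}{suffix}"
            if path.exists():
                found[table] = path
                break
    return found
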