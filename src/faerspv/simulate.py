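"""Synthetic FAERS-like quarterly bundles with known ground truth.

The generator emulates the statistical structure that disproportionality
analysis assumes: independent spontaneous reports, each carrying one
suspect drug drawn from a catalog (plus a background pool), reaction PTs
drawn per endpoint with probability background_rate x planted
reporting-rate ratio, filler PTs from a fixed neutral vocabulary, outcome
codes from configurable severity profiles, an indication term, and
occasional follow-up versions of the same case (for the deduplication
stage). With all planted ratios at 1 the database is null; with a planted
ratio m the ROR for that (drug, endpoint) converges to ~m and the
information component to ~log2(m) as the report count grows, which is what
the estimator-recovery tests exercise.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .dictionaries import default_endpoint_dictionary
from .records import QuarterBundle

#: fixed neutral filler vocabulary (50 PTs outside every endpoint group)
FILLER_PTS = (
    "Headache", "Nausea", "Dizziness", "Fatigue", "Vomiting", "Diarrhoea",
    "Insomnia", "Somnolence", "Dry mouth", "Constipation", "Rash",
    "Pruritus", "Anxiety", "Tremor", "Hyperhidrosis", "Weight increased",
    "Weight decreased", "Decreased appetite", "Abdominal pain", "Dyspepsia",
    "Paraesthesia", "Asthenia", "Malaise", "Irritability", "Agitation",
    "Blurred vision", "Tinnitus", "Myalgia", "Arthralgia", "Back pain",
    "Cough", "Dyspnoea", "Nasopharyngitis", "Hot flush", "Chills",
    "Pyrexia", "Oedema peripheral", "Hypertension", "Hypotension",
    "Libido decreased", "Nightmare", "Restlessness", "Yawning",
    "Vision blurred", "Dysgeusia", "Flatulence", "Muscle spasms",
    "Urinary retention", "Photosensitivity reaction", "Alopecia",
)

OTHER_INDICATIONS = ("Hypertension", "Anxiety", "Pain", "Diabetes mellitus",
                     "Insomnia")
DEPRESSION_INDICATIONS = ("Depression", "Major depression")

#: outcome distribution of a report not carrying any study endpoint
BASE_OUTCOME_PROFILE = {
    "hospitalization": 0.25, "other-serious": 0.20, "death": 0.02,
    "life-threatening": 0.03, "disability": 0.02, "none": 0.48,
}
#: default outcome distribution of an endpoint-positive report
EVENT_OUTCOME_PROFILE = {
    "hospitalization": 0.40, "other-serious": 0.10, "death": 0.08,
    "life-threatening": 0.22, "disability": 0.03, "none": 0.17,
}

_OUTCOME_KEYS = ("death", "life-threatening", "hospitalization", "disability",
                 "congenital-anomaly", "required-intervention",
                 "other-serious", "none")


class DrugSpec(BaseModel):
    name: str
    share: float = Field(gt=0.0, le=1.0)
    synonyms: list[str] = Field(default_factory=list)


class SimulationConfig(BaseModel):
    """Ground-truth parameters of one synthetic database."""
    seed: int = 0
    n_reports: int = Field(default=10_000, gt=0)
    drug_catalog: list[DrugSpec] = Field(default_factory=list)
    n_pool_drugs: int = Field(default=40, gt=0)
    endpoint_rates: dict[str, float] = Field(default_factory=dict)
    endpoint_terms: Optional[dict[str, list[str]]] = None
    planted_rrr: dict[str, dict[str, float]] = Field(default_factory=dict)
    severity_profile: dict[str, dict[str, dict[str, float]]] = Field(default_factory=dict)
    duplicate_fraction: float = Field(default=0.05, ge=0.0, lt=1.0)
    indication_share: float = Field(default=0.9, ge=0.0, le=1.0)
    concomitant_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    quarters: list[str] = Field(default_factory=lambda: ["2023Q1", "2023Q2",
                                                         "2023Q3", "2023Q4"])

    @field_validator("endpoint_rates")
    @classmethod
    def _rates_are_probs(cls, v: dict[str, float]) -> dict[str, float]:
        for endpoint, rate in v.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"endpoint rate for {endpoint!r} outside [0, 1]")
        return v

    @field_validator("severity_profile")
    @classmethod
    def _profiles_normalized(cls, v):
        for drug, by_ep in v.items():
            for endpoint, profile in by_ep.items():
                unknown = set(profile) - set(_OUTCOME_KEYS)
                if unknown:
                    raise ValueError(f"unknown outcome keys {unknown} for "
                                     f"({drug}, {endpoint})")
                total = sum(profile.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"severity profile for ({drug}, {endpoint}) "
                                     f"sums to {total}, not 1")
        return v

    @model_validator(mode="after")
    def _shares_and_multipliers(self) -> "SimulationConfig":
        total = sum(d.share for d in self.drug_catalog)
        if total > 1.0 + 1e-9:
            raise ValueError(f"drug shares sum to {total} > 1")
        names = [d.name for d in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in catalog")
        for drug, by_ep in self.planted_rrr.items():
            for endpoint, mult in by_ep.items():
                if not np.isfinite(mult) or mult < 0:
                    raise ValueError(f"multiplier for ({drug}, {endpoint}) "
                                     "must be finite and >= 0")
                rate = self.endpoint_rates.get(endpoint, 0.0)
                if rate * mult > 1.0:
                    raise ValueError(
                        f"rate x multiplier = {rate * mult} > 1 for "
                        f"({drug}, {endpoint}): ill-posed configuration")
        return self

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def study_like_config(seed: int = 0, n_reports: int = 100_000) -> SimulationConfig:
    """Defaults emulating the antidepressant arrhythmia study conditions.

    Marginal report shares per drug and per-endpoint background rates echo
    the observed composition of the depression/MDD cohort (shares from the
    drugs' report totals over the 746,507-report cohort; rates from the
    four endpoints' report counts), and the planted reporting-rate ratios
    mirror the published signal pattern (elevated QT/TdP and ventricular
    reporting for citalopram, escitalopram, fluoxetine and quetiapine;
    markedly depressed rates for duloxetine).
    """
    shares = {
        "citalopram": 0.067, "escitalopram": 0.068, "sertraline": 0.110,
        "venlafaxine": 0.105, "fluoxetine": 0.068, "mirtazapine": 0.048,
        "duloxetine": 0.106, "quetiapine": 0.031,
    }
    salts = {
        "citalopram": "CITALOPRAM HYDROBROMIDE", "escitalopram": "ESCITALOPRAM OXALATE",
        "sertraline": "SERTRALINE HYDROCHLORIDE", "venlafaxine": "VENLAFAXINE HYDROCHLORIDE",
        "fluoxetine": "FLUOXETINE HYDROCHLORIDE", "mirtazapine": "MIRTAZAPINE",
        "duloxetine": "DULOXETINE HYDROCHLORIDE", "quetiapine": "QUETIAPINE FUMARATE",
    }
    catalog = [DrugSpec(name=name, share=share,
                        synonyms=[name.upper(), salts[name]])
               for name, share in shares.items()]
    return SimulationConfig(
        seed=seed, n_reports=n_reports, drug_catalog=catalog,
        endpoint_rates={"qt_tdp": 0.0036, "af": 0.00092,
                        "heart_block": 0.00088, "ventricular_arrhythmia": 0.00083},
        planted_rrr={
            "citalopram": {"qt_tdp": 2.3, "af": 1.8, "heart_block": 1.4,
                           "ventricular_arrhythmia": 1.55},
            "escitalopram": {"qt_tdp": 1.75, "af": 1.35,
                             "ventricular_arrhythmia": 1.5},
            "fluoxetine": {"qt_tdp": 1.5, "af": 1.7},
            "quetiapine": {"qt_tdp": 1.5, "ventricular_arrhythmia": 2.4},
            "duloxetine": {"qt_tdp": 0.19, "heart_block": 0.26,
                           "ventricular_arrhythmia": 0.25},
        },
        severity_profile={
            "quetiapine": {"ventricular_arrhythmia": {
                "death": 0.20, "life-threatening": 0.35, "hospitalization": 0.25,
                "other-serious": 0.05, "disability": 0.02, "none": 0.13}},
        },
    )


def _quarter_dates(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """Random yyyymmdd strings inside each report's quarter."""
    years = np.array([int(q[:4]) for q in labels])
    qnum = np.array([int(q[5]) for q in labels])
    month = 3 * (qnum - 1) + 1 + rng.integers(0, 3, size=len(labels))
    day = rng.integers(1, 29, size=len(labels))
    return np.array([f"{y:04d}{m:02d}{d:02d}" for y, m, d in zip(years, month, day)])


def generate(config: SimulationConfig) -> list[QuarterBundle]:
    """Draw one synthetic database and split it into quarterly bundles.

    Reproducible: the same config (seed included) yields identical bundles,
    and writing them with :func:`faerspv.io.write_quarter` yields
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    catalog = config.drug_catalog
    shares = np.array([d.share for d in catalog])
    pool_share = 1.0 - shares.sum()
    pool_names = np.array([f"BACKGROUND DRUG {k:02d}"
                           for k in range(config.n_pool_drugs)])
    probs = np.append(shares, pool_share)
    choice = rng.choice(len(catalog) + 1, size=n, p=probs / probs.sum())
    drug_of = np.empty(n, dtype=object)
    verbatim = np.empty(n, dtype=object)
    for i, spec in enumerate(catalog):
        mask = choice == i
        drug_of[mask] = spec.name
        variants = np.array([spec.name.upper()] + [s.upper() for s in spec.synonyms])
        verbatim[mask] = variants[rng.integers(0, len(variants), size=int(mask.sum()))]
    pool_mask = choice == len(catalog)
    pool_pick = pool_names[rng.integers(0, len(pool_names), size=int(pool_mask.sum()))]
    drug_of[pool_mask] = pool_pick
    verbatim[pool_mask] = pool_pick

    endpoint_terms = config.endpoint_terms
    if endpoint_terms is None:
        endpoint_terms = {ep: sorted(pts) for ep, pts in
                          default_endpoint_dictionary().terms.items()}
        # the dictionary stores case-folded terms; title-case for realism
        endpoint_terms = {ep: [pt.capitalize() for pt in pts]
                          for ep, pts in endpoint_terms.items()}
    endpoints = sorted(config.endpoint_rates)

    event = np.zeros((n, len(endpoints)), dtype=bool)
    for k, endpoint in enumerate(endpoints):
        rate = config.endpoint_rates[endpoint]
        mult = np.ones(n)
        for drug, by_ep in config.planted_rrr.items():
            if endpoint in by_ep:
                mult[drug_of == drug] = by_ep[endpoint]
        p = rate * mult
        if (p > 1.0).any():
            raise ValueError(f"rate x multiplier exceeds 1 for {endpoint!r}")
        event[:, k] = rng.random(n) < p

    case_id = np.arange(100_000, 100_000 + n)
    primary_id = case_id * 10 + 1

    quarters = np.array(config.quarters)
    q_idx = rng.integers(0, len(quarters), size=n)
    event_dt = _quarter_dates(rng, quarters[q_idx])
    fda_dt = event_dt  # receipt in the same quarter

    age = np.round(rng.normal(56.0, 18.0, size=n).clip(18, 95), 1)
    age[rng.random(n) < 0.10] = np.nan
    weight = np.round(rng.normal(74.0, 16.0, size=n).clip(35, 160), 1)
    weight[rng.random(n) < 0.40] = np.nan
    sex = rng.choice(np.array(["male", "female", "unknown"]), size=n,
                     p=[0.30, 0.60, 0.10])
    country = rng.choice(np.array(["US", "GB", "CA", "FR", "unknown"]), size=n,
                         p=[0.40, 0.20, 0.10, 0.10, 0.20])

    # indications
    is_dep = rng.random(n) < config.indication_share
    indi_pt = np.where(
        is_dep,
        np.array(DEPRESSION_INDICATIONS)[rng.choice(2, size=n, p=[0.7, 0.3])],
        np.array(OTHER_INDICATIONS)[rng.integers(0, len(OTHER_INDICATIONS), size=n)])

    # outcome profile per report: planted (drug, endpoint) overrides beat the
    # generic event profile, which beats the base profile
    profile_key = np.where(event.any(axis=1), "event", "base").astype(object)
    profiles: dict[str, dict[str, float]] = {"base": BASE_OUTCOME_PROFILE,
                                             "event": EVENT_OUTCOME_PROFILE}
    for drug in sorted(config.severity_profile):
        for endpoint, prof in sorted(config.severity_profile[drug].items()):
            if endpoint not in endpoints:
                continue
            key = f"{drug}|{endpoint}"
            profiles[key] = prof
            mask = (drug_of == drug) & event[:, endpoints.index(endpoint)]
            profile_key[mask] = key
    outcome = np.empty(n, dtype=object)
    for key in sorted(profiles):
        mask = profile_key == key
        m = int(mask.sum())
        if m == 0:
            continue
        codes = np.array([k for k in _OUTCOME_KEYS if k in profiles[key]])
        p = np.array([profiles[key][c] for c in codes], dtype=float)
        outcome[mask] = codes[rng.choice(len(codes), size=m, p=p / p.sum())]

    # assemble long tables
    demo = pd.DataFrame({
        "primary_id": primary_id.astype(str), "case_id": case_id.astype(str),
        "event_date": event_dt, "age_years": age, "weight_kg": weight,
        "sex": sex, "reporter_country": country, "fda_receipt_date": fda_dt,
        "_q": q_idx,
    })

    drug_rows = [pd.DataFrame({"primary_id": demo["primary_id"], "drug_seq": 1,
                               "verbatim_name": verbatim, "role_code": "ps"})]
    conc = rng.random(n) < config.concomitant_fraction
    if conc.any():
        conc_names = pool_names[rng.integers(0, len(pool_names), size=int(conc.sum()))]
        drug_rows.append(pd.DataFrame({
            "primary_id": demo.loc[conc, "primary_id"].to_numpy(),
            "drug_seq": 2, "verbatim_name": conc_names, "role_code": "c"}))
    drug = pd.concat(drug_rows, ignore_index=True)

    reac_rows = []
    for k, endpoint in enumerate(endpoints):
        mask = event[:, k]
        m = int(mask.sum())
        if m == 0:
            continue
        terms = np.array(endpoint_terms[endpoint])
        reac_rows.append(pd.DataFrame({
            "primary_id": demo.loc[mask, "primary_id"].to_numpy(),
            "pt": terms[rng.integers(0, len(terms), size=m)]}))
    n_fill = rng.integers(1, 4, size=n)
    filler = np.array(FILLER_PTS)
    reac_rows.append(pd.DataFrame({
        "primary_id": np.repeat(demo["primary_id"].to_numpy(), n_fill),
        "pt": filler[rng.integers(0, len(filler), size=int(n_fill.sum()))]}))
    reac = pd.concat(reac_rows, ignore_index=True)

    has_outcome = outcome != "none"
    outc = pd.DataFrame({"primary_id": demo.loc[has_outcome, "primary_id"].to_numpy(),
                         "outcome_code": outcome[has_outcome]})
    indi = pd.DataFrame({"primary_id": demo["primary_id"], "indi_pt": indi_pt})

    # follow-up versions: same case, later receipt date, larger primary_id,
    # filed one quarter later where possible
    dup = rng.random(n) < config.duplicate_fraction
    if dup.any():
        dup_demo = demo.loc[dup].copy()
        dup_ids = dup_demo["primary_id"].to_numpy()
        new_ids = (dup_demo["case_id"].astype(int) * 10 + 2).astype(str).to_numpy()
        dup_demo["primary_id"] = new_ids
        dup_demo["_q"] = np.minimum(dup_demo["_q"] + 1, len(quarters) - 1)
        dup_demo["fda_receipt_date"] = _quarter_dates(
            rng, quarters[dup_demo["_q"].to_numpy()])
        # a follow-up must sort after the original even within one quarter
        dup_demo["fda_receipt_date"] = np.maximum(
            dup_demo["fda_receipt_date"], demo.loc[dup, "fda_receipt_date"])
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        remap = dict(zip(dup_ids, new_ids))
        for name in ("drug", "reac", "outc", "indi"):
            table = locals()[name]
            sub = table[table["primary_id"].isin(remap)].copy()
            sub["primary_id"] = sub["primary_id"].map(remap)
            if name == "drug":
                drug = pd.concat([drug, sub], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, sub], ignore_index=True)
            elif name == "outc":
                outc = pd.concat([outc, sub], ignore_index=True)
            else:
                indi = pd.concat([indi, sub], ignore_index=True)

    bundles = []
    for qi, label in enumerate(quarters):
        q_demo = demo[demo["_q"] == qi].drop(columns="_q").reset_index(drop=True)
        ids = set(q_demo["primary_id"])
        bundles.append(QuarterBundle(
            quarter_label=label, demo=q_demo,
            drug=drug[drug["primary_id"].isin(ids)].reset_index(drop=True),
            reac=reac[reac["primary_id"].isin(ids)].reset_index(drop=True),
            outc=outc[outc["primary_id"].isin(ids)].reset_index(drop=True),
            indi=indi[indi["primary_id"].isin(ids)].reset_index(drop=True)))
    return bundles


def simulate_to_dir(config: SimulationConfig, outdir: Path | str) -> list[Path]:
    """Generate and write "$"-delimited quarterly files; returns the paths."""
    from .io import write_quarter
    written: list[Path] = []
    for bundle in generate(config):
        written.extend(write_quarter(bundle, outdir).values())
    return written
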