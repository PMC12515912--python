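"""End-to-end orchestration: ingest -> dedup -> cohort -> statistics -> artifacts.

Every run writes a self-describing artifact directory: the signal table
(full precision and report-rounded), the drugs x endpoints signal matrix,
long-format and per-endpoint matrix pairwise contrasts, Table-1-style
descriptive summaries, the rejects log, and a manifest echoing the
configuration, seed, and the report counts at every stage (raw rows ->
deduplicated cases -> cohort cases), so any headline cohort size is
auditable. Identical configuration and seed give byte-identical artifacts.

A separate from-counts entry point runs the statistical core directly on
pre-tabulated (endpoint, drug, a, b, c, d) rows, bypassing I/O and cohort
construction entirely.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as fio
from .cohort import build_cohort
from .descriptive import descriptive_summary
from .dictionaries import (DEFAULT_INDICATION_TERMS, DrugDictionary,
                           EndpointDictionary, default_drug_dictionary,
                           default_endpoint_dictionary)
from .pairwise import all_pairs, or_matrix, pairs_frame
from .signals import (evaluate_all, load_counts_csv, make_tables,
                      results_frame, signal_matrix)
from .simulate import SimulationConfig, generate

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """One pipeline run: either parse quarter files or simulate them."""
    input_dir: Optional[str] = None
    quarters: Optional[list[str]] = None
    csv_dialect: bool = False
    simulate: Optional[SimulationConfig] = None
    drug_dictionary: Optional[str] = None        # YAML path; None -> packaged
    endpoint_dictionary: Optional[str] = None
    indication_terms: list[str] = Field(
        default_factory=lambda: sorted(DEFAULT_INDICATION_TERMS))
    outdir: str = "pv_run"
    seed: Optional[int] = None                   # overrides simulate.seed
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_input(self) -> "RunConfig":
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir or simulate must be set")
        if self.input_dir is not None and not self.quarters:
            raise ValueError("input_dir requires an explicit quarter list")
        return self


class StageError(RuntimeError):
    """Failure of one named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, exc) from exc


def _load_dictionaries(config: RunConfig) -> tuple[DrugDictionary, EndpointDictionary]:
    drugs = (DrugDictionary.from_yaml(config.drug_dictionary)
             if config.drug_dictionary else default_drug_dictionary())
    endpoints = (EndpointDictionary.from_yaml(config.endpoint_dictionary)
                 if config.endpoint_dictionary else default_endpoint_dictionary())
    return drugs, endpoints


def _write_signal_artifacts(outdir: Path, results, drugs, endpoints,
                            tables=None, cohort=None) -> None:
    results_frame(results).to_csv(outdir / "signals_full.csv", index=False)
    results_frame(results, rounded=True).to_csv(outdir / "signals.csv", index=False)
    signal_matrix(results).to_csv(outdir / "signal_matrix.csv")
    long_parts = []
    for endpoint in endpoints:
        kinds = ["constituent-ratio"] + (["severity"] if cohort is not None else [])
        for kind in kinds:
            pairs = all_pairs(endpoint, drugs, kind, tables=tables, cohort=cohort)
            long_parts.append(pairs_frame(pairs))
            or_matrix(pairs).round(4).to_csv(
                outdir / f"pairwise_{kind.replace('-ratio', '')}_{endpoint}.csv")
    pd.concat(long_parts, ignore_index=True).to_csv(
        outdir / "pairwise_long.csv", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured run; returns the artifact directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rejects = fio.RejectLog()
    counts: dict[str, int] = {}

    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = sim.model_copy(update={"seed": config.seed})
        bundles = _stage("simulate", generate, sim)
    else:
        def _ingest():
            profile = fio.CSV_PROFILE if config.csv_dialect else fio.ASCII_PROFILE
            out = []
            for label in config.quarters:
                paths = fio.quarter_paths(config.input_dir, label)
                out.append(fio.parse_quarter(paths, label, profile, rejects))
            return out
        bundles = _stage("ingest", _ingest)
    counts["raw_demo_rows"] = sum(len(b.demo) for b in bundles)

    cases = _stage("deduplicate", fio.deduplicate, bundles)
    counts["deduplicated_cases"] = cases.n_cases
    counts["dropped_versions"] = cases.n_dropped_versions

    drugs, endpoints = _stage("cohort_mapping", _load_dictionaries, config)
    cohort = _stage("cohort_mapping", build_cohort, cases, drugs, endpoints,
                    config.indication_terms)
    counts["cohort_cases"] = cohort.n

    tables = _stage("signal_stats", make_tables, cohort)
    results = _stage("signal_stats", evaluate_all, tables)
    _stage("comparative_stats", _write_signal_artifacts, outdir, results,
           list(cohort.drugs), list(cohort.endpoint_names), tables, cohort)

    summaries = _stage("reporting", lambda: pd.concat(
        [descriptive_summary(cohort, ep).to_frame() for ep in cohort.endpoint_names],
        ignore_index=True))
    summaries.to_csv(outdir / "descriptive.csv", index=False)
    rejects.write_csv(outdir / "rejects.csv")

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": (config.seed if config.seed is not None
                 else (config.simulate.seed if config.simulate else None)),
        "stage_counts": counts,
        "dictionaries": {
            "drugs": {g: sorted(s) for g, s in drugs.synonyms.items()},
            "endpoints": {e: sorted(s) for e, s in endpoints.terms.items()},
            "indication_terms": sorted(t.casefold() for t in config.indication_terms),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", counts)
    return outdir


def run_from_counts(counts_csv: Path | str, outdir: Path | str) -> Path:
    """Statistical core on pre-tabulated contingency rows (no raw data).

    This is the verification surface for published contingency tables:
    signal statistics, flags and constituent-ratio contrasts are computed
    exactly as in a full run, but severity contrasts (which need
    case-level outcomes) are not available.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = _stage("from_counts", load_counts_csv, counts_csv)
    drugs = list(dict.fromkeys(d for d, _ in tables))
    endpoints = list(dict.fromkeys(e for _, e in tables))
    results = _stage("signal_stats", evaluate_all, tables)
    _stage("comparative_stats", _write_signal_artifacts, outdir, results,
           drugs, endpoints, tables, None)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"mode": "from-counts", "source": str(counts_csv),
                   "n_tables": len(tables)}, fh, indent=2, sort_keys=True)
    return outdir
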