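"""faerspv: pharmacovigilance disproportionality analysis of spontaneous
adverse-event reports, with a synthetic report generator for validation."""

from importlib import resources

from .cohort import AnalysisCohort, build_cohort, severity_category
from .dictionaries import (DrugDictionary, EndpointDictionary, ENDPOINTS,
                           default_drug_dictionary, default_endpoint_dictionary,
                           normalize_drug_name)
from .io import (ASCII_PROFILE, CSV_PROFILE, RejectLog, deduplicate,
                 parse_quarter, write_quarter)
from .pairwise import (PairwiseOR, all_pairs, constituent_ratio_or, or_matrix,
                       pairs_frame, severity_or)
from .pipeline import RunConfig, StageError, run_from_counts, run_pipeline
from .records import CaseData, CaseReport, QuarterBundle
from .signals import (ContingencyTable, Estimate, SignalResult, compute_chi2,
                      compute_ic, compute_prr, compute_ror, evaluate_all,
                      evaluate_table, flag_signals, load_counts_csv,
                      make_tables, results_frame, signal_matrix)
from .simulate import SimulationConfig, generate, simulate_to_dir, study_like_config

__version__ = "0.1.0"


def table2_counts_path():
    """Path of the packaged published contingency-cell fixture
    (endpoint, drug, a, b, c, d rows for 8 drugs x 4 endpoints)."""
    return str(resources.files(__name__).joinpath("data", "table2_counts.csv"))


def table2_printed_stats_path():
    """Path of the packaged fixture of the statistics as printed in the
    source table, including the published signal (bolding) pattern."""
    return str(resources.files(__name__).joinpath("data", "table2_printed_stats.csv"))
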