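import pandas as pd
import pytest

import faerspv as pv


@pytest.fixture(scope="session")
def table2_tables():
    """Published 8 drugs x 4 endpoints contingency cells."""
    return pv.load_counts_csv(pv.table2_counts_path())


@pytest.fixture(scope="session")
def table2_printed():
    """The statistics and signal (bolding) pattern as printed."""
    return pd.read_csv(pv.table2_printed_stats_path())


@pytest.fixture(scope="session")
def sim_run():
    """One small study-like simulated run shared across tests:
    bundles -> deduplicated cases -> cohort."""
    config = pv.study_like_config(seed=7, n_reports=20_000)
    bundles = pv.generate(config)
    cases = pv.deduplicate(bundles)
    cohort = pv.build_cohort(cases, pv.default_drug_dictionary(),
                             pv.default_endpoint_dictionary())
    return config, bundles, cases, cohort


def make_bundle(label, demo_rows, drug_rows=(), reac_rows=(), outc_rows=(),
                indi_rows=()):
    """Hand-built bundle from canonical-row tuples (tests only)."""
    demo = pd.DataFrame(demo_rows, columns=[
        "primary_id", "case_id", "event_date", "age_years", "weight_kg",
        "sex", "reporter_country", "fda_receipt_date"])
    drug = pd.DataFrame(list(drug_rows) or None, columns=[
        "primary_id", "drug_seq", "verbatim_name", "role_code"])
    reac = pd.DataFrame(list(reac_rows) or None, columns=["primary_id", "pt"])
    outc = pd.DataFrame(list(outc_rows) or None, columns=["primary_id", "outcome_code"])
    indi = pd.DataFrame(list(indi_rows) or None, columns=["primary_id", "indi_pt"])
    return pv.QuarterBundle(quarter_label=label, demo=demo, drug=drug,
                            reac=reac, outc=outc, indi=indi)
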