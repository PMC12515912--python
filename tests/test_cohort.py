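"""Drug-name normalization, dictionaries, and cohort construction."""
import pandas as pd
import pytest

import faerspv as pv
from faerspv.dictionaries import DrugDictionary, EndpointDictionary

from conftest import make_bundle


@pytest.mark.parametrize("verbatim,expected", [
    ("CITALOPRAM HYDROBROMIDE 20MG", "citalopram"),
    ("Escitalopram", "escitalopram"),
    ("  QUETIAPINE FUMARATE ", "quetiapine"),
    ("Sertraline hydrochloride 50 mg tablets", "sertraline"),
    ("effexor xr", "effexor xr"),
])
def test_normalize_drug_name(verbatim, expected):
    assert pv.normalize_drug_name(verbatim) == expected


def test_normalization_is_idempotent():
    for verbatim in ("CITALOPRAM HYDROBROMIDE 20MG", "Prozac", "a  b   c"):
        once = pv.normalize_drug_name(verbatim)
        assert pv.normalize_drug_name(once) == once


def test_default_dictionaries_are_valid():
    drugs = pv.default_drug_dictionary()
    assert len(drugs.generics) == 8
    assert drugs.lookup("SEROQUEL") == "quetiapine"
    assert drugs.lookup("ibuprofen") is None
    endpoints = pv.default_endpoint_dictionary()
    assert set(endpoints.endpoints) == {"qt_tdp", "af", "heart_block",
                                        "ventricular_arrhythmia"}


def test_overlapping_synonyms_rejected():
    with pytest.raises(ValueError, match="share"):
        DrugDictionary.from_mapping({"a": ["same name"], "b": ["SAME NAME"]})
    with pytest.raises(ValueError, match="share"):
        EndpointDictionary.from_mapping({"e1": ["Pt one"], "e2": ["pt one"]})


def test_empty_dictionary_rejected():
    with pytest.raises(ValueError, match="empty"):
        DrugDictionary.from_mapping({})
    with pytest.raises(ValueError, match="empty"):
        EndpointDictionary.from_mapping({"e1": []})


@pytest.mark.parametrize("outcomes,expected", [
    ({"death", "hospitalization"}, "severe"),
    ({"life-threatening"}, "severe"),
    ({"hospitalization"}, "serious-non-severe"),
    ({"other-serious", "disability"}, "serious-non-severe"),
    (set(), "non-serious"),
])
def test_severity_category(outcomes, expected):
    assert pv.severity_category(outcomes) == expected


def _tiny_cases():
    """Three hand-built cases: one in-cohort with QT+AF PTs, one in-cohort
    unexposed, one excluded by indication."""
    bundle = make_bundle("2023Q1", [
        ("11", "1", "20230101", 40.0, 70.0, "female", "US", "20230110"),
        ("21", "2", "20230102", 50.0, 80.0, "male", "GB", "20230111"),
        ("31", "3", "20230103", 60.0, 90.0, "male", "US", "20230112"),
    ], drug_rows=[
        ("11", 1, "SERTRALINE", "ps"),
        ("11", 2, "QUETIAPINE FUMARATE", "c"),     # concomitant: no exposure
        ("21", 1, "SOME BACKGROUND DRUG", "ps"),
        ("31", 1, "SERTRALINE", "ps"),
    ], reac_rows=[
        ("11", "Atrial fibrillation"),
        ("11", "Electrocardiogram QT prolonged"),
        ("21", "Headache"),
        ("31", "Atrial fibrillation"),
    ], outc_rows=[
        ("11", "death"), ("11", "hospitalization"),
        ("21", "hospitalization"),
    ], indi_rows=[
        ("11", "Depression"), ("21", "Major depression"), ("31", "Hypertension"),
    ])
    return pv.deduplicate([bundle])


def test_build_cohort_flags_and_filters():
    cohort = pv.build_cohort(_tiny_cases(), pv.default_drug_dictionary(),
                             pv.default_endpoint_dictionary())
    assert cohort.n == 2                       # case 3 excluded by indication
    case1 = cohort.cases["case_id"] == "1"
    assert cohort.exposure.loc[case1.values, "sertraline"].all()
    assert not cohort.exposure.loc[case1.values, "quetiapine"].any()
    assert cohort.endpoints.loc[case1.values, ["af", "qt_tdp"]].all(axis=None)
    assert cohort.cases.loc[case1.values, "severity"].iloc[0] == "severe"
    case2 = cohort.cases["case_id"] == "2"
    assert not cohort.exposure.loc[case2.values].any(axis=None)
    assert cohort.cases.loc[case2.values, "severity"].iloc[0] == "serious-non-severe"


def test_endpoint_flags_monotone_in_pt_set():
    """Adding a reaction PT never removes an endpoint flag."""
    cases = _tiny_cases()
    before = pv.build_cohort(cases, pv.default_drug_dictionary(),
                             pv.default_endpoint_dictionary())
    cases.reac = pd.concat([cases.reac, pd.DataFrame(
        [("21", "Torsade de pointes")], columns=["primary_id", "pt"])],
        ignore_index=True)
    after = pv.build_cohort(cases, pv.default_drug_dictionary(),
                            pv.default_endpoint_dictionary())
    assert (before.endpoints.to_numpy() <= after.endpoints.to_numpy()).all()


def test_cohort_invariant_to_case_order(sim_run):
    _, _, cases, cohort = sim_run
    shuffled = pv.CaseData(
        demo=cases.demo.sample(frac=1, random_state=0).reset_index(drop=True),
        drug=cases.drug, reac=cases.reac, outc=cases.outc, indi=cases.indi)
    again = pv.build_cohort(shuffled, pv.default_drug_dictionary(),
                            pv.default_endpoint_dictionary())
    assert again.n == cohort.n
    pd.testing.assert_frame_equal(again.exposure, cohort.exposure)
    pd.testing.assert_frame_equal(again.endpoints, cohort.endpoints)


def test_planted_exposures_recovered_exactly(sim_run):
    """Every suspect mention that maps to a study generic is an exposure;
    the generator's verbatim names map back to their generic."""
    _, _, cases, cohort = sim_run
    drugs = pv.default_drug_dictionary()
    suspect = cases.drug[cases.drug["role_code"].isin({"ps", "ss"})]
    expected = {}
    for pid, name in zip(suspect["primary_id"], suspect["verbatim_name"]):
        generic = drugs.lookup(name)
        if generic:
            expected.setdefault(pid, set()).add(generic)
    index = pd.Index(cohort.cases["primary_id"])
    for drug in cohort.drugs:
        flagged = set(index[cohort.exposure[drug].to_numpy()])
        truth = {pid for pid, gs in expected.items() if drug in gs} & set(index)
        assert flagged == truth


def test_empty_indication_terms_rejected():
    with pytest.raises(ValueError, match="indication"):
        pv.build_cohort(_tiny_cases(), pv.default_drug_dictionary(),
                        pv.default_endpoint_dictionary(), indication_terms=[])
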