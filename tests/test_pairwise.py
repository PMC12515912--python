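"""Pairwise constituent-ratio and severity contrasts."""
import math

import numpy as np
import pytest

import faerspv as pv
from faerspv.signals import ContingencyTable
from faerspv.simulate import DrugSpec, SimulationConfig


class TestConstituentRatio:
    @pytest.mark.parametrize("cells_i,cells_j,expected,ci", [
        # citalopram vs escitalopram and vs duloxetine, QT endpoint,
        # from the published contingency cells
        ((381, 49824), (299, 50299), 1.29, (1.11, 1.50)),
        ((381, 49824), (60, 79205), 10.10, (7.69, 13.26)),
    ])
    def test_published_contrasts(self, cells_i, cells_j, expected, ci):
        t_i = ContingencyTable(cells_i[0], 1, cells_i[1], 1)
        t_j = ContingencyTable(cells_j[0], 1, cells_j[1], 1)
        r = pv.constituent_ratio_or("qt", "i", "j", t_i, t_j)
        assert round(r.or_value, 2) == pytest.approx(expected, abs=0.0101)
        assert round(r.ci_low, 2) == pytest.approx(ci[0], abs=0.0101)
        assert round(r.ci_high, 2) == pytest.approx(ci[1], abs=0.0101)
        assert not r.corrected

    def test_self_contrast_is_unity(self, table2_tables):
        t = table2_tables[("citalopram", "qt_tdp")]
        r = pv.constituent_ratio_or("qt_tdp", "citalopram", "citalopram", t, t)
        assert r.or_value == 1.0

    def test_reciprocity_exact(self, table2_tables):
        t_i = table2_tables[("citalopram", "af")]
        t_j = table2_tables[("quetiapine", "af")]
        fwd = pv.constituent_ratio_or("af", "i", "j", t_i, t_j)
        rev = pv.constituent_ratio_or("af", "j", "i", t_j, t_i)
        assert fwd.or_value * rev.or_value == pytest.approx(1.0, abs=1e-12)
        assert fwd.ci_low == pytest.approx(1.0 / rev.ci_high, abs=1e-12)

    def test_haldane_engages_only_on_zero_cell(self):
        zero = ContingencyTable(0, 5, 100, 5)
        other = ContingencyTable(10, 5, 100, 5)
        r = pv.constituent_ratio_or("e", "i", "j", zero, other)
        assert r.corrected and math.isfinite(r.or_value) and r.or_value > 0
        r2 = pv.constituent_ratio_or("e", "i", "j", other, other)
        assert not r2.corrected


def _severity_sim(profile_a, seed):
    """Two-drug simulation with controlled outcome profiles on one endpoint."""
    return SimulationConfig(
        seed=seed, n_reports=30_000,
        drug_catalog=[DrugSpec(name="druga", share=0.3),
                      DrugSpec(name="drugb", share=0.3)],
        endpoint_rates={"ep1": 0.05},
        endpoint_terms={"ep1": ["Synthetic event one"]},
        indication_share=1.0, duplicate_fraction=0.0,
        severity_profile={"druga": {"ep1": profile_a}})


def _cohort(config):
    drugs = pv.DrugDictionary.from_mapping({d.name: [] for d in config.drug_catalog})
    endpoints = pv.EndpointDictionary.from_mapping(
        {ep: pts for ep, pts in config.endpoint_terms.items()})
    return pv.build_cohort(pv.deduplicate(pv.generate(config)), drugs, endpoints)


class TestSeverity:
    def test_null_profiles_give_unit_or(self):
        # drug a gets exactly the default event profile -> planted OR = 1
        from faerspv.simulate import EVENT_OUTCOME_PROFILE
        cohort = _cohort(_severity_sim(dict(EVENT_OUTCOME_PROFILE), seed=21))
        r = pv.severity_or("ep1", "druga", "drugb", cohort)
        assert r.estimable
        assert r.ci_low < 1.0 < r.ci_high

    def test_planted_severity_odds_recovered(self):
        # severe|known odds for a: 0.6/0.3 = 2; for b (event profile):
        # 0.30/0.53; planted OR = 2 / (0.30/0.53) = 3.53
        profile_a = {"death": 0.30, "life-threatening": 0.30,
                     "hospitalization": 0.20, "other-serious": 0.10, "none": 0.10}
        cohort = _cohort(_severity_sim(profile_a, seed=22))
        r = pv.severity_or("ep1", "druga", "drugb", cohort)
        planted = (0.6 / 0.3) / (0.30 / 0.53)
        assert r.ci_low < planted < r.ci_high
        assert r.or_value > 1.5

    def test_unknown_outcomes_excluded_from_denominator(self):
        profile_a = {"death": 0.10, "none": 0.90}
        cohort = _cohort(_severity_sim(profile_a, seed=23))
        r = pv.severity_or("ep1", "druga", "drugb", cohort)
        sev, non = r.cells[0], r.cells[1]
        known = (cohort.exposure["druga"].to_numpy()
                 & cohort.endpoints["ep1"].to_numpy()
                 & cohort.cases["has_outcome"].to_numpy()).sum()
        assert sev + non == known  # "none" reports are not in the 2x2

    def test_no_known_outcomes_not_estimable(self):
        profile_a = {"none": 1.0}
        cohort = _cohort(_severity_sim(profile_a, seed=24))
        r = pv.severity_or("ep1", "druga", "drugb", cohort)
        assert not r.estimable


class TestAllPairs:
    def test_structure_and_diagonal(self, table2_tables):
        drugs = ["citalopram", "sertraline", "duloxetine"]
        pairs = pv.all_pairs("qt_tdp", drugs, "constituent-ratio",
                             tables=table2_tables)
        assert len(pairs) == 9
        matrix = pv.or_matrix(pairs)
        assert np.allclose(np.diag(matrix.loc[drugs, drugs]), 1.0)
        assert np.allclose(matrix.to_numpy() * matrix.to_numpy().T, 1.0,
                           atol=1e-12)

    def test_significance_marks_ci_excluding_one(self, table2_tables):
        pairs = pv.all_pairs("qt_tdp", ["citalopram", "duloxetine"],
                             "constituent-ratio", tables=table2_tables)
        frame = pv.pairs_frame(pairs)
        off = frame[frame.drug_i != frame.drug_j]
        assert off["significant"].all()   # the 10.10 contrast and inverse

    def test_single_drug_rejected(self, table2_tables):
        with pytest.raises(ValueError, match="two drugs"):
            pv.all_pairs("qt_tdp", ["citalopram"], "constituent-ratio",
                         tables=table2_tables)
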