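"""Disproportionality statistics: published-row checks, algebraic
invariants, and independent-library cross-checks."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

import faerspv as pv
from faerspv.signals import ContingencyTable, flag_signals

CELL = st.integers(min_value=1, max_value=500)


class TestAgainstPublishedRows:
    """Rows whose statistics appear in the published signal table."""

    @pytest.mark.parametrize("cells,prr,ci", [
        ((381, 2290, 49824, 694012), 2.31, (2.07, 2.57)),
        ((43, 573, 22720, 723171), 2.39, (1.75, 3.25)),
    ])
    def test_prr(self, cells, prr, ci):
        est = pv.compute_prr(ContingencyTable(*cells))
        assert round(est.value, 2) == prr
        assert (round(est.low, 2), round(est.high, 2)) == ci

    @pytest.mark.parametrize("cells,ror,ci", [
        ((381, 2290, 49824, 694012), 2.32, (2.08, 2.58)),
        ((62, 554, 50150, 695741), 1.55, (1.19, 2.02)),
    ])
    def test_ror(self, cells, ror, ci):
        est = pv.compute_ror(ContingencyTable(*cells))
        assert round(est.value, 2) == ror
        assert (round(est.low, 2), round(est.high, 2)) == ci

    @pytest.mark.parametrize("cells,chi2", [
        ((381, 2290, 49824, 694012), 241.669),
        ((43, 573, 22720, 723171), 30.912),
    ])
    def test_chi2(self, cells, chi2):
        assert round(pv.compute_chi2(ContingencyTable(*cells)), 3) == chi2

    @pytest.mark.parametrize("cells,ic,ci", [
        ((381, 2290, 49824, 694012), 1.08, (0.91, 1.21)),
        ((43, 573, 22720, 723171), 1.17, (0.67, 1.54)),
    ])
    def test_ic(self, cells, ic, ci):
        est = pv.compute_ic(ContingencyTable(*cells))
        assert round(est.value, 2) == ic
        assert (round(est.low, 2), round(est.high, 2)) == ci

    @pytest.mark.parametrize("cells,expected", [
        # all three criteria met
        ((381, 2290, 49824, 694012), (True, True, True)),
        # PRR below 2 but ROR lower bound and IC025 above their thresholds
        ((299, 2372, 50299, 693537), (False, True, True)),
        # IC025 barely negative, ROR lower bound barely above 1
        ((61, 628, 50537, 695281), (False, True, False)),
    ])
    def test_flag_pattern(self, cells, expected):
        result = pv.evaluate_table("drug", "endpoint", ContingencyTable(*cells))
        assert (result.prr_signal, result.ror_signal, result.ic_signal) == expected


class TestDegenerateTables:
    def test_symmetric_table_is_null(self):
        t = ContingencyTable(10, 10, 90, 90)
        assert pv.compute_prr(t).value == pytest.approx(1.0)
        assert pv.compute_ror(t).value == pytest.approx(1.0)
        assert pv.compute_chi2(t) == 0.0

    def test_zero_a_not_estimable_but_ic_defined(self):
        t = ContingencyTable(0, 100, 50, 850)
        assert not pv.compute_prr(t).estimable
        assert not pv.compute_ror(t).estimable
        ic = pv.compute_ic(t)
        assert ic.estimable and ic.value < 0
        result = pv.evaluate_table("d", "e", t)
        assert not (result.prr_signal or result.ror_signal)

    def test_ic_zero_when_observed_equals_expected(self):
        # E = (a+b)(a+c)/N = 100*100/1000 = 10 = a
        assert pv.compute_ic(ContingencyTable(10, 90, 90, 810)).value == 0.0

    def test_zero_margin_chi2_not_estimable(self):
        assert math.isnan(pv.compute_chi2(ContingencyTable(0, 0, 50, 850)))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestCrossChecks:
    """Independent oracles: scipy for the corrected chi-square, statsmodels
    for the odds ratio and its Woolf interval."""

    @pytest.mark.parametrize("cells", [
        (381, 2290, 49824, 694012), (43, 573, 22720, 723171),
        (5, 7, 11, 13), (120, 2551, 22643, 721193),
    ])
    def test_chi2_matches_scipy(self, cells):
        a, b, c, d = cells
        expected = chi2_contingency([[a, b], [c, d]], correction=True).statistic
        assert pv.compute_chi2(ContingencyTable(*cells)) == pytest.approx(expected)

    @pytest.mark.parametrize("cells", [
        (381, 2290, 49824, 694012), (5, 7, 11, 13), (62, 554, 50150, 695741),
    ])
    def test_ror_matches_statsmodels(self, cells):
        a, b, c, d = cells
        table = Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
        est = pv.compute_ror(ContingencyTable(*cells))
        assert est.value == pytest.approx(table.oddsratio)
        low, high = table.oddsratio_confint(0.05)
        # statsmodels uses the exact normal quantile, this package the
        # conventional rounded 1.96 -> agree to ~1e-4 relative
        assert est.low == pytest.approx(low, rel=1e-3)
        assert est.high == pytest.approx(high, rel=1e-3)


class TestAlgebraicInvariants:
    @settings(max_examples=200, deadline=None)
    @given(a=CELL, b=CELL, c=CELL, d=CELL)
    def test_yates_never_exceeds_uncorrected(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        uncorrected = chi2_contingency([[a, b], [c, d]], correction=False).statistic
        assert pv.compute_chi2(t) <= uncorrected + 1e-9

    @settings(max_examples=200, deadline=None)
    @given(a=CELL, b=CELL, c=CELL, d=CELL)
    def test_ror_prr_ordering_identity(self, a, b, c, d):
        """sign(ROR - PRR) = sign(ROR - 1): the odds ratio always lies on
        the far side of its proportion ratio relative to the null."""
        t = ContingencyTable(a, b, c, d)
        ror = pv.compute_ror(t).value
        prr = pv.compute_prr(t).value
        assert math.copysign(1, ror - prr) == math.copysign(1, ror - 1) \
            or ror == pytest.approx(prr)

    @settings(max_examples=200, deadline=None)
    @given(a=CELL, b=CELL, c=CELL, d=CELL)
    def test_interval_ordering(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        for est in (pv.compute_prr(t), pv.compute_ror(t), pv.compute_ic(t)):
            assert est.low < est.value < est.high

    @settings(max_examples=100, deadline=None)
    @given(a=CELL, b=CELL, c=CELL, d=CELL)
    def test_flags_deterministic(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        prr, ror, ic = pv.compute_prr(t), pv.compute_ror(t), pv.compute_ic(t)
        chi2 = pv.compute_chi2(t)
        assert flag_signals(t, prr, chi2, ror, ic) == \
            flag_signals(t, prr, chi2, ror, ic)


class TestMakeTables:
    def test_hand_counted_cells(self, sim_run):
        """Cells agree with direct boolean counting on the cohort."""
        _, _, _, cohort = sim_run
        tables = pv.make_tables(cohort)
        drug, endpoint = "citalopram", "qt_tdp"
        exposed = cohort.exposure[drug].to_numpy()
        event = cohort.endpoints[endpoint].to_numpy()
        t = tables[(drug, endpoint)]
        assert t.a == int((exposed & event).sum())
        assert t.b == int((~exposed & event).sum())
        assert t.c == int((exposed & ~event).sum())
        assert t.d == int((~exposed & ~event).sum())

    def test_margins_and_grand_total(self, sim_run):
        _, _, _, cohort = sim_run
        tables = pv.make_tables(cohort)
        for endpoint in cohort.endpoint_names:
            margins = {t.a + t.b for (d, e), t in tables.items() if e == endpoint}
            assert margins == {cohort.endpoint_total(endpoint)}
        assert {t.n for t in tables.values()} == {cohort.n}

    def test_unexposed_drug_gives_zero_row(self, sim_run):
        _, _, _, cohort = sim_run
        ghost = cohort.exposure.copy()
        ghost["nosuchdrug"] = False
        modified = pv.AnalysisCohort(cases=cohort.cases, exposure=ghost,
                                     endpoints=cohort.endpoints,
                                     drugs=cohort.drugs + ("nosuchdrug",),
                                     endpoint_names=cohort.endpoint_names)
        t = pv.make_tables(modified)[("nosuchdrug", "qt_tdp")]
        assert t.a == 0 and t.c == 0
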