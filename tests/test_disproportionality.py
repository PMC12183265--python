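"""ROR/BCPNN statistics, signal rules and inverse table reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosig import disproportionality as dp
from cardiosig import synthetic_faers as sf
from cardiosig.report_store import AdverseEventReport

cells = st.integers(min_value=1, max_value=5000)


class TestRorStatistic:
    def test_independence_gives_unity(self):
        r = dp.ror_statistic(dp.ContingencyTable(5, 10, 50, 100))
        assert r.ror == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = dp.ror_statistic(dp.ContingencyTable(3, 7, 30, 960))
        assert r.ror == pytest.approx(13.714, abs=5e-4)
        assert r.ror_l == pytest.approx(3.38, abs=5e-3)
        assert r.ror_u == pytest.approx(55.65, abs=5e-2)
        assert not r.corrected

    def test_zero_cell_triggers_haldane(self):
        r = dp.ror_statistic(dp.ContingencyTable(3, 0, 30, 960))
        assert r.corrected
        expected = (3.5 * 960.5) / (0.5 * 30.5)
        assert r.ror == pytest.approx(expected)

    def test_ci_symmetric_on_log_scale(self):
        r = dp.ror_statistic(dp.ContingencyTable(12, 88, 240, 4660))
        assert math.log(r.ror_u) - math.log(r.ror) == pytest.approx(
            math.log(r.ror) - math.log(r.ror_l)
        )

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, derandomize=True)
    def test_swap_invariance(self, a, b, c, d):
        base = dp.ror_statistic(dp.ContingencyTable(a, b, c, d))
        diag = dp.ror_statistic(dp.ContingencyTable(d, c, b, a))
        rows = dp.ror_statistic(dp.ContingencyTable(c, d, a, b))
        assert diag.ror == pytest.approx(base.ror)
        assert rows.ror == pytest.approx(1.0 / base.ror)

    def test_haldane_converges_for_large_cells(self):
        a, b, c, d = 1000, 2000, 3000, 4000
        plain = dp.ror_components(a, b, c, d)[0]
        shifted = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        assert abs(shifted - plain) / plain < 0.01


class TestBcpnnIc:
    def test_empty_cell_shrinks_below_independence(self):
        r = dp.bcpnn_ic(dp.ContingencyTable(0, 50, 60, 4000))
        assert r.ic < 0

    def test_monotone_in_cell_count(self):
        # fixed margins: a + b = 100, a + c = 120, N = 2000
        ics = []
        for a in range(0, 60, 5):
            t = dp.ContingencyTable(a, 100 - a, 120 - a, 2000 - 220 + a)
            ics.append(dp.bcpnn_ic(t).ic)
        assert all(x < y for x, y in zip(ics, ics[1:]))

    def test_exact_moments_match_sampling_oracle(self):
        # posterior draws of log2(p11/(px py)) under the independent-Beta
        # parametrization; the closed form must sit within MC error
        rng = np.random.default_rng(42)
        n = 200_000
        for table in [(25, 75, 900, 9000), (3, 40, 11, 2000), (60, 60, 60, 60)]:
            a, b, c, d = table
            N = a + b + c + d
            gamma = (N + 2) ** 2 / ((a + b + 1) * (a + c + 1))
            p11 = rng.beta(a + 1, N - a + gamma - 1, n)
            px = rng.beta(a + b + 1, N - (a + b) + 1, n)
            py = rng.beta(a + c + 1, N - (a + c) + 1, n)
            draws = np.log2(p11 / (px * py))
            res = dp.bcpnn_ic(dp.ContingencyTable(a, b, c, d))
            assert res.ic == pytest.approx(draws.mean(), abs=3 * draws.std() / math.sqrt(n))
            # SE of the sample SD via the empirical fourth moment
            m2 = draws.var()
            m4 = np.mean((draws - draws.mean()) ** 4)
            se_sd = math.sqrt(max(m4 - m2**2, 0) / (4 * m2 * n))
            assert res.ic_sd == pytest.approx(draws.std(), abs=3 * se_sd)

    def test_approx_method_close_to_exact_for_large_counts(self):
        t = dp.ContingencyTable(500, 1500, 4500, 93500)
        exact = dp.bcpnn_ic(t, method="exact")
        approx = dp.bcpnn_ic(t, method="approx")
        assert approx.ic == pytest.approx(exact.ic, abs=0.01)

    def test_bounds_definition(self):
        r = dp.bcpnn_ic(dp.ContingencyTable(25, 75, 900, 9000))
        assert r.ic025 == pytest.approx(r.ic - 1.96 * r.ic_sd)
        assert r.ic_minus_2sd == pytest.approx(r.ic - 2 * r.ic_sd)


class TestClassifySignal:
    def _score(self, **kw):
        base = dict(n_cases=10, ror=5, ror_l=2, ror_u=10, se_ln_ror=0.3,
                    ic=1, ic_sd=0.2, ic025=0.6, ic_minus_2sd=0.6)
        base.update(kw)
        return dp.SignalScore(**base)

    def test_case_count_gate(self):
        s = dp.classify_signal(self._score(n_cases=2, ror_l=5.0))
        assert not s.ror_positive and s.strength_ror == "none"

    def test_weak_ror_signal(self):
        s = dp.classify_signal(self._score(n_cases=59, ror_l=3.02))
        assert s.ror_positive and s.strength_ror == "weak"

    def test_ror_tier_boundaries(self):
        assert dp.classify_signal(self._score(ror_l=50.0)).strength_ror == "moderate"
        assert dp.classify_signal(self._score(ror_l=1000.0)).strength_ror == "strong"

    def test_ic_upper_boundary_inclusive(self):
        s = dp.classify_signal(self._score(ic025=0.5, ic_minus_2sd=3.0))
        assert s.strength_bcpnn == "moderate"
        s = dp.classify_signal(self._score(ic025=0.5, ic_minus_2sd=3.0001))
        assert s.strength_bcpnn == "strong"

    def test_bcpnn_gate_uses_ic025(self):
        s = dp.classify_signal(self._score(ic025=-0.01, ic_minus_2sd=0.5))
        assert not s.bcpnn_positive and s.strength_bcpnn == "none"


class TestBuildContingency:
    def test_single_report_with_both(self):
        r = AdverseEventReport("R1", [("osimertinib", "primary_suspect")], ["X"])
        t = dp.build_contingency([r], "osimertinib", "X")
        assert t.as_tuple() == (1, 0, 0, 0)

    def test_table2_fixture_cells(self, table2_fixture):
        reports, expected = table2_fixture
        t = dp.build_contingency(reports, "osimertinib", "Pericardial effusion")
        assert t.a == 59
        assert t.b == 15_382 - 59
        # background cells live in the analytic expectation table
        assert expected.loc["Pericardial effusion", "c"] == 18169

    def test_generator_cells_match_brute_force(self, small_config):
        reports, truth = sf.generate_reports(small_config)
        drug, event = truth.drugs[1], truth.events[2]
        t = dp.build_contingency(reports, drug, event)
        # brute-force recount straight off the report list
        a = sum(1 for r in reports
                if r.has_drug(drug, "primary_suspect") and r.has_event(event))
        n_drug = sum(1 for r in reports if r.has_drug(drug, "primary_suspect"))
        n_event = sum(1 for r in reports if r.has_event(event))
        assert t.a == a
        assert t.b == n_drug - a
        assert t.c == n_event - a
        assert t.d == len(reports) - n_drug - n_event + a
        # and the matrix path agrees with the ground-truth tally
        assert np.array_equal(
            dp.contingency_matrix(reports)[2], truth.cell_counts()
        )

    def test_absent_drug_gives_zero_a(self):
        r = AdverseEventReport("R1", [("gefitinib", "primary_suspect")], ["X"])
        t = dp.build_contingency([r], "osimertinib", "X")
        assert t.a == 0


class TestReconstructBackground:
    def test_pericardial_effusion_row(self):
        t = dp.reconstruct_background(59, 15_323, 3.02, 5.04)
        assert round(dp.ror_statistic(t).ror, 2) == 3.90

    def test_cardiac_dysfunction_row(self):
        t = dp.reconstruct_background(24, 15_358, 4.02, 9.00)
        assert round(dp.ror_statistic(t).ror, 2) == 6.02

    def test_round_trip_closure(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            a = int(rng.integers(3, 400))
            b = int(rng.integers(3, 20_000))
            c = int(rng.integers(3, 5_000))
            d = int(rng.integers(3, 2_000_000))
            r = dp.ror_statistic(dp.ContingencyTable(a, b, c, d))
            back = dp.reconstruct_background(a, b, r.ror_l, r.ror_u)
            assert (back.c, back.d) == (c, d)

    def test_infeasible_row_raises(self):
        # CI far too tight for the case count: se^2 < 1/a + 1/b
        with pytest.raises(dp.InfeasibleTableError, match="slack"):
            dp.reconstruct_background(10, 100, 2.0, 2.1)
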