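"""Protocol enumeration, argmax selection, threshold solving, and
decision-region maps."""

import math

import numpy as np
import pytest

from inbdx import (
    ActionKind,
    DiagnosticTest,
    Protocol,
    Rule,
    best_action,
    decision_map,
    enumerate_protocols,
    global_test_bounds,
    inb_protocol,
    pairwise_transition_p,
    protocol_thresholds_p,
    transition_threshold_p,
)
from inbdx.casestudies import random_panel


class TestEnumeration:
    def test_three_tests_give_33_protocols(self, prostate):
        assert len(enumerate_protocols(list(prostate.tests))) == 33

    def test_single_test_gives_one_protocol(self):
        assert len(enumerate_protocols(random_panel(1, 0))) == 1

    def test_two_tests_give_six_protocols(self):
        protos = enumerate_protocols(random_panel(2, 0))
        assert len(protos) == 6
        rules = sorted(p.rule.value for p in protos if len(p) == 2)
        assert rules == ["and", "and", "or", "or"]

    def test_four_tests_count_matches_combinatorics(self):
        protos = enumerate_protocols(random_panel(4, 0))
        # 4 singles + (12+24) AND + (12+24) OR + 24 majority triples
        expected = 4 + 2 * (math.perm(4, 2) + math.perm(4, 3) + math.perm(4, 4)) + math.perm(4, 3)
        assert len(protos) == expected

    def test_oversize_panel_rejected_with_estimate(self):
        with pytest.raises(ValueError, match="protocols"):
            enumerate_protocols(random_panel(7, 0))


class TestBestAction:
    def test_huge_losses_never_test(self):
        panel = [DiagnosticTest(f"T{i}", 0.9, 0.9, loss_over_b=10.0) for i in range(2)]
        protos = enumerate_protocols(panel)
        low = best_action(0.2, 0.5, protos)
        high = best_action(0.8, 0.5, protos)
        assert low.kind is ActionKind.NO_TEST_NO_TREAT
        assert high.kind is ActionKind.TREAT_WITHOUT_TESTING

    def test_prostate_single_ft_optimal_midrange(self, prostate):
        protos = enumerate_protocols(list(prostate.tests))
        action = best_action(0.30, 0.26, protos)
        assert action.kind is ActionKind.TEST
        assert action.protocol.id == "FT"

    def test_below_minimum_test_threshold_no_action(self, prostate):
        protos = enumerate_protocols(list(prostate.tests))
        action = best_action(0.05, 0.26, protos)
        assert action.kind is ActionKind.NO_TEST_NO_TREAT
        assert action.inb_value < 0

    def test_test_label_carries_positive_inb(self, prostate):
        protos = enumerate_protocols(list(prostate.tests))
        action = best_action(0.30, 0.26, protos)
        assert action.inb_value > 0
        assert action.inb_value == pytest.approx(
            inb_protocol(action.protocol, 0.30, 0.26)
        )


class TestProtocolThresholds:
    def test_conjunctive_pair_lower_threshold(self, prostate):
        proto = Protocol([prostate.test("hK2"), prostate.test("FT")], Rule.AND)
        ts = protocol_thresholds_p(proto, 0.26)
        assert round(ts.p_test, 2) == 0.12

    def test_disjunctive_pair_upper_threshold(self, prostate):
        proto = Protocol([prostate.test("FT"), prostate.test("hK2")], Rule.OR)
        ts = protocol_thresholds_p(proto, 0.26)
        assert round(ts.p_test_treat, 2) == 0.63

    def test_inb_vanishes_at_protocol_thresholds(self, prostate):
        for proto in enumerate_protocols(list(prostate.tests)):
            ts = protocol_thresholds_p(proto, 0.26)
            if ts.p_test is not None and 0 < ts.p_test < 0.26:
                assert abs(inb_protocol(proto, ts.p_test, 0.26)) < 1e-10
            if ts.p_test_treat is not None and 0.26 <= ts.p_test_treat < 1:
                assert abs(inb_protocol(proto, ts.p_test_treat, 0.26)) < 1e-10

    def test_hopeless_protocol_has_no_interval(self):
        t = DiagnosticTest("X", 0.8, 0.8, loss_over_b=5.0)
        ts = protocol_thresholds_p(Protocol([t]), 0.4)
        assert ts.p_test is None and ts.p_test_treat is None


class TestTransitions:
    def test_ft_to_disjunctive_pair(self, prostate):
        single = Protocol([prostate.test("FT")])
        pair = Protocol([prostate.test("FT"), prostate.test("hK2")], Rule.OR)
        assert round(transition_threshold_p(single, pair, 0.26), 2) == 0.44

    def test_same_protocol_returns_none(self, prostate):
        proto = Protocol([prostate.test("FT")])
        assert transition_threshold_p(proto, proto, 0.26) is None

    def test_single_test_case_reduces_to_closed_form(self, prostate):
        ft, hk2 = prostate.test("FT"), prostate.test("hK2")
        via_protocols = transition_threshold_p(
            Protocol([ft]), Protocol([hk2]), 0.26
        )
        via_closed_form = pairwise_transition_p(ft, hk2, 0.26)
        if via_protocols is not None and via_closed_form is not None:
            assert via_protocols == pytest.approx(via_closed_form, abs=1e-10)

    def test_agrees_with_grid_scan(self, prostate):
        single = Protocol([prostate.test("FT")])
        pair = Protocol([prostate.test("FT"), prostate.test("hK2")], Rule.OR)
        rho = 0.26
        grid = np.arange(rho, 1.0, 1e-4)
        diff = np.array(
            [inb_protocol(single, p, rho) - inb_protocol(pair, p, rho) for p in grid]
        )
        sign_changes = grid[np.where(np.diff(np.sign(diff)) != 0)[0]]
        crossing = transition_threshold_p(single, pair, rho)
        assert any(abs(crossing - s) < 2e-4 for s in sign_changes)


class TestGlobalBounds:
    def test_prostate_overall_range(self, prostate):
        protos = enumerate_protocols(list(prostate.tests))
        lo, hi = global_test_bounds(protos, 0.26)
        assert round(lo, 2) == 0.12
        assert round(hi, 2) == 0.63

    def test_single_protocol_list_returns_own_interval(self, prostate):
        proto = Protocol([prostate.test("FT")])
        ts = protocol_thresholds_p(proto, 0.26)
        lo, hi = global_test_bounds([proto], 0.26)
        assert lo == ts.p_test and hi == ts.p_test_treat

    def test_bounds_bracket_every_test_cell(self, prostate):
        protos = enumerate_protocols(list(prostate.tests))
        lo, hi = global_test_bounds(protos, 0.26)
        for p in np.linspace(0.01, 0.99, 99):
            action = best_action(float(p), 0.26, protos)
            if action.kind is ActionKind.TEST:
                assert lo - 1e-9 <= p <= hi + 1e-9


class TestDecisionMap:
    def test_hopeless_panel_splits_at_diagonal(self):
        panel = [DiagnosticTest(f"T{i}", 0.9, 0.9, loss_over_b=10.0) for i in range(2)]
        dm = decision_map(panel, n_grid=21)
        for i, rho in enumerate(dm.rho_grid):
            for j, p in enumerate(dm.p_grid):
                expected = dm.NO_TEST if p < rho else dm.TREAT
                assert dm.labels[i, j] == expected

    def test_prostate_row_test_cells_inside_global_bounds(self, prostate):
        protos = enumerate_protocols(list(prostate.tests))
        rho_grid = np.array([0.26])
        p_grid = np.linspace(0.005, 0.995, 199)
        dm = decision_map(list(prostate.tests), p_grid=p_grid, rho_grid=np.array([0.25, 0.26]))
        lo, hi = global_test_bounds(protos, 0.26)
        row = dm.labels[1]
        test_ps = dm.p_grid[row >= 0]
        assert test_ps.min() >= lo - 1e-9
        assert test_ps.max() <= hi + 1e-9

    def test_map_agrees_with_scalar_best_action(self, prostate):
        dm = decision_map(list(prostate.tests), n_grid=9)
        protos = list(dm.protocols)
        for i, rho in enumerate(dm.rho_grid):
            for j, p in enumerate(dm.p_grid):
                action = best_action(float(p), float(rho), protos)
                assert dm.inb[i, j] == pytest.approx(action.inb_value, abs=1e-12)
                if action.kind is ActionKind.TEST:
                    assert dm.label_name(i, j) == action.protocol.id
                else:
                    assert dm.labels[i, j] in (dm.NO_TEST, dm.TREAT)

    def test_test_cells_beat_random_competitors(self, prostate):
        rng = np.random.default_rng(0)
        dm = decision_map(list(prostate.tests), n_grid=15)
        protos = dm.protocols
        cells = np.argwhere(dm.labels >= 0)
        rng.shuffle(cells)
        for i, j in cells[:10]:
            p, rho = float(dm.p_grid[j]), float(dm.rho_grid[i])
            winner = protos[dm.labels[i, j]]
            assert dm.inb[i, j] > 0
            for k in rng.choice(len(protos), size=20, replace=True):
                rival = protos[int(k)]
                assert inb_protocol(winner, p, rho) >= inb_protocol(rival, p, rho) - 1e-12

    def test_long_format_export(self, prostate):
        dm = decision_map(list(prostate.tests), n_grid=5)
        df = dm.to_frame()
        assert list(df.columns) == ["p", "rho", "label", "inb"]
        assert len(df) == 25
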