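"""Unit and property tests for the 2x2 disproportionality statistics."""

import math

import numpy as np
import pytest

from pvsignal import (
    ContingencyTable,
    SignalCriteria,
    SignalStats,
    ValidationError,
    build_contingency,
    compute_signal_table,
    evaluate_signal,
    ic,
    prr,
    ror,
)


class TestPointEstimates:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 90, 100, 900), 1.0),  # identical reporting proportions
            ((20, 80, 10, 890), 18.0),  # (20/100)/(10/900)
        ],
    )
    def test_prr(self, table, expected):
        assert prr(ContingencyTable(*table)).estimate == pytest.approx(expected)

    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 90, 100, 900), 1.0),  # ad = bc
            ((20, 80, 10, 890), 22.25),  # (20*890)/(80*10)
        ],
    )
    def test_ror(self, table, expected):
        assert ror(ContingencyTable(*table)).estimate == pytest.approx(expected)

    def test_ic_zero_when_observed_equals_expected(self):
        # (10, 90, 90, 810): E = 100*100/1000 = 10 = a, so log2(10.5/10.5) = 0
        assert ic(ContingencyTable(10, 90, 90, 810)).estimate == 0.0

    def test_ic_hand_value(self):
        t = ContingencyTable(20, 80, 10, 890)
        assert t.expected == pytest.approx(3.0)
        assert ic(t).estimate == pytest.approx(math.log2(20.5 / 3.5))

    def test_prr_wald_interval_hand_value(self):
        est = prr(ContingencyTable(20, 80, 10, 890))
        assert est.ci_low == pytest.approx(8.67, abs=0.01)
        assert est.ci_high == pytest.approx(37.37, abs=0.01)


class TestUndefinedAndErrors:
    def test_prr_undefined_zero_cells(self):
        assert not prr(ContingencyTable(0, 100, 10, 890)).defined
        assert not prr(ContingencyTable(10, 90, 0, 900)).defined

    def test_ror_undefined_any_zero_cell(self):
        for table in [(0, 1, 1, 1), (1, 0, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)]:
            assert not ror(ContingencyTable(*table)).defined

    def test_prr_precondition(self):
        with pytest.raises(ValidationError):
            prr(ContingencyTable(0, 0, 10, 890))

    def test_ic_empty_table(self):
        with pytest.raises(ValidationError):
            ic(ContingencyTable(0, 0, 0, 0))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 1, 1, 1)


def _all_tables(n_max, min_cell=0):
    rng = np.arange(n_max + 1)
    a, b, c, d = np.meshgrid(rng, rng, rng, rng, indexing="ij")
    flat = np.stack([x.ravel() for x in (a, b, c, d)], axis=1)
    total = flat.sum(axis=1)
    keep = (total >= 1) & (total <= n_max) & (flat >= min_cell).all(axis=1)
    return flat[keep]


class TestProperties:
    def test_ror_at_least_as_extreme_as_prr(self):
        """For every all-positive table with N <= 40, PRR and ROR deviate
        from 1 in the same direction and ROR is the more extreme."""
        t = _all_tables(40, min_cell=1).astype(float)
        a, b, c, d = t.T
        prr_v = (a / (a + b)) / (c / (c + d))
        ror_v = (a * d) / (b * c)
        up = prr_v >= 1
        assert np.all(ror_v[up] >= prr_v[up])
        assert np.all(ror_v[~up] <= prr_v[~up])

    def test_prr_close_to_ror_for_rare_events(self):
        """When the event is rare in the universe ((a+c)/N < 1%), the two
        ratios agree within 5% — consistent with near-equal reported pairs."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            n_target = int(rng.integers(200, 2000))
            n_other = int(rng.integers(20_000, 80_000))
            a = int(rng.integers(1, max(2, n_target // 200)))
            c = int(rng.integers(1, n_other // 200))
            t = ContingencyTable(a, n_target - a, c, n_other - c)
            if (t.a + t.c) / t.n >= 0.01:
                continue
            p, r = prr(t).estimate, ror(t).estimate
            assert abs(p - r) / r < 0.05
            checked += 1

    def test_ic_shrinks_toward_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            a = int(rng.integers(1, 50))
            b = int(rng.integers(0, 500))
            c = int(rng.integers(0, 500))
            d = int(rng.integers(0, 5000))
            t = ContingencyTable(a, b, c, d)
            e = t.expected
            if e == 0 or a == e:
                continue
            assert abs(ic(t).estimate) <= abs(math.log2(a / e)) + 1e-12

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            t = ContingencyTable(*(int(rng.integers(1, 40)) for _ in range(4)))
            for est in (prr(t), ror(t), ic(t)):
                assert est.ci_low <= est.estimate <= est.ci_high


class TestEvaluateSignal:
    def _stats(self, table):
        return SignalStats.from_table("PT", ContingencyTable(*table))

    def test_clear_signal(self):
        # comfortably over every threshold, like a pair printing PRR=2.2, ROR=2.2
        ok, failed = evaluate_signal(self._stats((30, 170, 100, 1700)))
        assert ok and failed == []

    def test_prr_below_threshold_named(self):
        # PRR just under 2 with everything else passing is not a signal
        stats = self._stats((100, 900, 1026, 18974))
        assert 1.8 < stats.prr.estimate < 2.0 <= stats.ror.estimate
        ok, failed = evaluate_signal(stats)
        assert not ok and failed == ["prr"]

    def test_min_count_blocks_extreme_ratios(self):
        stats = self._stats((2, 10, 1, 10000))
        assert stats.prr.estimate > 100
        ok, failed = evaluate_signal(stats)
        assert not ok and "min_count" in failed

    def test_undefined_statistics_never_signal(self):
        ok, failed = evaluate_signal(self._stats((5, 10, 0, 1000)))
        assert not ok
        assert "prr_undefined" in failed and "ror_undefined" in failed


class TestContingencyConstruction:
    def test_hand_enumerated_six_cases(self, six_case_universe, six_case_target):
        t = build_contingency(six_case_universe, six_case_target, "Nausea")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)

    def test_absent_pt(self, six_case_universe, six_case_target):
        t = build_contingency(six_case_universe, six_case_target, "Vertigo")
        assert t.a == 0 and t.c == 0 and t.n == 6

    def test_marginals_conserve_case_pt_pairs(self, six_case_universe, six_case_target):
        pts = set(six_case_universe.reactions["pt"])
        total = sum(
            build_contingency(six_case_universe, six_case_target, pt).a
            + build_contingency(six_case_universe, six_case_target, pt).c
            for pt in pts
        )
        # brute-force distinct (case, PT) pairs: T1 has 2, N1's repeated Nausea is 1
        assert total == 7 == len(six_case_universe.case_pt_pairs())

    def test_target_must_be_subset(self, six_case_universe, six_case_target):
        with pytest.raises(ValidationError):
            build_contingency(six_case_target, six_case_universe, "Nausea")

    def test_vectorised_table_agrees_with_scalar_route(self, six_case_universe, six_case_target):
        table = compute_signal_table(six_case_universe, six_case_target, criteria=SignalCriteria())
        for row in table.itertuples(index=False):
            t = build_contingency(six_case_universe, six_case_target, row.pt)
            stats = SignalStats.from_table(row.pt, t)
            assert row.a == t.a
            assert row.expected == pytest.approx(t.expected)
            if stats.prr.defined:
                assert row.prr == pytest.approx(stats.prr.estimate)
                assert row.prr_low == pytest.approx(stats.prr.ci_low)
            else:
                assert np.isnan(row.prr)
            if stats.ror.defined:
                assert row.ror == pytest.approx(stats.ror.estimate)
            assert row.ic == pytest.approx(stats.ic.estimate)
            assert row.ic_low == pytest.approx(stats.ic.ci_low)
            assert row.is_signal == evaluate_signal(stats)[0]
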