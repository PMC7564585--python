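from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spcquant import samesame as ss

from conftest import matrix_from_counts


def brute_force_splits(items, k):
    """Oracle: every ordered k-subset, deduplicated as unordered pairs."""
    items = sorted(items)
    seen = set()
    for combo in combinations(items, k):
        rest = tuple(x for x in items if x not in combo)
        key = frozenset((frozenset(combo), frozenset(rest)))
        seen.add(key)
    return seen


class TestEnumeratePartitions:
    def test_six_replicates_give_exactly_ten(self):
        assert len(ss.enumerate_partitions({1, 2, 3, 4, 5, 6})) == 10

    def test_groups_disjoint_and_cover(self):
        for p in ss.enumerate_partitions({1, 2, 3, 4, 5, 6}):
            assert set(p.group_a) | set(p.group_b) == {1, 2, 3, 4, 5, 6}
            assert not set(p.group_a) & set(p.group_b)
            assert min(p.group_a) == 1  # canonical form

    def test_matches_brute_force_dedup(self):
        got = {
            frozenset((frozenset(p.group_a), frozenset(p.group_b)))
            for p in ss.enumerate_partitions({1, 2, 3, 4, 5, 6})
        }
        assert got == brute_force_splits(range(1, 7), 3)

    def test_arbitrary_replicate_labels(self):
        parts = ss.enumerate_partitions({3, 7, 10, 11, 20, 21})
        assert len(parts) == 10

    @pytest.mark.parametrize("n", [4, 5, 7])
    def test_wrong_replicate_count_rejected(self, n):
        with pytest.raises(ValueError):
            ss.enumerate_partitions(set(range(n)))

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_generalised_split_count_is_half_central_binomial(self, k):
        from math import comb
        splits = ss.nonredundant_splits(list(range(2 * k)), k)
        assert len(splits) == comb(2 * k, k) // 2
        got = {frozenset((frozenset(a), frozenset(b))) for a, b in splits}
        assert got == brute_force_splits(range(2 * k), k)


def bh_oracle(p):
    """Independent step-up computation: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert ss.bh_adjust([0.37]) == pytest.approx([0.37])

    def test_hand_step_up_example(self):
        # ranks 1..4: 4*0.01/1, 4*0.02/2, 4*0.03/3, 4*0.04/4 -> all 0.04
        np.testing.assert_allclose(
            ss.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(ss.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.bh_adjust([0.5, 1.2])

    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=100)
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_independent_oracle(self, p):
        np.testing.assert_allclose(ss.bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, p):
        q = ss.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def six_rep_state():
    rng = np.random.default_rng(11)
    counts = {
        f"P{i:03d}": list(rng.poisson(rng.uniform(5, 40), size=6)) for i in range(60)
    }
    counts = {k: v for k, v in counts.items() if all(c > 0 for c in v)}
    return matrix_from_counts("ctl", counts)


class TestPqfdrCurve:
    def test_zero_at_q_zero_and_full_at_q_one(self, six_rep_state):
        part = ss.enumerate_partitions(six_rep_state.replicate_numbers)[0]
        curve = ss.pqfdr_for_partition(six_rep_state, part)
        assert curve.pqfdr[0] == 0.0
        assert curve.pqfdr[-1] == pytest.approx(100.0)

    def test_non_decreasing_and_bounded_for_every_partition(self, six_rep_state):
        for part in ss.enumerate_partitions(six_rep_state.replicate_numbers):
            curve = ss.pqfdr_for_partition(six_rep_state, part)
            assert (np.diff(curve.pqfdr) >= 0).all()
            assert ((curve.pqfdr >= 0) & (curve.pqfdr <= 100)).all()

    def test_empty_high_stringency_set_rejected(self):
        m = matrix_from_counts("s", {f"P{i}": [1, 0, 1, 0, 1, 0] for i in range(4)})
        part = ss.enumerate_partitions(m.replicate_numbers)[0]
        with pytest.raises(ValueError, match="high-stringency"):
            ss.pqfdr_for_partition(m, part)

    def test_relabelling_replicates_leaves_state_average_unchanged(self, six_rep_state):
        avg, _ = ss.samesame_state_curve(six_rep_state)
        relabelled = six_rep_state.counts.copy()
        relabelled.columns = [4, 6, 1, 3, 2, 5]
        m2 = matrix_from_counts(
            "ctl",
            {
                ident: [int(relabelled.loc[ident, r]) for r in sorted(relabelled.columns)]
                for ident in relabelled.index
            },
        )
        avg2, _ = ss.samesame_state_curve(m2)
        np.testing.assert_allclose(avg.pqfdr, avg2.pqfdr, atol=1e-9)


class TestAverageCurves:
    def grid(self):
        return ss.default_q_grid()

    def test_average_of_identical_curves_is_the_curve(self):
        c = ss.PQFDRCurve(self.grid(), np.linspace(0, 100, 101), 10, "a")
        avg = ss.average_curves([c, c, c])
        np.testing.assert_allclose(avg.pqfdr, c.pqfdr)

    def test_average_of_constants(self):
        c0 = ss.PQFDRCurve(self.grid(), np.zeros(101), 10, "a")
        c2 = ss.PQFDRCurve(self.grid(), np.full(101, 2.0), 10, "b")
        np.testing.assert_allclose(ss.average_curves([c0, c2]).pqfdr, np.ones(101))

    def test_grid_mismatch_rejected(self):
        c0 = ss.PQFDRCurve(self.grid(), np.zeros(101), 10, "a")
        c1 = ss.PQFDRCurve(np.linspace(0, 1, 51), np.zeros(51), 10, "b")
        with pytest.raises(ValueError, match="grid"):
            ss.average_curves([c0, c1])


class TestDeriveThreshold:
    def test_identically_zero_curve_gives_q_one(self):
        c = ss.PQFDRCurve(ss.default_q_grid(), np.zeros(101), 10, "z")
        assert ss.derive_threshold(c, 1.0).q_star == 1.0

    def test_linear_curve_closed_form(self):
        g = ss.default_q_grid()
        c = ss.PQFDRCurve(g, 100.0 * g, 10, "lin")
        assert ss.derive_threshold(c, 1.0).q_star == pytest.approx(0.01)

    def test_sub_grid_interpolation(self):
        g = ss.default_q_grid()
        # flat 0 until q=0.27 (pqfdr 0.8), then 1.2 at 0.28: crosses 1% inside the cell
        f = np.zeros(101)
        f[27:] = 0.8
        f[28:] = 1.2
        f[29:] = 5.0
        q = ss.derive_threshold(ss.PQFDRCurve(g, f, 10, "x"), 1.0).q_star
        assert 0.27 < q < 0.28
        assert q == pytest.approx(0.27 + 0.01 * (1.0 - 0.8) / (1.2 - 0.8))

    def test_no_permissive_threshold_gives_zero(self):
        g = ss.default_q_grid()
        f = np.concatenate([[0.0], np.full(100, 50.0)])
        assert ss.derive_threshold(ss.PQFDRCurve(g, f, 10, "x"), 1.0).q_star == 0.0

    def test_threshold_respects_target_on_monotone_curves(self, six_rep_state):
        avg, _ = ss.samesame_state_curve(six_rep_state)
        thr = ss.derive_threshold(avg, 1.0)
        achieved = np.interp(thr.q_star, avg.q_grid, avg.pqfdr)
        assert achieved <= 1.0 + 1e-9
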