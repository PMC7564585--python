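import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spcquant import comparison as cmp
from spcquant.stat_tests import ttest_rows, ttest_shared
from spcquant.stringency import StringencyPartition, build_stringency_partition

from conftest import matrix_from_counts


def part(high_c, all_c, high_t, all_t):
    return StringencyPartition(
        high={"c": set(high_c), "t": set(high_t)},
        all_proteins={"c": set(all_c), "t": set(all_t)},
        min_summed_count=5,
    )


class TestSharedAndUnique:
    def test_plain_set_algebra_when_all_equals_high(self):
        p = part({"A", "B"}, {"A", "B"}, {"B", "C"}, {"B", "C"})
        shared, uc, ut = cmp.shared_and_unique(p, "c", "t")
        assert (shared, uc, ut) == ({"B"}, {"A"}, {"C"})

    def test_low_stringency_presence_makes_shared_not_unique(self):
        # A qualifies in control and is seen (low stringency) in treatment
        p = part({"A"}, {"A"}, set(), {"A"})
        shared, uc, ut = cmp.shared_and_unique(p, "c", "t")
        assert shared == {"A"} and uc == set() and ut == set()

    def test_identical_states_have_no_uniques(self):
        p = part({"A", "B"}, {"A", "B"}, {"A", "B"}, {"A", "B"})
        shared, uc, ut = cmp.shared_and_unique(p, "c", "t")
        assert shared == {"A", "B"} and not uc and not ut

    def test_missing_state_raises(self):
        p = part({"A"}, {"A"}, {"A"}, {"A"})
        with pytest.raises(KeyError):
            cmp.shared_and_unique(p, "c", "nope")


class TestTtest:
    def test_identical_vectors_give_p_one(self):
        assert ttest_shared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self):
        a = [0.0, 0.001, -0.001]
        b = [10.0, 10.001, 9.999]
        assert ttest_shared(a, b) < 1e-8

    def test_matches_hand_pooled_variance_computation(self):
        # means 1.0 vs 1.2, each sample variance 0.01, pooled s^2 = 0.01,
        # t = -0.2 / sqrt(0.01 * (1/3 + 1/3)), df = 4
        a, b = [1.0, 1.1, 0.9], [1.2, 1.3, 1.1]
        t_hand = -0.2 / np.sqrt(0.01 * (2.0 / 3.0))
        p_hand = 2.0 * stats.t.sf(abs(t_hand), df=4)
        assert ttest_shared(a, b) == pytest.approx(p_hand, rel=1e-10)

    def test_zero_variance_unequal_means_is_p_zero(self):
        assert ttest_shared([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]) == 0.0

    def test_zero_variance_equal_means_is_p_one(self):
        assert ttest_shared([1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            ttest_shared([1.0], [1.0, 2.0])

    def test_rowwise_matches_scalar(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(12, 3)), rng.normal(size=(12, 4))
        rows = ttest_rows(a, b)
        for i in range(12):
            assert rows[i] == pytest.approx(ttest_shared(a[i], b[i]))


@pytest.fixture()
def two_state_matrices():
    # three large stable proteins keep the NSAF denominators comparable
    # between states, so FLAT is not dragged by compositional shifts
    bulk = {"BLK1": [100, 98, 102], "BLK2": [150, 149, 151], "BLK3": [120, 122, 118]}
    counts_c = {
        "UPP": [5, 6, 5], "DWN": [40, 38, 42], "FLAT": [10, 11, 9],
        "UC": [8, 9, 7], "LOWT": [6, 7, 6], **bulk,
    }
    counts_t = {
        "UPP": [25, 28, 26], "DWN": [8, 7, 9], "FLAT": [10, 10, 11],
        "LOWT": [0, 2, 0], "UT": [12, 14, 13], **bulk,
    }
    mw = {k: 50.0 for k in set(counts_c) | set(counts_t)}
    mc = matrix_from_counts("c", counts_c, mw)
    mt = matrix_from_counts("t", counts_t, mw)
    return mc, mt, build_stringency_partition([mc, mt], 5)


class TestCompareAndClassify:
    def test_high_stringency_stream_layout(self, two_state_matrices):
        mc, mt, p = two_state_matrices
        table = cmp.classify(cmp.compare_states(mc, mt, p, cmp.Stream.HIGH_STRINGENCY))
        by_id = table.set_index("identifier")
        assert by_id.loc["UC", "category"] == "unique_control"
        assert by_id.loc["UT", "category"] == "unique_treatment"
        assert by_id.loc["UPP", "category"] == "upregulated"
        assert by_id.loc["DWN", "category"] == "downregulated"
        assert by_id.loc["FLAT", "category"] == "unchanged"
        # LOWT qualifies in control, observed at low stringency in treatment: tested
        assert np.isfinite(by_id.loc["LOWT", "p_value"])

    def test_categories_partition_stream_inventory(self, two_state_matrices):
        mc, mt, p = two_state_matrices
        table = cmp.classify(cmp.compare_states(mc, mt, p, cmp.Stream.HIGH_STRINGENCY))
        assert table["category"].notna().all()
        shared, uc, ut = cmp.shared_and_unique(p, "c", "t")
        assert len(table) == len(shared) + len(uc) + len(ut)

    def test_all_proteins_stream_tests_union_without_uniques(self, two_state_matrices):
        mc, mt, p = two_state_matrices
        table = cmp.classify(cmp.compare_states(mc, mt, p, cmp.Stream.ALL_PROTEINS))
        assert len(table) == len(p.all_proteins["c"] | p.all_proteins["t"])
        assert not table["category"].str.startswith("unique").any()
        assert table["p_value"].notna().all()

    def test_label_swap_antisymmetry(self, two_state_matrices):
        mc, mt, p = two_state_matrices
        fwd = cmp.classify(
            cmp.compare_states(mc, mt, p, cmp.Stream.HIGH_STRINGENCY)
        ).set_index("identifier")
        swapped_part = StringencyPartition(
            high={"c": p.high["t"], "t": p.high["c"]},
            all_proteins={"c": p.all_proteins["t"], "t": p.all_proteins["c"]},
            min_summed_count=p.min_summed_count,
        )
        mt2, mc2 = mt, mc
        rev = cmp.classify(
            cmp.compare_states(mt2, mc2, p, cmp.Stream.HIGH_STRINGENCY)
        ).set_index("identifier")
        tested = fwd.index[fwd["p_value"].notna()]
        np.testing.assert_allclose(
            rev.loc[tested, "log2_fold_change"], -fwd.loc[tested, "log2_fold_change"]
        )
        np.testing.assert_allclose(rev.loc[tested, "p_value"], fwd.loc[tested, "p_value"])
        mapping = {"upregulated": "downregulated", "downregulated": "upregulated",
                   "unchanged": "unchanged"}
        for ident in tested:
            assert rev.loc[ident, "category"] == mapping[fwd.loc[ident, "category"]]
        assert rev.loc["UC", "category"] == "unique_treatment"

    @pytest.mark.parametrize(
        "p_val, fc, alpha, expected",
        [(0.01, 1.0, 0.05, "upregulated"),
         (0.20, 3.0, 0.05, "unchanged"),
         (0.01, -0.5, 0.05, "downregulated"),
         (0.049, 0.2, 0.05, "upregulated")],
    )
    def test_classify_examples(self, p_val, fc, alpha, expected):
        table = pd.DataFrame(
            {"identifier": ["X"], "log2_fold_change": [fc], "p_value": [p_val],
             "q_value": [p_val], "category": [pd.NA]}
        )
        assert cmp.classify(table, alpha).loc[0, "category"] == expected

    def test_classify_with_bh_threshold(self):
        table = pd.DataFrame(
            {"identifier": ["X", "Y"], "log2_fold_change": [1.0, 1.0],
             "p_value": [0.04, 0.04], "q_value": [0.2, 0.35], "category": [pd.NA] * 2}
        )
        out = cmp.classify(table, use_bh=True, bh_q=0.274)
        assert list(out["category"]) == ["upregulated", "unchanged"]

    def test_null_data_false_positive_rate_near_alpha(self):
        # both states i.i.d. -> about 5% of shared proteins at p < 0.05
        rng = np.random.default_rng(42)
        n = 4000
        a = rng.normal(size=(n, 3))
        b = rng.normal(size=(n, 3))
        frac = (ttest_rows(a, b) < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n))
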