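"""Consensus rank aggregation: hand examples, brute-force oracle, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reprank import (
    RankedDrugList,
    aggregate_across_datasets,
    aggregate_within_dataset,
    rank_pathways,
    retain_threshold,
    truncate_top_k,
)
from conftest import make_list


def padded_lists(rankings, k=50):
    """Build K-item tool lists whose top entries are the given rankings."""
    lists = []
    for ti, items in enumerate(rankings):
        fillers = [f"pad{ti}_{i}" for i in range(k - len(items))]
        lists.append(make_list(items + fillers, tool_id=f"t{ti}"))
    return lists


class TestWithinDataset:
    def test_perfect_consensus_scores_one(self):
        lists = padded_lists([["winner"], ["winner"], ["winner"]])
        table = aggregate_within_dataset(lists)
        top = table.iloc[0]
        assert top["item_id"] == "winner"
        assert top["R"] == pytest.approx(1.0)
        assert top["A"] == pytest.approx(1.0)
        assert top["score"] == pytest.approx(1.0)

    def test_hand_computed_ranks_1_2_3(self):
        # ranks 1, 2, 3 in three K=50 lists: R=(1.00+0.98+0.96)/3=0.98, score=0.986
        lists = padded_lists([["x"], ["a", "x"], ["a", "b", "x"]])
        table = aggregate_within_dataset(lists).set_index("item_id")
        assert table.loc["x", "R"] == pytest.approx(0.98)
        assert table.loc["x", "score"] == pytest.approx(0.7 * 0.98 + 0.3 * 1.0)

    def test_hand_computed_rank_50_in_one_of_three(self):
        items = [f"mid{i}" for i in range(49)] + ["tail"]
        lists = padded_lists([items, [], []])
        table = aggregate_within_dataset(lists).set_index("item_id")
        assert table.loc["tail", "R"] == pytest.approx(0.02)
        assert table.loc["tail", "A"] == pytest.approx(1 / 3)
        assert table.loc["tail", "score"] == pytest.approx(0.7 * 0.02 + 0.3 / 3)

    def test_score_identity_holds_to_1e12(self):
        lists = padded_lists([["a", "b"], ["b", "c"], ["c", "a"]], k=10)
        table = aggregate_within_dataset(lists)
        np.testing.assert_allclose(table["score"], 0.7 * table["R"] + 0.3 * table["A"], atol=1e-12)
        assert ((table["score"] >= 0) & (table["score"] <= 1)).all()

    def test_duplicate_item_in_one_list_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedDrugList(entries=[("a", -2.0), ("a", -1.0)])

    def test_mismatched_datasets_rejected(self):
        lists = [make_list(["a"], dataset_id="DS1"), make_list(["a"], dataset_id="DS2")]
        with pytest.raises(ValueError, match="share"):
            aggregate_within_dataset(lists)


class TestAcrossDatasets:
    def test_single_dataset_preserves_order_and_top_score(self):
        within = aggregate_within_dataset(padded_lists([["a", "b"], ["a", "c"]], k=10))
        cross = aggregate_across_datasets([within], stage="MM")
        assert list(cross["item_id"]) == list(within["item_id"])
        assert cross.iloc[0]["score"] == pytest.approx(1.0)

    def test_top_in_two_of_four_datasets(self):
        # top rank in 2 of 4 datasets, each list M=100: R=1, A=0.5, score=0.85
        def consensus_table(top_item):
            items = [top_item] + [f"f{i}" for i in range(99)]
            scores = np.linspace(1.0, 0.01, 100)
            return pd.DataFrame({"item_id": items, "score": scores})

        present = [consensus_table("hit"), consensus_table("hit")]
        absent = [consensus_table("other1"), consensus_table("other2")]
        cross = aggregate_across_datasets(present + absent, stage="MM").set_index("item_id")
        assert cross.loc["hit", "R"] == pytest.approx(1.0)
        assert cross.loc["hit", "A"] == pytest.approx(0.5)
        assert cross.loc["hit", "score"] == pytest.approx(0.85)

    def test_absent_items_do_not_appear(self):
        within = aggregate_within_dataset(padded_lists([["a"]], k=5))
        cross = aggregate_across_datasets([within], stage="MM")
        assert "zzz" not in set(cross["item_id"])


class TestTruncateAndRetain:
    def test_truncation_to_50(self):
        ranked = make_list([f"d{i}" for i in range(120)])
        assert len(truncate_top_k(ranked)) == 50

    def test_short_list_unchanged(self):
        ranked = make_list([f"d{i}" for i in range(30)])
        assert len(truncate_top_k(ranked)) == 30

    def test_k_zero_empties(self):
        assert len(truncate_top_k(make_list(["a", "b"]), k=0)) == 0

    def test_retention_boundary_inclusive(self):
        scores = pd.DataFrame(
            {"item_id": ["a", "b", "c"], "score": [0.75, 0.7499, 0.9], "stage": ["MM"] * 3}
        )
        shortlist = retain_threshold(scores)
        assert shortlist.item_ids == ["c", "a"]

    def test_empty_survivors_allowed(self):
        scores = pd.DataFrame({"item_id": ["a"], "score": [0.1], "stage": ["MM"]})
        assert len(retain_threshold(scores)) == 0


class TestRankPathways:
    def test_pathway_top_everywhere_scores_one(self):
        tables = [
            pd.DataFrame({"term_id": ["P1", "P2", "P3"], "adj_p": [0.001, 0.01, 0.5]})
            for _ in range(3)
        ]
        out = rank_pathways(tables, stage="MGUS")
        assert out.iloc[0]["item_id"] == "P1"
        assert out.iloc[0]["score"] == pytest.approx(1.0)

    def test_tied_adj_p_share_average_rank(self):
        table = pd.DataFrame({"term_id": ["P1", "P2", "P3"], "adj_p": [0.01, 0.01, 0.5]})
        out = rank_pathways([table], stage="MM").set_index("item_id")
        # P1 and P2 share rank 1.5 of 3: value (3 - 1.5 + 1)/3
        assert out.loc["P1", "R"] == pytest.approx((3 - 1.5 + 1) / 3)
        assert out.loc["P1", "R"] == out.loc["P2", "R"]

    def test_missing_adj_p_rejected(self):
        with pytest.raises(ValueError, match="adj_p"):
            rank_pathways([pd.DataFrame({"term_id": ["P"], "p": [0.1]})])

    def test_shared_planted_pathway_scores_near_one(self):
        """A pathway significant in all datasets lands in the ~0.99 bracket."""
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(3):
            terms = ["SHARED"] + [f"T{i}" for i in range(60)]
            adj = np.concatenate([[1e-8], np.sort(rng.uniform(1e-4, 1.0, 60))])
            tables.append(pd.DataFrame({"term_id": terms, "adj_p": adj}))
        out = rank_pathways(tables, stage="sMM").set_index("item_id")
        assert out.loc["SHARED", "score"] >= 0.99


# -- independent brute-force oracle -------------------------------------------

def naive_rank(scores, value):
    """Fractional competition rank of `value` among `scores` (1 = smallest)."""
    below = sum(1 for s in scores if s < value)
    equal = sum(1 for s in scores if s == value)
    return below + (1 + equal) / 2


def naive_within(lists, w1=0.7, w2=0.3):
    union = sorted({item for ranked in lists for item, _ in ranked.entries})
    out = {}
    for item in union:
        values, appearances = [], 0
        for ranked in lists:
            entries = dict(ranked.entries)
            if item in entries:
                appearances += 1
                all_scores = [s for _, s in ranked.entries]
                r = naive_rank(all_scores, entries[item])
                k = len(ranked.entries)
                values.append((k - r + 1) / k)
        r_mean = sum(values) / len(values)
        a = appearances / len(lists)
        out[item] = (r_mean, a, w1 * r_mean + w2 * a)
    return out


def naive_cross(tables, w1=0.7, w2=0.3):
    union = sorted({item for t in tables for item in t["item_id"]})
    out = {}
    for item in union:
        values, appearances = [], 0
        for table in tables:
            ids = list(table["item_id"])
            if item in ids:
                appearances += 1
                scores = list(table["score"])
                score = scores[ids.index(item)]
                r = naive_rank([-s for s in scores], -score)
                m = len(ids)
                values.append((m - r + 1) / m)
        r_mean = sum(values) / len(values)
        a = appearances / len(tables)
        out[item] = (r_mean, a, w1 * r_mean + w2 * a)
    return out


@pytest.mark.parametrize("n_items", [2, 4, 6])
@pytest.mark.parametrize("n_tools", [1, 2, 3])
@pytest.mark.parametrize("n_datasets", [1, 2, 3])
def test_matches_exhaustive_naive_recomputation(n_items, n_tools, n_datasets):
    """Implementation vs. unvectorised loop-level recomputation, to 1e-12."""
    rng = np.random.default_rng(n_items * 100 + n_tools * 10 + n_datasets)
    items = [f"it{i}" for i in range(n_items)]
    per_dataset_lists, per_dataset_tables = [], []
    for d in range(n_datasets):
        lists = []
        for t in range(n_tools):
            chosen = list(rng.permutation(items)[: rng.integers(1, n_items + 1)])
            scores = np.round(-rng.random(len(chosen)) * 100, 1)  # rounding forces ties
            entries = sorted(zip(chosen, scores), key=lambda kv: (kv[1], kv[0]))
            lists.append(RankedDrugList(entries=entries, tool_id=f"t{t}", dataset_id=f"D{d}"))
        per_dataset_lists.append(lists)
        table = aggregate_within_dataset(lists)
        per_dataset_tables.append(table)
        oracle = naive_within(lists)
        for _, row in table.iterrows():
            r, a, s = oracle[row["item_id"]]
            assert row["R"] == pytest.approx(r, abs=1e-12)
            assert row["A"] == pytest.approx(a, abs=1e-12)
            assert row["score"] == pytest.approx(s, abs=1e-12)

    cross = aggregate_across_datasets(per_dataset_tables, stage="MM")
    oracle = naive_cross(per_dataset_tables)
    for _, row in cross.iterrows():
        r, a, s = oracle[row["item_id"]]
        assert row["R"] == pytest.approx(r, abs=1e-12)
        assert row["A"] == pytest.approx(a, abs=1e-12)
        assert row["score"] == pytest.approx(s, abs=1e-12)


# -- hypothesis property tests -------------------------------------------------

@st.composite
def tool_lists(draw):
    n_items = draw(st.integers(3, 8))
    items = [f"d{i}" for i in range(n_items)]
    n_tools = draw(st.integers(2, 4))
    lists = []
    for t in range(n_tools):
        size = draw(st.integers(1, n_items))
        perm = draw(st.permutations(items))
        lists.append(make_list(list(perm)[:size], tool_id=f"t{t}"))
    return lists


@settings(derandomize=True, max_examples=30, deadline=None)
@given(tool_lists(), st.randoms(use_true_random=False))
def test_permutation_invariance_of_tool_order(lists, rnd):
    base = aggregate_within_dataset(lists)
    shuffled = list(lists)
    rnd.shuffle(shuffled)
    permuted = aggregate_within_dataset(shuffled)
    pd.testing.assert_frame_equal(base, permuted)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(tool_lists())
def test_scores_bounded_and_identity(lists):
    table = aggregate_within_dataset(lists)
    assert ((table["score"] >= -1e-12) & (table["score"] <= 1 + 1e-12)).all()
    np.testing.assert_allclose(table["score"], 0.7 * table["R"] + 0.3 * table["A"], atol=1e-12)


def test_improving_a_rank_never_lowers_the_score():
    """Moving an item up within one tool list cannot decrease its score."""
    items = [f"d{i}" for i in range(6)]
    base_lists = [make_list(items, tool_id="t0"), make_list(items[::-1], tool_id="t1")]
    target = "d4"
    base_score = (
        aggregate_within_dataset(base_lists).set_index("item_id").loc[target, "score"]
    )
    improved_order = [target] + [i for i in items if i != target]
    improved_lists = [make_list(improved_order, tool_id="t0"), make_list(items[::-1], tool_id="t1")]
    new_score = (
        aggregate_within_dataset(improved_lists).set_index("item_id").loc[target, "score"]
    )
    assert new_score >= base_score


def test_adding_an_appearance_never_lowers_a():
    lists2 = [make_list(["a", "b"], tool_id="t0"), make_list(["b"], tool_id="t1")]
    lists3 = lists2 + [make_list(["a", "b"], tool_id="t2")]
    a2 = aggregate_within_dataset(lists2).set_index("item_id").loc["a", "A"]
    a3 = aggregate_within_dataset(lists3).set_index("item_id").loc["a", "A"]
    assert a3 >= a2
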