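from itertools import product

import numpy as np
import pandas as pd
import pytest

from triohet import build_mid_parent, classify_all, classify_trio, common_degs
from triohet.patterns import (
    CATEGORIES,
    CATEGORY_ADDITIVITY,
    CATEGORY_DOMINANCE,
    CATEGORY_NONE,
    CATEGORY_TRANS_DOWN,
    CATEGORY_TRANS_UP,
    PATTERN_AMBIGUOUS,
    PATTERN_NULL,
    PATTERN_NUMERALS,
    PATTERN_TABLE,
)
from .conftest import ROLES

ALL_TRIPLES = list(product((-1, 0, 1), repeat=3))


class TestDecisionTable:
    def test_partition_of_27_triples(self):
        """12 patterns + 1 null + 14 ambiguous, total and exclusive."""
        results = {t: classify_trio(*t) for t in ALL_TRIPLES}
        patterns = [pat for pat, _ in results.values()]
        assert len(results) == 27
        assert sum(p in PATTERN_NUMERALS for p in patterns) == 12
        assert sum(p == PATTERN_NULL for p in patterns) == 1
        assert sum(p == PATTERN_AMBIGUOUS for p in patterns) == 14
        # each numeral used exactly once
        assert sorted(p for p in patterns if p in PATTERN_NUMERALS) == sorted(
            PATTERN_NUMERALS
        )

    def test_category_groupings(self):
        by_cat = {}
        for pat, cat in PATTERN_TABLE.values():
            by_cat.setdefault(cat, set()).add(pat)
        assert by_cat[CATEGORY_ADDITIVITY] == {"I", "XII"}
        assert by_cat[CATEGORY_DOMINANCE] == {"II", "XI", "IV", "IX"}
        assert by_cat[CATEGORY_TRANS_DOWN] == {"III", "VII", "X"}
        assert by_cat[CATEGORY_TRANS_UP] == {"V", "VI", "VIII"}

    @pytest.mark.parametrize(
        "triple,expected_cat,expected_pats",
        [
            ((-1, 1, -1), CATEGORY_ADDITIVITY, {"I", "XII"}),
            ((1, -1, 1), CATEGORY_ADDITIVITY, {"I", "XII"}),
            ((0, 1, 1), CATEGORY_TRANS_UP, {"V", "VI", "VIII"}),
            ((1, 0, 1), CATEGORY_DOMINANCE, {"II", "XI", "IV", "IX"}),
            ((0, -1, -1), CATEGORY_TRANS_DOWN, {"III", "VII", "X"}),
        ],
    )
    def test_known_configurations(self, triple, expected_cat, expected_pats):
        pat, cat = classify_trio(*triple)
        assert cat == expected_cat
        assert pat in expected_pats

    def test_inconsistent_triple_ambiguous(self):
        # hybrid above one parent but parents flat and other comparison flat
        assert classify_trio(0, 1, 0) == (PATTERN_AMBIGUOUS, CATEGORY_NONE)
        assert classify_trio(0, 0, 0) == (PATTERN_NULL, CATEGORY_NONE)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            classify_trio(2, 0, 0)

    def test_parent_swap_mirror_symmetry(self):
        """Swapping parents maps every triple to one with the same category."""
        for t in ALL_TRIPLES:
            _, cat = classify_trio(*t)
            _, cat_sw = classify_trio(-t[0], t[2], t[1])
            assert cat_sw == cat


class TestMidParent:
    def test_pooling_rule(self):
        mid, n_mid = build_mid_parent(np.array([10]), np.array([20]), 1e6, 1e6)
        assert mid[0] == 30 and n_mid == 2e6
        # rate per parental library-equivalent: 30 / 2 = 15
        assert mid[0] / (n_mid / 1e6) == pytest.approx(15.0)

    def test_one_parent_all_zero(self):
        mid, n_mid = build_mid_parent(np.zeros(3, int), np.array([1, 2, 3]), 5e5, 1e6)
        np.testing.assert_array_equal(mid, [1, 2, 3])
        assert n_mid == 1.5e6

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            build_mid_parent(np.zeros(3), np.zeros(4), 1.0, 1.0)


class TestClassifyAll:
    def test_recovers_planted_categories(self, small_classification):
        cls, truth = small_classification
        a = cls.assignments
        up = truth["category"] == "transgressive_up"
        down = truth["category"] == "transgressive_down"
        dom = truth["category"].isin(["dominance_maternal", "dominance_paternal"])
        assert (a.loc[up.values, "category"] == CATEGORY_TRANS_UP).mean() > 0.85
        assert (a.loc[down.values, "category"] == CATEGORY_TRANS_DOWN).mean() > 0.85
        assert (a.loc[dom.values, "category"] == CATEGORY_DOMINANCE).mean() > 0.7

    def test_category_counts_sum(self, small_classification):
        cls, _ = small_classification
        a = cls.assignments
        n_categorized = (~a["category"].isin([CATEGORY_NONE])).sum()
        assert sum(cls.summary["category_counts"].values()) == n_categorized

    def test_summary_structure(self, small_classification):
        cls, _ = small_classification
        assert set(cls.summary["pattern_counts"]) == set(PATTERN_NUMERALS)
        assert set(cls.summary["category_counts"]) == set(CATEGORIES)

    def test_parent_swap_preserves_categories(self, small_trio):
        cm, _ = small_trio
        cls = classify_all(cm, ROLES)
        swapped = classify_all(
            cm,
            {"maternal": "paternal", "hybrid": "hybrid", "paternal": "maternal"},
        )
        pd.testing.assert_series_equal(
            cls.assignments["category"], swapped.assignments["category"]
        )
        np.testing.assert_array_equal(
            cls.assignments["s_pp"].to_numpy(), -swapped.assignments["s_pp"].to_numpy()
        )

    def test_missing_role_errors(self, small_trio):
        cm, _ = small_trio
        with pytest.raises(ValueError, match="role"):
            classify_all(cm, {"maternal": "maternal", "hybrid": "hybrid"})


class TestCommonDEGs:
    def test_identity_intersection(self, small_classification):
        cls, _ = small_classification
        a = cls.assignments
        common = common_degs(a, a)
        for cat in CATEGORIES:
            assert common[cat]["count"] == int((a["category"] == cat).sum())

    def test_shared_planted_genes_dominate(self, small_trio):
        cm, truth = small_trio
        cls_a = classify_all(cm, ROLES)
        # second "hybrid" identical trio: same planted genes by construction
        cls_b = classify_all(cm, ROLES)
        common = common_degs(cls_a.assignments, cls_b.assignments)
        planted_up = set(truth.index[truth["category"] == "transgressive_up"])
        found = set(common[CATEGORY_TRANS_UP]["genes"])
        assert len(found & planted_up) / max(len(found), 1) > 0.8

    def test_disjoint_universes_warn(self, small_classification):
        cls, _ = small_classification
        a = cls.assignments
        b = a.copy()
        b.index = pd.Index([f"other_{g}" for g in b.index], name="gene_id")
        with pytest.warns(UserWarning, match="no genes"):
            common = common_degs(a, b)
        assert all(common[cat]["count"] == 0 for cat in CATEGORIES)
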