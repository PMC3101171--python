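import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfcluster import (
    AssociationParams,
    ExpressionMatrix,
    TFSet,
    all_neighborhoods,
    association,
    compare_methods,
    rank_with_ties,
    spearman_rho,
    top_coexpressed,
)

finite_vectors = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=30,
)


class TestRankWithTies:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((10, 20, 30), (1, 2, 3)),
            ((5, 5, 9), (1.5, 1.5, 3)),
            ((7, 7, 7, 7), (2.5, 2.5, 2.5, 2.5)),
        ],
    )
    def test_average_rank_examples(self, v, expected):
        np.testing.assert_array_equal(rank_with_ties(v), expected)

    @settings(derandomize=True, max_examples=50)
    @given(finite_vectors)
    def test_rank_sum_is_conserved(self, v):
        m = len(v)
        assert rank_with_ties(v).sum() == pytest.approx(m * (m + 1) / 2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rank_with_ties([1.0, np.nan, 2.0])


class TestSpearmanRho:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4, 5), (1, 2, 3, 4, 5), 1.0),
            ((1, 2, 3, 4, 5), (5, 4, 3, 2, 1), -1.0),
            # closed form 1 - 6*4/(5*24) with d = (-1, 1, -1, 1, 0)
            ((1, 2, 3, 4, 5), (2, 1, 4, 3, 5), 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_tied_input_matches_rank_correlation_oracle(self):
        # ranks computed by hand: x=(1,2,2,4) -> (1,2.5,2.5,4); y=(3,1,4,4) -> (2,1,3.5,3.5)
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([2, 1, 3.5, 3.5])
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert spearman_rho((1, 2, 2, 4), (3, 1, 4, 4)) == pytest.approx(oracle)

    def test_all_permutations_match_tie_free_closed_form(self):
        x = np.arange(1, 6)
        for perm in itertools.permutations(range(1, 6)):
            d2 = sum((a - b) ** 2 for a, b in zip(x, perm))
            closed = 1 - 6 * d2 / (5 * (25 - 1))
            assert spearman_rho(x, perm) == pytest.approx(closed)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_monotone_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho = spearman_rho(x, y)
        assert spearman_rho(y, x) == pytest.approx(rho)
        # strictly monotone transforms leave ranks, hence rho, unchanged
        assert spearman_rho(np.exp(x), y**3 + 2 * y) == pytest.approx(rho)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho((1, 1, 1), (1, 2, 3))


class TestAssociation:
    def test_pearson_identity(self):
        assert association((1, 2, 3, 4), (1, 2, 3, 4), "pearson") == pytest.approx(1.0)

    def test_regression_collinear_p_zero(self):
        p = association((1, 2, 3, 4), (2, 4, 6, 8), "regression")
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_regression_matches_t_statistic_oracle(self):
        from scipy import stats

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.2, 1.9, 3.4, 3.6, 5.5, 5.8])
        r = float(np.corrcoef(x, y)[0, 1])
        t = r * np.sqrt((6 - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), df=4)
        assert association(x, y, "regression") == pytest.approx(expected, rel=1e-12)


class TestTopCoexpressed:
    def test_positive_direction_with_lexicographic_tie(self, toy_expr):
        # g3 and g4 tie at rho = 0.8; g3 wins lexicographically
        nb = top_coexpressed("t", toy_expr, AssociationParams(omega=2))
        assert nb.members == ("g1", "g3")
        assert nb.scores == pytest.approx((1.0, 0.8))

    def test_absolute_direction_picks_reversal(self, toy_expr):
        nb = top_coexpressed(
            "t", toy_expr, AssociationParams(omega=2, direction="absolute")
        )
        assert nb.members == ("g1", "g2")

    def test_omega_equals_universe_minus_one(self, toy_expr):
        nb = top_coexpressed("t", toy_expr, AssociationParams(omega=4))
        assert set(nb.members) == {"g1", "g2", "g3", "g4"}
        assert "t" not in nb.members

    def test_omega_too_large_rejected(self, toy_expr):
        with pytest.raises(ValueError, match="omega"):
            top_coexpressed("t", toy_expr, AssociationParams(omega=5))

    def test_members_dominate_non_members(self):
        # brute force: every member's rho >= every non-member's rho
        rng = np.random.default_rng(7)
        expr = ExpressionMatrix(
            tuple(f"g{k}" for k in range(12)),
            tuple(f"s{j}" for j in range(9)),
            rng.normal(size=(12, 9)),
        )
        nb = top_coexpressed("g0", expr, AssociationParams(omega=4))
        others = set(expr.gene_ids) - set(nb.members) - {"g0"}
        worst_member = min(
            association(expr.profile("g0"), expr.profile(g)) for g in nb.members
        )
        best_other = max(
            association(expr.profile("g0"), expr.profile(g)) for g in others
        )
        assert worst_member >= best_other

    def test_gene_row_order_irrelevant(self, toy_expr):
        perm = [3, 0, 4, 1, 2]
        shuffled = ExpressionMatrix(
            tuple(toy_expr.gene_ids[i] for i in perm),
            toy_expr.sample_ids,
            toy_expr.values[perm],
        )
        a = top_coexpressed("t", toy_expr, AssociationParams(omega=2))
        b = top_coexpressed("t", shuffled, AssociationParams(omega=2))
        assert a.members == b.members and a.scores == pytest.approx(b.scores)


def _random_expr(rng, q=30, m=20):
    return ExpressionMatrix(
        tuple(f"g{k}" for k in range(q)),
        tuple(f"s{j}" for j in range(m)),
        rng.normal(size=(q, m)),
    )


class TestAllNeighborhoods:
    def test_tf_list_order_and_count(self):
        expr = _random_expr(np.random.default_rng(0))
        tfs = TFSet(("g5", "g0", "g9"))
        with pytest.warns(UserWarning, match="recommended"):
            nbs = all_neighborhoods(expr, tfs, AssociationParams(omega=5))
        assert [n.tf_id for n in nbs] == ["g5", "g0", "g9"]

    def test_worker_count_does_not_change_output(self):
        expr = _random_expr(np.random.default_rng(1), q=40, m=60)
        tfs = TFSet(tuple(f"g{k}" for k in range(8)))
        params = AssociationParams(omega=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            serial = all_neighborhoods(expr, tfs, params, workers=1)
            parallel = all_neighborhoods(expr, tfs, params, workers=4)
        assert [(n.tf_id, n.members, n.scores) for n in serial] == [
            (n.tf_id, n.members, n.scores) for n in parallel
        ]

    def test_small_compendium_warns(self):
        expr = _random_expr(np.random.default_rng(2), q=20, m=30)
        tfs = TFSet(("g0", "g1"))
        with pytest.warns(UserWarning, match="30 chips"):
            all_neighborhoods(expr, tfs, AssociationParams(omega=5))

    def test_constant_tf_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 60))
        vals[1] = 2.5
        expr = ExpressionMatrix(
            ("g0", "gconst", "g2", "g3", "g4"), tuple(f"s{j}" for j in range(60)), vals
        )
        tfs = TFSet(("g0", "gconst"))
        with pytest.warns(UserWarning, match="gconst"):
            nbs = all_neighborhoods(expr, tfs, AssociationParams(omega=2))
        assert [n.tf_id for n in nbs] == ["g0"]


class TestCompareMethods:
    def test_identical_methods_have_no_unique_genes(self):
        expr = _random_expr(np.random.default_rng(4), q=25, m=60)
        rep = compare_methods(
            expr, ["g0", "g1"],
            AssociationParams(omega=5),
            AssociationParams(omega=5),
        )
        assert rep.common_a == rep.common_b
        assert rep.unique_a == () and rep.unique_b == ()
        assert rep.shared == rep.common_a

    def test_mismatched_omega_rejected(self):
        expr = _random_expr(np.random.default_rng(5))
        with pytest.raises(ValueError, match="omega"):
            compare_methods(
                expr, ["g0"],
                AssociationParams(omega=5),
                AssociationParams(omega=6),
            )

    def test_empty_tf_subset_rejected(self):
        expr = _random_expr(np.random.default_rng(6))
        with pytest.raises(ValueError, match="empty"):
            compare_methods(
                expr, [], AssociationParams(omega=5), AssociationParams(omega=5)
            )

    def test_planted_factor_shared_under_spearman(self):
        # 3 TFs and 6 targets driven by one factor: the targets provably
        # outrank independent noise genes in every TF's top list
        rng = np.random.default_rng(8)
        f = rng.normal(size=60)
        rows, ids = [], []
        for k in range(3):
            ids.append(f"tf{k}")
            rows.append(f + 0.1 * rng.normal(size=60))
        for k in range(6):
            ids.append(f"target{k}")
            rows.append(f + 0.1 * rng.normal(size=60))
        for k in range(30):
            ids.append(f"noise{k}")
            rows.append(rng.normal(size=60))
        expr = ExpressionMatrix(tuple(ids), tuple(f"s{j}" for j in range(60)), np.array(rows))
        rep = compare_methods(
            expr, ["tf0", "tf1", "tf2"],
            AssociationParams(method="spearman", omega=8),
            AssociationParams(method="pearson", omega=8),
        )
        assert len(rep.common_a) >= 1
        assert any(g.startswith("target") for g in rep.common_a)
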