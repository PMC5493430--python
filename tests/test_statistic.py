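import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from kbt2 import (
    InteractionScores,
    PathwayCollection,
    PathwayDefinition,
    PathwayCovariance,
    ProcessingConfig,
    ExpressionProfile,
    UnmappedPathwayError,
    build_covariance,
    hotelling_t2,
    map_profile_to_pathway,
    numeric_rank,
    test_all_pathways,
    test_pathway,
)


def make_profile(values, qualified=None):
    qualified = qualified or {k: True for k in values}
    return ExpressionProfile(dict(values), dict(qualified), dict(values))


class TestMapping:
    def test_order_is_sorted_intersection(self):
        profile = make_profile({"B": 1.0, "A": -1.0, "Z": 2.0})
        pw = PathwayDefinition("p", "t", frozenset(("A", "B", "C")))
        order, x = map_profile_to_pathway(profile, pw)
        assert order == ("A", "B")
        assert list(x) == [-1.0, 1.0]

    def test_unqualified_member_zeroed_but_kept(self):
        profile = make_profile({"A": 1.0, "B": 2.0}, {"A": True, "B": False})
        pw = PathwayDefinition("p", "t", frozenset(("A", "B")))
        order, x = map_profile_to_pathway(profile, pw)
        assert order == ("A", "B") and list(x) == [1.0, 0.0]

    def test_no_overlap_signals_unmapped(self):
        profile = make_profile({"A": 1.0, "B": 1.5})
        pw = PathwayDefinition("p", "t", frozenset(("X",)))
        with pytest.raises(UnmappedPathwayError):
            map_profile_to_pathway(profile, pw)


def rulebook_oracle(order, x, scores, diag):
    """Direct, loop-free-of-cleverness restatement of the four rules."""
    q = len(order)
    S = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            if i == j:
                S[i, j] = diag
            else:
                c = scores.get(order[i], order[j])
                if c is None:
                    S[i, j] = 0.0
                elif x[i] * x[j] >= 0:
                    S[i, j] = c
                else:
                    S[i, j] = -c
    return S


class TestCovarianceRules:
    def test_diagonal_constant(self, small_scores):
        cov = build_covariance(("A", "B", "C"), np.ones(3), small_scores, 0.4)
        assert np.all(np.diag(cov.S) == 0.4)

    def test_sign_rules(self, small_scores):
        cov = build_covariance(("A", "B"), np.array([1.2, 0.8]), small_scores, 0.4)
        assert cov.S[0, 1] == 0.9
        cov = build_covariance(("A", "B"), np.array([1.2, -0.8]), small_scores, 0.4)
        assert cov.S[0, 1] == -0.9

    def test_zero_ratio_counts_as_same_sign(self, small_scores):
        # x_i·x_j = 0 falls on the ≥ 0 branch of the sign rule
        cov = build_covariance(("A", "B"), np.array([0.0, -1.0]), small_scores, 0.4)
        assert cov.S[0, 1] == 0.9

    def test_unscored_pair_zero(self, small_scores):
        cov = build_covariance(("A", "C"), np.ones(2), small_scores, 0.4)
        assert cov.S[0, 1] == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_pathways(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"P{i}" for i in range(8)]
        edges = [
            (a, b, float(rng.uniform(0.01, 1.0)))
            for i, a in enumerate(names)
            for b in names[i + 1:]
            if rng.random() < 0.4
        ]
        scores = InteractionScores.from_edges(edges)
        q = int(rng.integers(1, 7))
        order = tuple(rng.choice(names, size=q, replace=False))
        x = rng.normal(size=q)
        x[rng.random(q) < 0.3] = 0.0
        cov = build_covariance(order, x, scores, 0.4)
        assert np.array_equal(cov.S, rulebook_oracle(order, x, scores, 0.4))


class TestNumericRank:
    @pytest.mark.parametrize(
        "S, expected",
        [
            (0.4 * np.eye(3), 3),
            (np.array([[0.4, 0.4], [0.4, 0.4]]), 1),
            (np.zeros((2, 2)), 0),
        ],
    )
    def test_known_ranks(self, S, expected):
        assert numeric_rank(S) == expected


def cofactor_inverse(S):
    """Brute-force adjugate/determinant inverse for q <= 3."""
    q = S.shape[0]
    det = np.linalg.det(S)
    adj = np.zeros_like(S)
    for i in range(q):
        for j in range(q):
            minor = np.delete(np.delete(S, i, axis=0), j, axis=1)
            adj[j, i] = (-1) ** (i + j) * (np.linalg.det(minor) if q > 1 else 1.0)
    return adj / det


class TestHotellingT2:
    def test_zero_vector(self):
        cov = PathwayCovariance(("A", "B"), 0.4 * np.eye(2), 0.4)
        frag = hotelling_t2(np.zeros(2), cov)
        assert frag.T2 == 0.0 and frag.p_value == 1.0

    def test_diagonal_closed_form(self):
        cov = PathwayCovariance(("A", "B"), 0.4 * np.eye(2), 0.4)
        frag = hotelling_t2(np.ones(2), cov)
        assert frag.T2 == pytest.approx(5.0)
        assert frag.rank_q == 2 and not frag.degenerate
        assert frag.p_value == pytest.approx(chi2.sf(5.0, 2))

    def test_two_by_two_hand_inverse(self):
        S = np.array([[0.4, 0.3], [0.3, 0.4]])
        frag = hotelling_t2(np.ones(2), PathwayCovariance(("A", "B"), S, 0.4))
        assert frag.T2 == pytest.approx(0.2 / 0.07)

    def test_singular_uses_pseudoinverse_and_rank(self):
        S = np.array([[0.4, 0.4], [0.4, 0.4]])
        frag = hotelling_t2(np.ones(2), PathwayCovariance(("A", "B"), S, 0.4))
        assert frag.T2 == pytest.approx(2.5)
        assert frag.rank_q == 1 and frag.degenerate

    def test_indefinite_matrix_flagged_p_one(self):
        # eigenvalues −0.1 and 0.9: indefinite; x along the negative axis
        S = np.array([[0.4, -0.5], [-0.5, 0.4]])
        frag = hotelling_t2(np.ones(2), PathwayCovariance(("A", "B"), S, 0.4))
        assert frag.T2 < 0 and frag.indefinite and frag.p_value == 1.0

    def test_rank_zero_matrix(self):
        frag = hotelling_t2(np.ones(2), PathwayCovariance(("A", "B"), np.zeros((2, 2)), 0.4))
        assert frag.T2 == 0.0 and frag.p_value == 1.0 and frag.degenerate

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    def test_matches_cofactor_oracle(self, seed, q):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(q, q))
        S = A @ A.T + 0.4 * np.eye(q)  # PD, generic
        S = (S + S.T) / 2
        x = rng.normal(size=q)
        frag = hotelling_t2(x, PathwayCovariance(tuple("ABC"[:q]), S, 0.4))
        expected = float(x @ cofactor_inverse(S) @ x)
        assert frag.T2 == pytest.approx(expected, abs=1e-9, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        q = 5
        A = rng.normal(size=(q, q))
        S = (A @ A.T + np.eye(q))
        x = rng.normal(size=q)
        perm = rng.permutation(q)
        f1 = hotelling_t2(x, PathwayCovariance(tuple(map(str, range(q))), S, 0.4))
        f2 = hotelling_t2(
            x[perm],
            PathwayCovariance(tuple(map(str, perm)), S[np.ix_(perm, perm)], 0.4),
        )
        assert f1.T2 == pytest.approx(f2.T2, rel=1e-9)
        assert f1.rank_q == f2.rank_q

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10))
    def test_scale_property(self, seed, c):
        rng = np.random.default_rng(seed)
        q = 4
        A = rng.normal(size=(q, q))
        S = A @ A.T + np.eye(q)
        x = rng.normal(size=q)
        cov = PathwayCovariance(tuple(map(str, range(q))), S, 0.4)
        f1 = hotelling_t2(x, cov)
        f2 = hotelling_t2(c * x, cov)
        assert f2.T2 == pytest.approx(c * c * f1.T2, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pseudoinverse_agrees_with_inverse_when_nonsingular(self, seed):
        rng = np.random.default_rng(seed)
        q = 4
        A = rng.normal(size=(q, q))
        S = A @ A.T + np.eye(q)
        x = rng.normal(size=q)
        direct = float(x @ np.linalg.solve(S, x))
        via_pinv = float(x @ np.linalg.pinv(S) @ x)
        assert direct == pytest.approx(via_pinv, rel=1e-9, abs=1e-9)


class TestTestPathway:
    def test_two_member_no_interactions(self, small_collection):
        profile = make_profile({"X": 1.0, "Y": 1.0})
        result = test_pathway(
            profile, small_collection["pwC"], InteractionScores(), ProcessingConfig()
        )
        assert result.T2 == pytest.approx(5.0) and result.rank_q == 2

    def test_all_members_unqualified(self, small_collection, small_scores):
        profile = make_profile({"A": 1.0, "B": 1.0}, {"A": False, "B": False})
        result = test_pathway(profile, small_collection["pwB"], small_scores)
        assert result.T2 == 0.0 and result.p_value == 1.0

    def test_singleton_pathway_scalar_case(self):
        profile = make_profile({"A": 2.0, "B": 0.1})
        pw = PathwayDefinition("p", "t", frozenset("A"))
        result = test_pathway(profile, pw, InteractionScores())
        assert result.T2 == pytest.approx(10.0) and result.rank_q == 1


class TestTestAllPathways:
    def test_unmapped_pathways_reported_separately(self, small_collection, small_scores):
        profile = make_profile({"A": 1.0, "B": -1.0, "C": 0.5, "D": 2.0})
        results, skipped = test_all_pathways(profile, small_collection, small_scores)
        assert {r.pathway_id for r in results} == {"pwA", "pwB"}
        assert skipped == ["pwC"]
        assert all(r.p_bh is not None for r in results)

    def test_collection_order_does_not_matter(self, small_scores):
        profile = make_profile({"A": 1.0, "B": -1.0, "C": 0.5, "D": 2.0})
        pws = [
            PathwayDefinition("p1", "t", frozenset(("A", "B"))),
            PathwayDefinition("p2", "t", frozenset(("C", "D"))),
        ]
        r1, _ = test_all_pathways(profile, PathwayCollection(pws), small_scores)
        r2, _ = test_all_pathways(profile, PathwayCollection(reversed(pws)), small_scores)
        assert [(r.pathway_id, r.T2) for r in r1] == [(r.pathway_id, r.T2) for r in r2]

    def test_duplicate_pathway_ids_fatal(self):
        coll = PathwayCollection([PathwayDefinition("p1", "t", frozenset("A"))])
        with pytest.raises(ValueError):
            coll.add(PathwayDefinition("p1", "t", frozenset("B")))
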