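"""The exact comparative decomposition: factorization, ordering, exclusivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import eigh

from gsvdcna import core_gsvd as cg
from gsvdcna.errors import DataMismatchError, RankDeficiencyError

from conftest import random_pair


class TestGsvdFactorization:
    def test_identity_pair_is_fully_degenerate(self):
        res = cg.gsvd(cg.ProfilePair(np.eye(3), np.eye(3), list("abc")))
        np.testing.assert_allclose(res.sigma1, np.ones(3), atol=1e-12)
        np.testing.assert_allclose(res.sigma2, np.ones(3), atol=1e-12)
        np.testing.assert_allclose(res.theta, np.zeros(3), atol=1e-12)
        np.testing.assert_allclose(res.VT, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.U1, np.eye(3), atol=1e-12)
        assert res.degenerate_groups == [[0, 1, 2]]

    def test_diagonal_pair(self):
        res = cg.gsvd(cg.ProfilePair(np.diag([3.0, 1.0]), np.eye(2), list("ab")))
        np.testing.assert_allclose(res.sigma1, [3.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(res.sigma2, [1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(res.theta, [np.arctan(3) - np.pi / 4, 0.0], atol=1e-12)

    def test_squared_ratios_match_gram_pencil_eigenvalues(self):
        rng = np.random.default_rng(11)
        pair = random_pair(rng, 8, 8, 3)
        res = cg.gsvd(pair)
        pencil = eigh(pair.D1.T @ pair.D1, pair.D2.T @ pair.D2, eigvals_only=True)[::-1]
        np.testing.assert_allclose(res.ratios**2, pencil, rtol=1e-8)

    @pytest.mark.parametrize("m1,m2,n", [(10, 12, 4), (300, 280, 20), (2000, 2100, 35)])
    def test_reconstruction_orthonormality_row_norms(self, m1, m2, n):
        rng = np.random.default_rng(m1 + m2 + n)
        pair = random_pair(rng, m1, m2, n)
        res = cg.gsvd(pair)
        for i, D in ((1, pair.D1), (2, pair.D2)):
            err = np.linalg.norm(res.reconstruct(i) - D) / np.linalg.norm(D)
            assert err <= 1e-10
        assert np.abs(res.U1.T @ res.U1 - np.eye(n)).max() <= 1e-10
        assert np.abs(res.U2.T @ res.U2 - np.eye(n)).max() <= 1e-10
        assert np.abs(np.linalg.norm(res.VT, axis=1) - 1).max() <= 1e-10
        assert np.all(res.sigma1 > 0) and np.all(res.sigma2 > 0)
        assert np.all(np.diff(res.ratios) <= 1e-12)
        assert np.all(np.abs(res.theta) < np.pi / 4)

    def test_exchange_symmetry(self):
        rng = np.random.default_rng(5)
        pair = random_pair(rng, 40, 50, 6)
        fwd = cg.gsvd(pair)
        swp = cg.gsvd(cg.ProfilePair(pair.D2, pair.D1, pair.patient_ids))
        np.testing.assert_allclose(swp.theta, -fwd.theta[::-1], atol=1e-9)
        np.testing.assert_allclose(swp.sigma1, fwd.sigma2[::-1], atol=1e-9)
        np.testing.assert_allclose(swp.sigma2, fwd.sigma1[::-1], atol=1e-9)
        # same components up to order reversal and the +-1 phase freedom
        overlap = np.abs(swp.VT @ fwd.VT[::-1].T)
        np.testing.assert_allclose(np.diag(overlap), np.ones(6), atol=1e-9)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        pair = random_pair(rng, 30, 35, 5)
        perm = rng.permutation(5)
        permuted = cg.ProfilePair(
            pair.D1[:, perm], pair.D2[:, perm], [pair.patient_ids[j] for j in perm]
        )
        a, b = cg.gsvd(pair), cg.gsvd(permuted)
        np.testing.assert_allclose(b.sigma1, a.sigma1, atol=1e-10)
        np.testing.assert_allclose(b.theta, a.theta, atol=1e-10)
        np.testing.assert_allclose(b.U1, a.U1, atol=1e-9)
        np.testing.assert_allclose(b.VT, a.VT[:, perm], atol=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        pair = random_pair(rng, 25, 30, 4)
        perm = rng.permutation(25)
        shuffled = cg.ProfilePair(pair.D1[perm], pair.D2, pair.patient_ids)
        a, b = cg.gsvd(pair), cg.gsvd(shuffled)
        np.testing.assert_allclose(b.U1, a.U1[perm], atol=1e-10)
        np.testing.assert_allclose(b.U2, a.U2, atol=1e-10)
        np.testing.assert_allclose(b.VT, a.VT, atol=1e-10)
        np.testing.assert_allclose(b.sigma1, a.sigma1, atol=1e-10)

    def test_sign_convention_is_bit_deterministic(self):
        rng = np.random.default_rng(9)
        pair = random_pair(rng, 60, 55, 7)
        a, b = cg.gsvd(pair), cg.gsvd(pair)
        assert np.array_equal(a.VT, b.VT)
        assert np.array_equal(a.U1, b.U1)
        # and the convention itself: leading |entry| of each row positive
        lead = np.argmax(np.abs(a.VT), axis=1)
        assert np.all(a.VT[np.arange(7), lead] > 0)

    def test_rank_deficiency_error_names_matrix(self):
        rng = np.random.default_rng(10)
        D1 = rng.normal(size=(10, 3))
        D1[:, 2] = D1[:, 0] + D1[:, 1]
        D2 = rng.normal(size=(12, 3))
        with pytest.raises(RankDeficiencyError, match="D1.*rank 2"):
            cg.gsvd(cg.ProfilePair(D1, D2, list("abc")))
        with pytest.raises(RankDeficiencyError, match="D2"):
            cg.gsvd(cg.ProfilePair(D2, D1, list("abc")))

    def test_mismatched_inputs_rejected_before_numerics(self):
        with pytest.raises(DataMismatchError, match="duplicate"):
            cg.ProfilePair(np.eye(3), np.eye(3), ["a", "a", "b"])
        with pytest.raises(DataMismatchError, match="column counts"):
            cg.ProfilePair(np.eye(3), np.eye(3)[:, :2], list("abc"))
        with pytest.raises(DataMismatchError, match="N <= min"):
            cg.ProfilePair(np.ones((2, 3)) + np.eye(3)[:2], np.eye(3), list("abc"))

    def test_hdf5_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        res = cg.gsvd(random_pair(rng, 20, 22, 4))
        path = tmp_path / "gsvd.h5"
        cg.save_gsvd_hdf5(res, path, metadata={"seed": 12})
        back, meta = cg.load_gsvd_hdf5(path)
        assert meta["seed"] == 12
        np.testing.assert_array_equal(back.U1, res.U1)
        np.testing.assert_array_equal(back.VT, res.VT)
        np.testing.assert_array_equal(back.theta, res.theta)
        assert back.degenerate_groups == res.degenerate_groups
        assert back.patient_ids == res.patient_ids


class TestAngularDistance:
    @pytest.mark.parametrize("s", [1.0, 0.5, 7.3])
    def test_zero_at_equal_values(self, s):
        assert cg.angular_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_limit_at_extreme_ratio(self):
        assert cg.angular_distance(1e9, 1.0) == pytest.approx(np.pi / 4, abs=1e-8)
        assert cg.angular_distance(1.0, 1e9) == pytest.approx(-np.pi / 4, abs=1e-8)

    def test_closed_form_value(self):
        assert cg.angular_distance(3.0, 1.0) == pytest.approx(0.46364760, abs=1e-8)

    def test_antisymmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        s1, s2 = rng.uniform(0.01, 100, 50), rng.uniform(0.01, 100, 50)
        th = cg.angular_distance(s1, s2)
        np.testing.assert_allclose(cg.angular_distance(s2, s1), -th, atol=1e-12)
        assert np.all(np.abs(th) < np.pi / 4)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            cg.angular_distance(0.0, 1.0)
        with pytest.raises(ValueError):
            cg.angular_distance(1.0, -2.0)


class TestFractionsAndEntropy:
    def test_uniform_fractions(self):
        np.testing.assert_allclose(
            cg.generalized_fractions([3.3] * 4), [0.25] * 4, atol=1e-14
        )

    def test_squared_convention_hand_value(self):
        np.testing.assert_allclose(
            cg.generalized_fractions([2.0, 1.0, 1.0], exponent=2),
            [2 / 3, 1 / 6, 1 / 6],
            atol=1e-14,
        )
        np.testing.assert_allclose(
            cg.generalized_fractions([2.0, 1.0, 1.0], exponent=1),
            [0.5, 0.25, 0.25],
            atol=1e-14,
        )

    def test_fractions_normalize_and_preserve_order(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            s = rng.uniform(0.01, 10, rng.integers(2, 20))
            p = cg.generalized_fractions(s)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.array_equal(np.argsort(p), np.argsort(s))
        with pytest.raises(ValueError):
            cg.generalized_fractions([1.0, 0.0])

    def test_entropy_extremes_and_value(self):
        assert cg.generalized_entropy([0.25] * 4) == pytest.approx(1.0, abs=1e-12)
        assert cg.generalized_entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-12)
        assert cg.generalized_entropy([0.9, 0.1]) == pytest.approx(0.4690, abs=1e-3)
        with pytest.raises(ValueError):
            cg.generalized_entropy([1.0])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=20))
def test_fraction_and_entropy_invariants_hold_for_any_spectrum(sigma):
    """Fractions form a probability vector and entropy stays in [0, 1]
    for every positive spectrum, under both exponent conventions."""
    s = np.asarray(sigma)
    for k in (1, 2):
        p = cg.generalized_fractions(s, exponent=k)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p > 0)
        assert -1e-12 <= cg.generalized_entropy(p) <= 1 + 1e-12


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.floats(1e-6, 1e6), st.floats(1e-6, 1e6)
)
def test_angular_distance_antisymmetry_and_bounds(s1, s2):
    th = cg.angular_distance(s1, s2)
    assert cg.angular_distance(s2, s1) == pytest.approx(-th, abs=1e-12)
    assert -np.pi / 4 < th < np.pi / 4


class TestComponentCalls:
    def _result(self, theta, p1, p2):
        n = len(theta)
        eye = np.eye(n)
        return cg.GSVDResult(
            U1=eye, U2=eye, sigma1=np.ones(n), sigma2=np.ones(n), VT=eye,
            theta=np.asarray(theta), fractions1=np.asarray(p1), fractions2=np.asarray(p2),
            entropy1=1.0, entropy2=1.0,
        )

    def test_rule_outcomes(self):
        res = self._result(
            [0.70, 0.01, 0.70, -0.70],
            [0.30, 0.20, 0.001, 0.10],
            [0.001, 0.20, 0.30, 0.30],
        )
        calls = cg.call_components(res, theta_threshold=np.pi / 8, fraction_threshold=0.05)
        assert [c.call for c in calls] == [
            "exclusive_to_1",
            "common",
            "unassigned",
            "exclusive_to_2",
        ]

    def test_threshold_validation(self):
        res = self._result([0.0], [1.0], [1.0])
        with pytest.raises(ValueError):
            cg.call_components(res, theta_threshold=1.0)
        with pytest.raises(ValueError):
            cg.call_components(res, fraction_threshold=0.0)
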