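"""SPD geometry: shrinkage covariance, matrix functions, centering."""

import numpy as np
import pytest

from neuraxes.geometry import (SpdMatrix, average_seed_signal, center_cohort,
                               equally_spaced_volumes, karcher_mean,
                               ledoit_wolf_cov, parallel_transport,
                               seed_connectivity, spd_exp, spd_invsqrt,
                               spd_log, spd_sqrt, tangent_project,
                               tangent_retract)


def _random_spd(p, rng, scale=1.0):
    A = rng.standard_normal((p, p))
    return A @ A.T / p + scale * np.eye(p)


class TestLedoitWolf:
    def test_matches_sklearn_oracle_on_fixed_input(self):
        from sklearn.covariance import ledoit_wolf
        rng = np.random.default_rng(42)
        X = rng.standard_normal((20, 5)) @ np.diag([1.0, 2.0, 0.5, 1.5, 1.0])
        mine, shrink = ledoit_wolf_cov(X, return_shrinkage=True)
        sk_cov, sk_shrink = ledoit_wolf(X)
        assert abs(shrink - sk_shrink) < 1e-10
        assert np.abs(mine.values - sk_cov).max() < 1e-10

    def test_white_noise_is_near_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20000, 4))
        cov = ledoit_wolf_cov(X).values
        off = cov[~np.eye(4, dtype=bool)]
        se = 1.0 / np.sqrt(20000)
        assert np.abs(off).max() < 3 * se
        assert np.allclose(np.diag(cov), 1.0, atol=3 * se)

    def test_positive_definite_when_p_exceeds_subepoch_n(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 60))
        cov = ledoit_wolf_cov(X).values
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_constant_column_jitter_policy(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning, match="constant column"):
            cov = ledoit_wolf_cov(X).values
        assert np.linalg.eigvalsh(cov).min() > 0


class TestMatrixFunctions:
    def test_log_identity_is_zero(self):
        assert np.allclose(spd_log(np.eye(4)), 0.0)

    def test_sqrt_of_diagonal(self):
        assert np.allclose(spd_sqrt(np.diag([4.0, 9.0])),
                           np.diag([2.0, 3.0]))

    def test_exp_log_round_trip(self):
        rng = np.random.default_rng(3)
        S = _random_spd(6, rng)
        assert np.abs(spd_exp(spd_log(S)) - S).max() < 1e-8

    def test_sqrt_squares_back(self):
        rng = np.random.default_rng(4)
        S = _random_spd(5, rng)
        R = spd_sqrt(S)
        assert np.abs(R @ R - S).max() < 1e-8

    def test_log_rejects_non_pd(self):
        with pytest.raises(ValueError, match="positive definite"):
            spd_log(np.diag([1.0, -0.5]))


class TestKarcherMean:
    def test_single_matrix_is_itself(self):
        rng = np.random.default_rng(5)
        S = _random_spd(4, rng)
        assert np.allclose(karcher_mean([S]).values, S)

    def test_scalar_geometric_mean(self):
        m = karcher_mean([np.array([[1.0]]), np.array([[4.0]])])
        assert m.values[0, 0] == pytest.approx(2.0, abs=1e-8)

    def test_commuting_diagonal_family(self):
        mats = [np.diag([1.0, 8.0]), np.diag([4.0, 2.0]), np.diag([2.0, 4.0])]
        expected = np.diag([np.exp(np.mean(np.log([1, 4, 2]))),
                            np.exp(np.mean(np.log([8, 2, 4])))])
        assert np.abs(karcher_mean(mats).values - expected).max() < 1e-8

    def test_duplicates_and_permutation_invariance(self):
        rng = np.random.default_rng(6)
        S1, S2, S3 = (_random_spd(4, rng) for _ in range(3))
        m1 = karcher_mean([S1, S2, S3]).values
        m2 = karcher_mean([S3, S1, S2]).values
        assert np.abs(m1 - m2).max() < 1e-7
        md = karcher_mean([S1, S1]).values
        assert np.abs(md - S1).max() < 1e-7

    def test_fixed_point_residual_below_tolerance(self):
        rng = np.random.default_rng(7)
        mats = [_random_spd(5, rng) for _ in range(8)]
        M = karcher_mean(mats, tol=1e-8).values
        Mis = spd_invsqrt(M)
        W = np.mean([spd_log(Mis @ S @ Mis) for S in mats], axis=0)
        assert np.linalg.norm(W) < 1e-8


class TestTangent:
    def test_projection_at_base_is_zero(self):
        rng = np.random.default_rng(8)
        S = _random_spd(4, rng)
        assert np.abs(tangent_project(S, S).values).max() < 1e-10

    def test_identity_base_collapses_to_log(self):
        rng = np.random.default_rng(9)
        S = _random_spd(4, rng)
        T = tangent_project(S, np.eye(4))
        assert np.abs(T.values - spd_log(S)).max() < 1e-10

    def test_round_trip_through_exp_map(self):
        rng = np.random.default_rng(10)
        S, B = _random_spd(5, rng), _random_spd(5, rng)
        back = tangent_retract(tangent_project(S, B), B)
        assert np.abs(back.values - S).max() < 1e-8

    def test_congruence_equivariance(self):
        rng = np.random.default_rng(11)
        S, B = _random_spd(4, rng), _random_spd(4, rng)
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        left = tangent_project(A @ S @ A.T, A @ B @ A.T).values
        right = A @ tangent_project(S, B).values @ A.T
        assert np.abs(left - right).max() < 1e-6 * max(1, np.abs(right).max())

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            tangent_project(np.eye(3), np.eye(4))


class TestTransport:
    def test_same_base_is_identity(self):
        rng = np.random.default_rng(12)
        B = _random_spd(4, rng)
        T = tangent_project(_random_spd(4, rng), B)
        out = parallel_transport(T, B, B)
        assert np.abs(out.values - T.values).max() < 1e-8

    def test_zero_vector_maps_to_zero(self):
        rng = np.random.default_rng(13)
        A, B = _random_spd(4, rng), _random_spd(4, rng)
        out = parallel_transport(np.zeros((4, 4)), A, B)
        assert np.abs(out.values).max() == 0.0

    def test_affine_invariant_norm_preserved(self):
        rng = np.random.default_rng(14)
        A, B = _random_spd(5, rng), _random_spd(5, rng)
        T = tangent_project(_random_spd(5, rng), A)
        Tc = parallel_transport(T, A, B)
        Ais, Bis = spd_invsqrt(A), spd_invsqrt(B)
        n1 = np.linalg.norm(Ais @ T.values @ Ais)
        n2 = np.linalg.norm(Bis @ Tc.values @ Bis)
        assert n1 == pytest.approx(n2, abs=1e-8)


class TestCenterCohort:
    def test_equal_conditions_give_zero_tangents(self):
        rng = np.random.default_rng(15)
        S1, S2 = _random_spd(4, rng), _random_spd(4, rng)
        covs = {"a": {"x": SpdMatrix(S1), "y": SpdMatrix(S1)},
                "b": {"x": SpdMatrix(S2), "y": SpdMatrix(S2)}}
        cent = center_cohort(covs)
        for subj in ("a", "b"):
            for cond in ("x", "y"):
                assert np.abs(cent[subj][cond].values).max() < 1e-6

    def test_commuting_contrasts_align_across_subjects(self):
        # two subjects, identical within-subject contrast, different
        # (commuting, diagonal) base covariance
        contrast = np.diag([1.2, 1.0, 0.8])
        base_a, base_b = np.diag([1.0, 2.0, 3.0]), np.diag([2.0, 1.0, 0.5])
        covs = {
            "a": {"hi": SpdMatrix(base_a @ contrast),
                  "lo": SpdMatrix(base_a @ np.linalg.inv(contrast))},
            "b": {"hi": SpdMatrix(base_b @ contrast),
                  "lo": SpdMatrix(base_b @ np.linalg.inv(contrast))},
        }
        cent = center_cohort(covs)
        diff_a = cent["a"]["hi"].values - cent["a"]["lo"].values
        diff_b = cent["b"]["hi"].values - cent["b"]["lo"].values
        assert np.abs(diff_a - diff_b).max() < 1e-6

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            center_cohort({})


class TestSeedHelpers:
    def test_average_seed_signal_collapses_columns(self):
        rng = np.random.default_rng(20)
        X = rng.standard_normal((30, 6))
        out = average_seed_signal(X, [1, 3])
        assert out.shape == (30, 5)
        assert np.allclose(out[:, 0], X[:, [1, 3]].mean(axis=1))
        assert np.allclose(out[:, 1:], X[:, [0, 2, 4, 5]])

    def test_equally_spaced_volumes_cover_scan(self):
        idx = equally_spaced_volumes(204, 100)
        assert idx[0] == 0 and idx[-1] == 203
        assert len(idx) == 100
        assert np.all(np.diff(idx) >= 1)
        assert np.array_equal(equally_spaced_volumes(50, 50), np.arange(50))

    def test_equally_spaced_volumes_validates(self):
        with pytest.raises(ValueError):
            equally_spaced_volumes(10, 11)


class TestSeedConnectivity:
    def test_zero_tangent_gives_zero_vector(self):
        v = seed_connectivity(np.zeros((5, 5)), [0, 1])
        assert v.shape == (3,)
        assert np.all(v == 0)

    def test_single_seed_returns_its_row(self):
        rng = np.random.default_rng(16)
        T = rng.standard_normal((4, 4))
        T = T + T.T
        v = seed_connectivity(T, [2])
        assert np.allclose(v, T[2, [0, 1, 3]])

    def test_hand_computed_two_seed_means(self):
        T = np.array([[0.0, 1.0, 2.0, 3.0],
                      [1.0, 0.0, 4.0, 5.0],
                      [2.0, 4.0, 0.0, 6.0],
                      [3.0, 5.0, 6.0, 0.0]])
        v = seed_connectivity(T, [0, 1])
        assert np.allclose(v, [(2 + 4) / 2, (3 + 5) / 2])

    def test_full_seed_set_rejected(self):
        with pytest.raises(ValueError, match="covers all"):
            seed_connectivity(np.zeros((3, 3)), [0, 1, 2])
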