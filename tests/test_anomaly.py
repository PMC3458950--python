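"""One-class SVM training, abnormality indices and the mixed-group protocol."""

import numpy as np
import pytest
from scipy import optimize, stats

from normcoh import (
    abnormality_index,
    default_gamma,
    mixed_group_protocol,
    rbf_kernel,
    train_ocsvm,
)


def brute_force_ocsvm(X, nu, gamma):
    """Independent dual solve: minimize 0.5 a'Ka s.t. 0<=a<=1/(nu n), sum a = 1.

    Solved with SLSQP from several starts; rho from a margin support vector.
    """
    n = X.shape[0]
    K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    ub = 1.0 / (nu * n)
    best = None
    for start in range(3):
        a0 = np.random.default_rng(start).dirichlet(np.ones(n))
        res = optimize.minimize(
            lambda a: 0.5 * a @ K @ a,
            np.clip(a0, 0, ub),
            jac=lambda a: K @ a,
            bounds=[(0.0, ub)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    a = best.x
    margin = (a > 1e-6) & (a < ub - 1e-6)
    sv = margin if margin.any() else a > 1e-6
    rho = np.median(K[sv] @ a)
    return a, rho, K


class TestKernel:
    def test_closed_forms(self):
        u = np.array([1.0, 2.0])
        assert rbf_kernel(u, u, 0.7) == 1.0
        assert abs(rbf_kernel(u, u + [1.0, 0.0], 1.0) - np.exp(-1)) < 1e-15
        assert rbf_kernel(u, u + 100.0, 1e-9) > 0.999  # gamma -> 0 limit

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel([1.0], [1.0, 2.0], 1.0)

    def test_default_gamma_heuristic(self):
        assert default_gamma(125) == 1.0 / 125
        assert default_gamma(1) == 1.0
        assert default_gamma(124) == 1.0 / 124
        with pytest.raises(ValueError):
            default_gamma(0)


class TestTraining:
    def test_identical_points_equal_scores(self):
        X = np.tile([1.0, 2.0, 3.0], (8, 1))
        m = train_ocsvm(X, nu=0.5)
        scores = [m.decision_score(v) for v in X]
        assert np.ptp(scores) < 1e-9

    def test_dual_constraints_hold(self, rng):
        X = rng.standard_normal((42, 10))
        m = train_ocsvm(X, nu=0.5)
        assert abs(m.alphas.sum() - 1.0) < 1e-6
        assert (m.alphas >= -1e-12).all()
        assert (m.alphas <= 1.0 / (0.5 * 42) + 1e-9).all()

    @pytest.mark.parametrize("nu", [0.2, 0.5, 0.8])
    def test_nu_property(self, rng, nu):
        """Outlier fraction <= nu and support fraction >= nu, within 1/n."""
        X = rng.standard_normal((60, 8))
        m = train_ocsvm(X, nu=nu)
        scores = np.array([m.decision_score(v) for v in X])
        n = X.shape[0]
        # margin support vectors sit numerically at zero; don't count them
        assert (scores < -1e-7).mean() <= nu + 1.0 / n
        assert m.alphas.size / n >= nu - 1.0 / n

    def test_agrees_with_bruteforce_dual(self, rng):
        X = rng.standard_normal((6, 2))
        nu, gamma = 0.5, 0.5
        m = train_ocsvm(X, nu=nu, gamma=gamma)
        a_bf, rho_bf, K = brute_force_ocsvm(X, nu, gamma)
        # compare decision scores (alphas may permute among ties)
        mine = np.array([m.decision_score(v) for v in X])
        brute = K @ a_bf - rho_bf
        assert np.abs(mine - brute).max() < 1e-4

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            train_ocsvm(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            train_ocsvm(np.zeros((5, 3)), nu=1.5)
        X = np.zeros((5, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_ocsvm(X)


class TestAbnormalityIndex:
    def test_outlier_scores_higher_than_center(self, rng):
        X = rng.standard_normal((50, 3))
        m = train_ocsvm(np.vstack([X, [[30.0, 30.0, 30.0]]]), nu=0.3, gamma=0.2)
        central = abnormality_index(m, X.mean(axis=0))
        outlier = abnormality_index(m, np.array([30.0, 30.0, 30.0]))
        assert outlier > central

    def test_margin_error_has_positive_index(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)), [[50.0, 50.0]]])
        m = train_ocsvm(X, nu=0.2, gamma=0.5)
        assert abnormality_index(m, np.array([50.0, 50.0])) > 0

    def test_anticorrelates_with_density_ranking(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 2))
        m = train_ocsvm(X, nu=0.5, gamma=0.5)
        idx = np.array([abnormality_index(m, v) for v in X])
        kde = stats.gaussian_kde(X.T)(X.T)
        assert stats.spearmanr(idx, kde).statistic < -0.8

    def test_dimension_mismatch_raises(self, rng):
        m = train_ocsvm(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError, match="dimension"):
            abnormality_index(m, np.zeros(3))


class TestMixedGroupProtocol:
    def test_identical_groups_identical_distributions(self, rng):
        A = rng.standard_normal((10, 5))
        results, _ = mixed_group_protocol(A, A.copy(), group_names=("g1", "g2"))
        g1 = sorted(r.index for r in results if r.group == "g1")
        g2 = sorted(r.index for r in results if r.group == "g2")
        assert np.allclose(g1, g2, atol=1e-9)

    def test_trains_on_pooled_sample(self, rng):
        A = rng.standard_normal((21, 6))
        B = rng.standard_normal((21, 6))
        results, model = mixed_group_protocol(A, B)
        assert model.n_train == 42
        assert len(results) == 42

    def test_row_permutation_invariance(self, rng):
        A = rng.standard_normal((12, 5))
        B = rng.standard_normal((12, 5))
        r1, _ = mixed_group_protocol(A, B)
        perm = rng.permutation(12)
        r2, _ = mixed_group_protocol(A[perm], B)
        i1 = np.sort([r.index for r in r1])
        i2 = np.sort([r.index for r in r2])
        assert np.allclose(i1, i2, atol=1e-6)

    def test_duplicating_training_set_keeps_indices(self, rng):
        A = rng.standard_normal((10, 4))
        B = rng.standard_normal((10, 4))
        r1, _ = mixed_group_protocol(A, B)
        r2, _ = mixed_group_protocol(np.vstack([A, A]), np.vstack([B, B]))
        i1 = np.array([r.index for r in r1])
        i2 = np.array([r.index for r in r2[:10] + r2[20:30]])
        assert np.allclose(i1, i2, atol=1e-4)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            mixed_group_protocol(rng.standard_normal((5, 3)), rng.standard_normal((5, 4)))

    def test_separated_cluster_geometry(self, rng):
        """Points between two far clusters score as less typical than
        members of the tighter cluster."""
        tight = 0.1 * rng.standard_normal((15, 2))
        far = 0.1 * rng.standard_normal((15, 2)) + 20.0
        results, model = mixed_group_protocol(tight, far, nu=0.3, gamma=0.05)
        between = abnormality_index(model, np.array([10.0, 10.0]))
        tight_med = np.median([r.index for r in results[:15]])
        assert tight_med < between
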