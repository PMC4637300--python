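"""Two-block PLS: SVD oracle, orthogonality, R^2, correlation circle, shift."""

import numpy as np
import pandas as pd
import pytest

from assocmod.pls import (
    correlation_circle,
    cumulative_r2,
    effector_target_shift,
    fit_pls,
)


def svd_first_weight(X, Y):
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    u, _, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    return u[:, 0]


class TestFitPLS:
    def test_weight_matches_svd_oracle_over_many_instances(self):
        cosines = []
        for s in range(100):
            r = np.random.default_rng(s)
            X = r.normal(size=(50, 20))
            Y = r.normal(size=(50, 15))
            model = fit_pls(X, Y, 1)
            cosines.append(abs(svd_first_weight(X, Y) @ model.x_weights[:, 0]))
        assert min(cosines) >= 0.999

    def test_y_equals_x_gives_first_principal_component(self, rng):
        X = rng.normal(size=(50, 10))
        model = fit_pls(X, X, 1)
        Xc = X - X.mean(0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Xc @ vt[0]
        cos = abs(pc1 @ model.x_scores[:, 0]) / (
            np.linalg.norm(pc1) * np.linalg.norm(model.x_scores[:, 0])
        )
        assert cos >= 0.999

    def test_scores_orthogonal_and_reconstruction(self, rng):
        X = rng.normal(size=(40, 12))
        Y = rng.normal(size=(40, 9))
        model = fit_pls(X, Y, 4)
        T = model.x_scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))
        Xc = X - X.mean(0)
        recon = T @ model.x_loadings.T + model.x_residual
        assert np.max(np.abs(Xc - recon)) < 1e-8

    def test_zero_components_base_case(self, rng):
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=(10, 3))
        model = fit_pls(X, Y, 0)
        assert model.x_scores.shape == (10, 0)
        np.testing.assert_allclose(model.x_residual, X - X.mean(0))

    def test_zero_variance_column_dropped_with_warning(self, rng, caplog):
        X = rng.normal(size=(20, 5))
        X[:, 2] = 1.0
        Y = rng.normal(size=(20, 4))
        with caplog.at_level("WARNING"):
            model = fit_pls(X, Y, 2)
        assert any("zero-variance" in r.message for r in caplog.records)
        assert np.all(model.x_weights[2] == 0.0)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, X, 5)

    def test_matches_sklearn_regression_mode(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(60, 10))
        Y = rng.normal(size=(60, 7))
        model = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, Y)
        for k in range(3):
            cos = abs(sk.x_weights_[:, k] @ model.x_weights[:, k])
            assert cos >= 0.999


class TestCumulativeR2:
    def test_full_rank_identity_block(self, rng):
        X = rng.normal(size=(30, 6))
        model = fit_pls(X, X, 6)
        assert cumulative_r2(model, X, 6) == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_components(self, rng):
        X = rng.normal(size=(40, 10))
        Y = rng.normal(size=(40, 8))
        model = fit_pls(X, Y, 5)
        r2 = [cumulative_r2(model, Y, m) for m in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 12))
        Y = rng.normal(size=(50, 9))
        model = fit_pls(X, Y, 4)
        Yc = Y - Y.mean(0)
        for m in (1, 2, 3, 4):
            T = model.x_scores[:, :m]
            coef = np.linalg.lstsq(T, Yc, rcond=None)[0]
            ref = 1.0 - np.sum((Yc - T @ coef) ** 2) / np.sum(Yc**2)
            assert cumulative_r2(model, Y, m) == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_column_permutation_of_y(self, rng):
        X = rng.normal(size=(30, 8))
        Y = rng.normal(size=(30, 6))
        perm = rng.permutation(6)
        r1 = cumulative_r2(fit_pls(X, Y, 2), Y, 2)
        r2 = cumulative_r2(fit_pls(X, Y[:, perm], 2), Y[:, perm], 2)
        assert r1 == pytest.approx(r2, abs=1e-10)


class TestCorrelationCircle:
    def test_geometry_of_known_variables(self, rng):
        X = rng.normal(size=(60, 6))
        Y = rng.normal(size=(60, 4))
        model = fit_pls(X, Y, 2)
        t1 = model.x_scores[:, 0]
        ortho = rng.normal(size=60)
        for t in (model.x_scores[:, 0], model.x_scores[:, 1]):
            ortho -= (ortho @ t) / (t @ t) * t
        const = np.ones(60)
        dup = X[:, 0] * 2.0 + 5.0  # r = 1 with X[:,0]
        Xext = pd.DataFrame(
            np.column_stack([X, t1, ortho, const, dup]),
            columns=[*(f"x{i}" for i in range(6)), "is_t1", "is_orth", "is_const", "is_dup"],
        )
        coords = correlation_circle(model, Xext, Y).set_index("variable")
        assert coords.loc["is_t1", "c1"] == pytest.approx(1.0, abs=1e-8)
        assert coords.loc["is_t1", "c2"] == pytest.approx(0.0, abs=1e-8)
        assert abs(coords.loc["is_orth", "c1"]) < 1e-8 and abs(coords.loc["is_orth", "c2"]) < 1e-8
        assert bool(coords.loc["is_const", "flagged"])
        assert coords.loc["is_dup", ["c1", "c2"]].to_numpy() == pytest.approx(
            coords.loc["x0", ["c1", "c2"]].to_numpy(), abs=1e-10
        )
        norms = np.hypot(coords["c1"], coords["c2"])
        assert (norms <= 1.0 + 1e-9).all()


class TestEffectorTargetShift:
    def _arms_targets(self, rng, coupled=True, beta=0.8):
        n = 80
        focal = rng.normal(size=n)
        others = pd.DataFrame(
            rng.normal(size=(4, n)), index=[f"arm{i}" for i in range(4)]
        )
        if coupled:
            targets = np.vstack([beta * focal + rng.normal(size=n) for _ in range(20)])
        else:
            targets = rng.normal(size=(20, n))
        return focal, others, pd.DataFrame(targets, index=[f"g{i}" for i in range(20)])

    def test_coupled_targets_shift_detected(self, rng):
        focal, others, targets = self._arms_targets(rng, coupled=True)
        _, _, _, p = effector_target_shift(focal, others, targets)
        assert p < 0.01

    def test_independent_focal_arm_not_significant_usually(self):
        hits = 0
        for s in range(30):
            r = np.random.default_rng(900 + s)
            focal, others, targets = self._arms_targets(r, coupled=False)
            _, _, _, p = effector_target_shift(focal, others, targets)
            hits += p < 0.05
        assert hits <= 5

    def test_background_equal_to_focal_gives_identity(self, rng):
        focal, _, targets = self._arms_targets(rng, coupled=True)
        others = pd.DataFrame([focal], index=["same"])
        _, _, d, p = effector_target_shift(focal, others, targets)
        assert d == 0.0 and p == 1.0

    def test_too_few_targets_rejected(self, rng):
        focal, others, targets = self._arms_targets(rng)
        with pytest.raises(ValueError, match="targets"):
            effector_target_shift(focal, others, targets.iloc[:3])
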