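"""Dictionary learning core: OMP, initialization, updates, training, residuals."""

import itertools

import numpy as np
import pytest

from myodict.dfdl import (
    DfdlClassifier,
    aggregate_trial,
    classify_window,
    dfdl_objective,
    estimate_sparsity_level,
    init_dictionary,
    load_model,
    omp_sparse_code,
    quadratic_objective,
    save_model,
    update_dictionary,
    update_matrices,
)


def unit_dictionary(rng, d, k):
    D = rng.standard_normal((d, k))
    return D / np.linalg.norm(D, axis=0)


def best_single_atom_residual(y, D):
    """Exhaustive 1-sparse least-squares oracle."""
    best = np.inf
    for j in range(D.shape[1]):
        a = D[:, j]
        coef = (a @ y) / (a @ a)
        best = min(best, float(np.linalg.norm(y - coef * a)))
    return best


class TestOmp:
    def test_exact_atom_identity(self, rng):
        D = unit_dictionary(rng, 8, 5)
        S = omp_sparse_code(D[:, [3]], D, 1)
        assert S[3, 0] == pytest.approx(1.0, abs=1e-10)
        assert np.sum(np.abs(S) > 1e-10) == 1

    def test_L_zero_gives_zero_code(self, rng):
        D = unit_dictionary(rng, 8, 5)
        y = rng.standard_normal((8, 3))
        S = omp_sparse_code(y, D, 0)
        assert np.allclose(S, 0.0)

    def test_L1_matches_exhaustive_single_atom(self, rng):
        """Greedy OMP is optimal at L=1: equals the best single-atom residual."""
        for _ in range(100):
            D = unit_dictionary(rng, 6, 10)
            y = rng.standard_normal((6, 1))
            S = omp_sparse_code(y, D, 1)
            omp_res = float(np.linalg.norm(y[:, 0] - D @ S[:, 0]))
            assert omp_res == pytest.approx(best_single_atom_residual(y[:, 0], D), abs=1e-10)

    def test_residual_nonincreasing_in_L(self, rng):
        D = unit_dictionary(rng, 12, 20)
        Y = rng.standard_normal((12, 30))
        prev = np.full(30, np.inf)
        for L in range(1, 5):
            S = omp_sparse_code(Y, D, L)
            res = np.linalg.norm(Y - D @ S, axis=0)
            assert np.all(res <= prev + 1e-12)
            assert np.all(np.sum(np.abs(S) > 1e-10, axis=0) <= L)
            prev = res

    def test_L_exceeding_k_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            omp_sparse_code(rng.standard_normal((4, 2)), unit_dictionary(rng, 4, 3), 5)

    def test_zero_atom_rejected(self, rng):
        D = unit_dictionary(rng, 4, 3)
        D[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero atoms"):
            omp_sparse_code(rng.standard_normal((4, 2)), D, 1)


class TestInitDictionary:
    def test_deterministic_given_seed(self, rng):
        Y = rng.standard_normal((10, 40))
        D1, S1 = init_dictionary(Y, 5, 0.1, seed=3)
        D2, S2 = init_dictionary(Y, 5, 0.1, seed=3)
        np.testing.assert_allclose(D1, D2, atol=1e-12)
        np.testing.assert_allclose(S1, S2, atol=1e-12)

    def test_planted_dictionary_reconstruction(self, rng):
        """Noiseless 3-sparse data from k atoms is reconstructed within 20%."""
        d, k, n = 20, 8, 200
        Dt = unit_dictionary(rng, d, k)
        S = np.zeros((k, n))
        for i in range(n):
            sup = rng.choice(k, 3, replace=False)
            S[sup, i] = rng.standard_normal(3)
        Y = Dt @ S
        D0, S0 = init_dictionary(Y, k, 0.1, seed=0, max_iter=30)
        rel = np.linalg.norm(Y - D0 @ S0) / np.linalg.norm(Y)
        assert rel <= 0.2

    def test_atom_norm_bound(self, rng):
        D0, _ = init_dictionary(rng.standard_normal((10, 30)), 6, 0.2, seed=1)
        assert np.all(np.linalg.norm(D0, axis=0) <= 1 + 1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            init_dictionary(np.zeros((4, 0)), 2)


class TestSparsityLevel:
    def test_constant_l0(self, rng):
        S = np.zeros((10, 6))
        for i in range(6):
            S[rng.choice(10, 3, replace=False), i] = 1.0
        assert estimate_sparsity_level(S) == 3

    def test_round_half_up(self):
        S = np.zeros((5, 4))
        for i, l0 in enumerate((1, 2, 3, 4)):  # mean 2.5 -> 3
            S[:l0, i] = 1.0
        assert estimate_sparsity_level(S) == 3

    def test_all_zero_floors_at_one(self):
        assert estimate_sparsity_level(np.zeros((5, 4))) == 1


class TestObjective:
    def test_exact_reconstruction_empty_complement_is_zero(self, rng):
        D = unit_dictionary(rng, 6, 4)
        S = np.zeros((4, 3))
        S[0] = [1.0, 2.0, -1.0]
        Y = D @ S
        obj = dfdl_objective(D, Y, np.zeros((6, 0)), 1, rho=0.7)
        assert obj == pytest.approx(0.0, abs=1e-18)

    def test_matches_exhaustive_support_oracle(self, rng):
        """On instances where greedy attains the exhaustive optimum, the
        objective equals the brute-force best-L-subset evaluation."""

        def exhaustive(y, D, L):
            best = np.inf
            for sup in itertools.combinations(range(D.shape[1]), L):
                A = D[:, sup]
                s, *_ = np.linalg.lstsq(A, y, rcond=None)
                best = min(best, float(np.sum((y - A @ s) ** 2)))
            return best

        rho, L = 0.3, 2
        checked = 0
        for _ in range(40):
            D = unit_dictionary(rng, 4, 3)
            Y = rng.standard_normal((4, 5))
            Yb = rng.standard_normal((4, 5))
            S = omp_sparse_code(Y, D, L)
            Sb = omp_sparse_code(Yb, D, L)
            omp_in = float(np.sum((Y - D @ S) ** 2))
            omp_out = float(np.sum((Yb - D @ Sb) ** 2))
            ex_in = sum(exhaustive(Y[:, i], D, L) for i in range(5))
            ex_out = sum(exhaustive(Yb[:, i], D, L) for i in range(5))
            if abs(omp_in - ex_in) < 1e-9 and abs(omp_out - ex_out) < 1e-9:
                obj = dfdl_objective(D, Y, Yb, L, rho)
                assert obj == pytest.approx(ex_in / 5 - rho * ex_out / 5, abs=1e-9)
                checked += 1
        assert checked >= 5  # greedy matches exhaustive often enough to test

    def test_objective_decreases_in_rho(self, rng):
        D = unit_dictionary(rng, 6, 4)
        Y = rng.standard_normal((6, 5))
        Yb = rng.standard_normal((6, 5))
        assert dfdl_objective(D, Y, Yb, 2, 0.5) < dfdl_objective(D, Y, Yb, 2, 0.1)


class TestUpdateDictionary:
    def _instance(self, rng, d=8, k=5, n=20, nbar=30):
        D = unit_dictionary(rng, d, k)
        Y = rng.standard_normal((d, n))
        Yb = rng.standard_normal((d, nbar))
        S = omp_sparse_code(Y, D, 2)
        Sb = omp_sparse_code(Yb, D, 2)
        return D, Y, Yb, S, Sb

    def test_norm_bound_after_update(self, rng):
        D, Y, Yb, S, Sb = self._instance(rng)
        out = update_dictionary(D, Y, Yb, S, Sb, rho=0.1)
        assert np.all(np.linalg.norm(out, axis=0) <= 1 + 1e-9)

    def test_rho_zero_unconstrained_stationarity(self, rng):
        """With rho=0 and inactive norm constraints, D R = P (normal equations)."""
        d, k, n = 8, 4, 50
        # exact factorization Y = D_true S with ||d_j|| = 0.7: the
        # unconstrained minimizer P R^{-1} is D_true, inside the unit ball
        D_true = 0.7 * unit_dictionary(rng, d, k)
        S = rng.standard_normal((k, n))
        Y = D_true @ S
        D = unit_dictionary(rng, d, k)
        empty = np.zeros((d, 0))
        out = update_dictionary(D, Y, empty, S, np.zeros((k, 0)), rho=0.0, max_sweeps=1000, tol=1e-14)
        P, R = update_matrices(Y, empty, S, np.zeros((k, 0)), 0.0)
        assert np.all(np.linalg.norm(out, axis=0) < 1.0 - 1e-6)  # constraints inactive
        np.testing.assert_allclose(out @ R, P, atol=1e-6)
        np.testing.assert_allclose(out, P @ np.linalg.inv(R), atol=1e-5)

    def test_quadratic_never_increases(self, rng):
        for _ in range(100):
            D, Y, Yb, S, Sb = self._instance(rng)
            P, R = update_matrices(Y, Yb, S, Sb, 0.1)
            before = quadratic_objective(D, P, R)
            out = update_dictionary(D, Y, Yb, S, Sb, rho=0.1)
            after = quadratic_objective(out, P, R)
            assert after <= before + 1e-10

    def test_nonfinite_input_rejected(self, rng):
        D, Y, Yb, S, Sb = self._instance(rng)
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            update_dictionary(D, Y, Yb, S, Sb, 0.1)


def planted_two_class(rng, d=24, k=6, n=120, noise=0.02):
    """Disjoint planted atom sets, 2-sparse codes, mild noise."""
    Xs, ys, dicts = [], [], []
    for cls in (1, 2):
        Dc = unit_dictionary(rng, d, k)
        dicts.append(Dc)
        S = np.zeros((k, n))
        for i in range(n):
            sup = rng.choice(k, 2, replace=False)
            S[sup, i] = 1.0 + 0.3 * rng.standard_normal(2)
        Y = Dc @ S + noise * rng.standard_normal((d, n))
        Y /= np.linalg.norm(Y, axis=0)
        Xs.append(Y.T)
        ys.append(np.full(n, cls))
    return np.vstack(Xs), np.concatenate(ys), dicts


class TestTraining:
    def test_planted_two_class_discrimination(self, rng):
        X, y, _ = planted_two_class(rng)
        tr = np.arange(len(y)) % 4 != 0
        clf = DfdlClassifier(
            k_per_class=6, L_override=2, max_outer_iters=5, random_state=0
        ).fit(X[tr], y[tr])
        Xh, yh = X[~tr], y[~tr]
        for i, cls in enumerate(clf.classes_):
            D = clf.dictionaries_[i].atoms
            L = clf.dictionaries_[i].L
            own = Xh[yh == cls].T
            other = Xh[yh != cls].T
            r_own = np.linalg.norm(own - D @ omp_sparse_code(own, D, L), axis=0).mean()
            r_other = np.linalg.norm(other - D @ omp_sparse_code(other, D, L), axis=0).mean()
            assert r_own < r_other

    def test_objective_traces_nonincreasing(self, rng):
        X, y, _ = planted_two_class(rng, n=60)
        clf = DfdlClassifier(k_per_class=6, max_outer_iters=6, random_state=1).fit(X, y)
        for trace in clf.objective_traces_:
            diffs = np.diff(trace)
            assert np.all(diffs <= 1e-6)

    def test_zero_outer_iters_returns_initialization(self, rng):
        X, y, _ = planted_two_class(rng, n=40)
        clf = DfdlClassifier(k_per_class=6, max_outer_iters=0, random_state=5).fit(X, y)
        seeds = np.random.SeedSequence(5).generate_state(2)
        for i, cd in enumerate(clf.dictionaries_):
            D0, _ = init_dictionary(
                X[y == clf.classes_[i]].T, 6, clf.lambda_init, int(seeds[i]) % (2**31),
                clf.init_max_iter,
            )
            np.testing.assert_allclose(cd.atoms, D0, atol=1e-12)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="2 classes"):
            DfdlClassifier().fit(X, np.ones(10))

    def test_rho_zero_with_override_matches_plain_alternation(self, rng):
        """With rho=0 the complementary term vanishes: training on (Y, Ybar)
        gives the same in-class objective trace as alternating coding/update
        on Y alone."""
        X, y, _ = planted_two_class(rng, n=50)
        clf = DfdlClassifier(
            k_per_class=6, L_override=2, rho=1e-12, max_outer_iters=4, random_state=2
        ).fit(X, y)
        cls = clf.classes_[0]
        seeds = np.random.SeedSequence(2).generate_state(2)
        Y = X[y == cls].T
        D, _ = init_dictionary(Y, 6, clf.lambda_init, int(seeds[0]) % (2**31), clf.init_max_iter)
        empty = np.zeros((Y.shape[0], 0))
        trace = [dfdl_objective(D, Y, empty, 2, 0.0)]
        for _ in range(4):
            S = omp_sparse_code(Y, D, 2)
            D = update_dictionary(D, Y, empty, S, np.zeros((6, 0)), 0.0)
            trace.append(dfdl_objective(D, Y, empty, 2, 0.0))
        np.testing.assert_allclose(clf.objective_traces_[0], trace[: len(clf.objective_traces_[0])], atol=1e-6)


class TestClassification:
    def _orthogonal_model(self):
        """Two classes with dictionaries in orthogonal coordinate subspaces."""
        d = 8
        model = DfdlClassifier(gamma=1e-4)
        model.classes_ = np.array([1, 2])
        model.n_features_in_ = d
        from myodict.dfdl import ClassDictionary

        D1 = np.eye(d)[:, :3]
        D2 = np.eye(d)[:, 3:6]
        model.dictionaries_ = [ClassDictionary(D1, 1, 1), ClassDictionary(D2, 2, 1)]
        model.objective_traces_ = [[], []]
        return model

    def test_atom_of_class_two_classified_as_two(self):
        model = self._orthogonal_model()
        y = np.zeros(8)
        y[4] = 1.0  # an atom of D2, orthogonal to D1's span
        res = classify_window(y, model)
        assert res.predicted_class == 2
        assert res.residuals[1] <= 1e-3
        assert res.residuals[1] < res.residuals[0]

    def test_all_residuals_equal_ties_to_first_class(self):
        model = self._orthogonal_model()
        y = np.zeros(8)
        y[7] = 1.0  # orthogonal to every atom of both dictionaries
        res = classify_window(y, model)
        assert res.residuals[0] == pytest.approx(res.residuals[1], abs=1e-12)
        assert res.predicted_class == 1

    def test_dimension_mismatch_rejected(self):
        model = self._orthogonal_model()
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((1, 5)))

    def test_end_to_end_planted_accuracy(self, rng):
        X, y, _ = planted_two_class(rng, n=100)
        tr = np.arange(len(y)) % 5 != 0
        clf = DfdlClassifier(k_per_class=6, L_override=2, random_state=3).fit(X[tr], y[tr])
        assert clf.score(X[~tr], y[~tr]) >= 0.95


class TestAggregateTrial:
    def test_unanimous(self):
        assert aggregate_trial([5, 5, 5]) == 5

    def test_majority(self):
        assert aggregate_trial([1, 1, 2]) == 1

    def test_tie_goes_to_lowest_class(self):
        assert aggregate_trial([1, 3, 3, 1]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_trial([])


def test_model_roundtrip_preserves_decisions(tmp_path, rng):
    X, y, _ = planted_two_class(rng, n=40)
    clf = DfdlClassifier(k_per_class=6, L_override=2, random_state=7).fit(X, y)
    save_model(clf, tmp_path / "model.json")
    back = load_model(tmp_path / "model.json")
    probe = rng.standard_normal((20, X.shape[1]))
    np.testing.assert_array_equal(clf.predict(probe), back.predict(probe))
    for a, b in zip(clf.dictionaries_, back.dictionaries_):
        assert np.array_equal(a.atoms, b.atoms)


def test_sklearn_clone_compatible():
    from sklearn.base import clone

    clf = DfdlClassifier(k_per_class=9, rho=0.2)
    cloned = clone(clf)
    assert cloned.get_params() == clf.get_params()
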