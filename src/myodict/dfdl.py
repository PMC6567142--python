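"""Discriminative feature-oriented dictionary learning (DFDL).

One dictionary D_i (d x k_i, atoms bounded to unit l2 norm) is learned per
gesture class so that in-class feature windows Y_i are reconstructed well by
L-sparse codes while complementary-class windows Ybar_i are reconstructed
poorly.  The per-class training objective is the signed, size-normalized
difference of sparse-coding residuals

    f(D) = (1/N)  min_{|S|_0 <= L}    ||Y  - D S||_F^2
         - (rho/Nbar) min_{|Sbar|_0 <= L} ||Ybar - D Sbar||_F^2

minimized by alternating (a) joint orthogonal-matching-pursuit coding of
[Y, Ybar] and (b) a dictionary update that minimizes the fixed-code quadratic
-2 tr(P D^T) + tr(D R D^T) with

    P = (1/N) Y S^T - (rho/Nbar) Ybar Sbar^T
    R = (1/N) S S^T - (rho/Nbar) Sbar Sbar^T

by block coordinate descent over atoms with projection onto the unit ball.
Because R can be indefinite (the discriminative term enters with a minus
sign), two safeguards keep the procedure monotone: a column update that
would increase the quadratic is rejected, and an outer iteration whose
freshly evaluated objective f(D) increases is rejected, terminating training
for that class at the previous dictionary.

The sparsity level L is estimated from an unsupervised initialization
(online dictionary learning with an l1 penalty lambda): L is the mean
l0-norm of the initial codes, rounded half-up and floored at 1.

Classification of a window y codes it against the concatenation of all class
dictionaries D_t = [D_1, ..., D_C] by l1-regularized least squares
(weight gamma) and assigns the class whose block minimizes the
reconstruction residual r_i(y) = ||y - D_i delta_i(s)||_2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import MiniBatchDictionaryLearning
from sklearn.linear_model import Lasso
from sklearn.utils.validation import check_is_fitted

SUPPORT_EPS = 1e-10  # numerical zero for support counting
_DIAG_EPS = 1e-10  # R_jj below this: atom left unchanged in the sweep


# ---------------------------------------------------------------------------
# sparse coding


def omp_sparse_code(Y: np.ndarray, D: np.ndarray, L: int) -> np.ndarray:
    """Batch orthogonal matching pursuit: codes S with per-column support <= L.

    Greedy atom selection by maximal normalized correlation with the current
    residual, followed by a least-squares refit on the selected support;
    stops early when the residual norm falls below 1e-12.  Runs on the Gram
    matrix, so per-column work is O(L * k) after two matmuls.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    D = np.asarray(D, dtype=float)
    d, k = D.shape
    if L > k:
        raise ValueError(f"sparsity level L={L} exceeds dictionary size k={k}")
    norms = np.linalg.norm(D, axis=0)
    if np.any(norms == 0):
        raise ValueError("dictionary contains all-zero atoms")
    n = Y.shape[1]
    S = np.zeros((k, n))
    if L == 0 or n == 0:
        return S
    G = D.T @ D
    DtY = D.T @ Y
    yty = np.sum(Y * Y, axis=0)
    support = np.zeros((L, n), dtype=int)
    active = np.ones(n, dtype=bool)
    for it in range(L):
        GS = G @ S
        resid_sq = yty - 2.0 * np.sum(S * DtY, axis=0) + np.sum(S * GS, axis=0)
        active &= resid_sq > 1e-24
        if not np.any(active):
            break
        cols = np.flatnonzero(active)
        corr = np.abs(DtY[:, cols] - GS[:, cols]) / norms[:, None]
        if it > 0:  # already-selected atoms are ineligible
            corr[support[:it, cols], np.arange(cols.size)[None, :]] = -np.inf
        support[it, cols] = np.argmax(corr, axis=0)
        # least-squares refit on each column's support, batched over columns
        sub = support[: it + 1, cols].T  # (n_active, t)
        Gs = G[sub[:, :, None], sub[:, None, :]]
        b = DtY[sub, cols[:, None]]
        try:
            s_sub = np.linalg.solve(Gs, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            s_sub = np.stack(
                [np.linalg.lstsq(Gs[i], b[i], rcond=None)[0] for i in range(len(cols))]
            )
        S[:, cols] = 0.0
        S[sub.T, cols[None, :]] = s_sub.T
    return S


def estimate_sparsity_level(S0: np.ndarray) -> int:
    """L = mean per-column l0 norm of the initial codes, rounded half-up, >= 1."""
    S0 = np.atleast_2d(np.asarray(S0))
    if S0.shape[1] == 0:
        raise ValueError("S0 must be non-empty")
    l0 = np.sum(np.abs(S0) > SUPPORT_EPS, axis=0)
    return max(1, int(np.floor(np.mean(l0) + 0.5)))


def init_dictionary(
    Y: np.ndarray, k: int, lambda_init: float = 0.2, seed: int = 0, max_iter: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Unsupervised initialization (D0, S0) by online dictionary learning.

    Approximately minimizes ||Y - D S||_F^2 + lambda ||S||_1 with unit-norm
    atoms; the l1 weight is halved when handed to scikit-learn, whose
    objective carries a 1/2 on the quadratic term.  Deterministic given seed.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    d, n = Y.shape
    if n == 0:
        raise ValueError("cannot initialize a dictionary from an empty sample matrix")
    if n < k:
        warnings.warn(f"class has {n} samples but k={k} atoms; dictionary is undercomplete in data")
    learner = MiniBatchDictionaryLearning(
        n_components=k,
        alpha=lambda_init / 2.0,
        max_iter=max_iter,
        batch_size=min(256, max(8, n // 2)),
        transform_algorithm="lasso_cd",
        transform_alpha=lambda_init / 2.0,
        transform_max_iter=2000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lasso_cd convergence chatter at loose alpha
        S0 = learner.fit_transform(Y.T).T
        D0 = learner.components_.T.copy()
    # sklearn returns unit (or zero) rows; enforce the <=1 norm contract
    norms = np.linalg.norm(D0, axis=0)
    over = norms > 1.0
    D0[:, over] /= norms[over]
    return D0, S0


# ---------------------------------------------------------------------------
# dictionary update


def update_matrices(
    Y: np.ndarray, Ybar: np.ndarray, S: np.ndarray, Sbar: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """P and R of the fixed-code quadratic -2 tr(P D^T) + tr(D R D^T)."""
    n = Y.shape[1]
    nbar = Ybar.shape[1]
    P = Y @ S.T / n
    R = S @ S.T / n
    if nbar > 0:
        P = P - (rho / nbar) * (Ybar @ Sbar.T)
        R = R - (rho / nbar) * (Sbar @ Sbar.T)
    R = (R + R.T) / 2.0
    return P, R


def quadratic_objective(D: np.ndarray, P: np.ndarray, R: np.ndarray) -> float:
    return float(-2.0 * np.sum(P * D) + np.sum((D @ R) * D))


def update_dictionary(
    D: np.ndarray,
    Y: np.ndarray,
    Ybar: np.ndarray,
    S: np.ndarray,
    Sbar: np.ndarray,
    rho: float,
    tol: float = 1e-8,
    max_sweeps: int = 100,
) -> np.ndarray:
    """Minimize the fixed-code quadratic over atoms with ||d_j||_2 <= 1.

    Block coordinate descent: d_j <- (p_j - sum_{l != j} d_l R_lj) / R_jj,
    projected onto the unit ball.  Columns with R_jj <= eps are skipped for
    the sweep, and any column move that would increase the quadratic is
    rejected (R may be indefinite), so the objective never increases.
    """
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(S)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite inputs to dictionary update")
    D = np.array(D, dtype=float)
    P, R = update_matrices(Y, Ybar, S, Sbar, rho)
    k = D.shape[1]
    obj = quadratic_objective(D, P, R)
    for _ in range(max_sweeps):
        prev = obj
        for j in range(k):
            rjj = R[j, j]
            if rjj <= _DIAG_EPS:
                continue
            # residual excluding atom j's own contribution
            g = P[:, j] - D @ R[:, j] + D[:, j] * rjj
            d_new = g / rjj
            nrm = np.linalg.norm(d_new)
            if nrm > 1.0:
                d_new = d_new / nrm
            # exact change of the quadratic for replacing column j
            delta = d_new - D[:, j]
            change = rjj * (delta @ delta) + 2.0 * delta @ (D @ R[:, j] - P[:, j])
            if change < 0.0:
                D[:, j] = d_new
                obj += change
        if prev - obj < tol:
            break
    return D


# ---------------------------------------------------------------------------
# objective


def dfdl_objective(
    D: np.ndarray, Y: np.ndarray, Ybar: np.ndarray, L: int, rho: float
) -> float:
    """Signed discriminative objective with OMP inner sparse coding."""
    S = omp_sparse_code(Y, D, L)
    val = float(np.sum((Y - D @ S) ** 2)) / Y.shape[1]
    if Ybar is not None and Ybar.shape[1] > 0:
        Sbar = omp_sparse_code(Ybar, D, L)
        val -= rho * float(np.sum((Ybar - D @ Sbar) ** 2)) / Ybar.shape[1]
    return val


# ---------------------------------------------------------------------------
# model containers


@dataclass
class ClassDictionary:
    atoms: np.ndarray  # d x k_i
    class_label: int
    L: int


@dataclass
class ClassificationResult:
    residuals: np.ndarray  # length C, ordered by ascending class label
    predicted_class: int
    code: np.ndarray


@dataclass
class DfdlHyperparams:
    """Bag of DFDL knobs mirroring DfdlClassifier's constructor."""

    k_per_class: int = 40
    rho: float = 0.05
    lambda_init: float = 0.2
    gamma: float = 0.01
    max_outer_iters: int = 10
    objective_tol: float = 1e-6
    L_override: int | None = None
    init_max_iter: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rho, self.lambda_init, self.gamma) <= 0:
            raise ValueError("rho, lambda_init and gamma must be positive")
        if self.k_per_class < 1 or self.max_outer_iters < 0:
            raise ValueError("k_per_class >= 1 and max_outer_iters >= 0 required")

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


class DfdlClassifier(ClassifierMixin, BaseEstimator):
    """Sparse-representation gesture classifier with per-class dictionaries.

    scikit-learn estimator API: ``fit(X, y)`` with X of shape
    (n_windows, d) — feature rows as produced by WaveletPacketFeaturizer —
    and ``predict`` returning the residual-argmin class.  Ties in the
    residual argmin go to the lowest class label.

    Parameters
    ----------
    k_per_class : atoms per class dictionary.
    rho : weight of the complementary (discriminative) residual term.
    lambda_init : l1 weight of the online-dictionary-learning initialization.
    gamma : l1 weight of the classification-time sparse coder.
    max_outer_iters : alternations of joint coding and dictionary update.
    objective_tol : stop when the per-class objective improves by less.
    L_override : fixed sparsity level; otherwise estimated from the
        initialization codes.
    init_max_iter : epochs of the online initialization.
    random_state : master seed; one child stream per class.

    Attributes
    ----------
    classes_ : sorted class labels.
    dictionaries_ : list of ClassDictionary, aligned with classes_.
    objective_traces_ : per-class list of accepted objective values.
    n_features_in_ : feature dimension d.
    """

    def __init__(
        self,
        k_per_class: int = 40,
        rho: float = 0.05,
        lambda_init: float = 0.2,
        gamma: float = 0.01,
        max_outer_iters: int = 10,
        objective_tol: float = 1e-6,
        L_override: int | None = None,
        init_max_iter: int = 5,
        random_state: int = 0,
    ):
        self.k_per_class = k_per_class
        self.rho = rho
        self.lambda_init = lambda_init
        self.gamma = gamma
        self.max_outer_iters = max_outer_iters
        self.objective_tol = objective_tol
        self.L_override = L_override
        self.init_max_iter = init_max_iter
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_windows, d) with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError(
                "DFDL needs at least 2 classes: the complementary sample set "
                "of a single class would be empty"
            )
        self.n_features_in_ = X.shape[1]
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.classes_.size)
        self.dictionaries_ = []
        self.objective_traces_ = []
        for idx, cls in enumerate(self.classes_):
            mask = y == cls
            Y = X[mask].T
            Ybar = X[~mask].T
            if Y.shape[1] < self.k_per_class:
                warnings.warn(
                    f"class {cls}: {Y.shape[1]} windows < k_per_class={self.k_per_class}"
                )
            D, L, trace = self._fit_one_class(Y, Ybar, int(seeds[idx]) % (2**31))
            self.dictionaries_.append(ClassDictionary(atoms=D, class_label=cls, L=L))
            self.objective_traces_.append(trace)
        return self

    def _fit_one_class(
        self, Y: np.ndarray, Ybar: np.ndarray, seed: int
    ) -> tuple[np.ndarray, int, list[float]]:
        k = min(self.k_per_class, Y.shape[1])
        D, S0 = init_dictionary(Y, k, self.lambda_init, seed, self.init_max_iter)
        L = self.L_override if self.L_override is not None else estimate_sparsity_level(S0)
        L = min(L, D.shape[1])
        Yhat = np.concatenate([Y, Ybar], axis=1)
        n = Y.shape[1]

        def code_and_value(Dcur):
            # joint OMP coding of [Y, Ybar]; its codes also give the objective
            S_hat = omp_sparse_code(Yhat, Dcur, L)
            S, Sbar = S_hat[:, :n], S_hat[:, n:]
            val = float(np.sum((Y - Dcur @ S) ** 2)) / n
            if Ybar.shape[1] > 0:
                val -= self.rho * float(np.sum((Ybar - Dcur @ Sbar) ** 2)) / Ybar.shape[1]
            return S, Sbar, val

        S, Sbar, obj = code_and_value(D)
        trace = [obj]
        for _ in range(self.max_outer_iters):
            D_cand = update_dictionary(D, Y, Ybar, S, Sbar, self.rho)
            S_cand, Sbar_cand, obj_cand = code_and_value(D_cand)
            if obj_cand > trace[-1] + 1e-12:
                break  # monotone acceptance: keep the previous dictionary
            improved = trace[-1] - obj_cand
            D, S, Sbar = D_cand, S_cand, Sbar_cand
            trace.append(obj_cand)
            if improved < self.objective_tol:
                break
        return D, L, trace

    # -- prediction --------------------------------------------------------

    def _joint_dictionary(self) -> tuple[np.ndarray, list[slice]]:
        check_is_fitted(self, "dictionaries_")
        blocks = [cd.atoms for cd in self.dictionaries_]
        offsets = np.cumsum([0] + [b.shape[1] for b in blocks])
        slices = [slice(offsets[i], offsets[i + 1]) for i in range(len(blocks))]
        return np.concatenate(blocks, axis=1), slices

    def sparse_codes(self, X) -> np.ndarray:
        """l1-regularized codes of each row of X against D_t = [D_1 .. D_C]."""
        Dt, _ = self._joint_dictionary()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        d = Dt.shape[0]
        lasso = Lasso(
            alpha=self.gamma / (2.0 * d),
            fit_intercept=False,
            tol=1e-7,
            max_iter=50_000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso.fit(Dt, X.T)
        codes = np.atleast_2d(lasso.coef_)
        return codes  # (n_windows, k_total)

    def reconstruction_residuals(self, X) -> np.ndarray:
        """r_i(y) = ||y - D_i delta_i(s)||_2 for every window and class."""
        Dt, slices = self._joint_dictionary()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        codes = self.sparse_codes(X)
        res = np.empty((X.shape[0], len(slices)))
        for i, sl in enumerate(slices):
            recon = codes[:, sl] @ self.dictionaries_[i].atoms.T
            res[:, i] = np.linalg.norm(X - recon, axis=1)
        return res

    def predict(self, X):
        res = self.reconstruction_residuals(X)
        return self.classes_[np.argmin(res, axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers


def train_dfdl(features, hyperparams: DfdlHyperparams | None = None) -> DfdlClassifier:
    """Fit a DfdlClassifier on a FeatureMatrix (columns = windows)."""
    if hyperparams is None:
        hyperparams = DfdlHyperparams()
    clf = DfdlClassifier(
        k_per_class=hyperparams.k_per_class,
        rho=hyperparams.rho,
        lambda_init=hyperparams.lambda_init,
        gamma=hyperparams.gamma,
        max_outer_iters=hyperparams.max_outer_iters,
        objective_tol=hyperparams.objective_tol,
        L_override=hyperparams.L_override,
        init_max_iter=hyperparams.init_max_iter,
        random_state=hyperparams.seed,
    )
    return clf.fit(features.values.T, features.labels)


def classify_window(
    y: np.ndarray, model: DfdlClassifier, gamma: float | None = None
) -> ClassificationResult:
    """Classify one feature column; ties go to the lowest class label."""
    y = np.asarray(y, dtype=float).ravel()
    if gamma is not None and gamma != model.gamma:
        model = clone_with_gamma(model, gamma)
    codes = model.sparse_codes(y[None, :])
    res = model.reconstruction_residuals(y[None, :])[0]
    pred = model.classes_[int(np.argmin(res))]
    return ClassificationResult(residuals=res, predicted_class=pred, code=codes[0])


def clone_with_gamma(model: DfdlClassifier, gamma: float) -> DfdlClassifier:
    out = DfdlClassifier(**{**model.get_params(), "gamma": gamma})
    for attr in ("classes_", "dictionaries_", "objective_traces_", "n_features_in_"):
        setattr(out, attr, getattr(model, attr))
    return out


def aggregate_trial(window_results: list) -> int:
    """Majority vote over window predictions; ties to the lowest class label."""
    if not window_results:
        raise ValueError("cannot aggregate an empty list of window results")
    preds = [
        r.predicted_class if isinstance(r, ClassificationResult) else int(r)
        for r in window_results
    ]
    labels, counts = np.unique(preds, return_counts=True)
    return int(labels[np.argmax(counts)])


# ---------------------------------------------------------------------------
# serialization


def save_model(model: DfdlClassifier, path: str | Path) -> None:
    """JSON archive of dictionaries, hyperparameters and objective traces.

    Floats are serialized via repr, so reloaded dictionaries are bitwise
    identical and classification decisions are preserved exactly.
    """
    check_is_fitted(model, "dictionaries_")
    payload = {
        "params": model.get_params(),
        "classes": [int(c) for c in model.classes_],
        "n_features_in": int(model.n_features_in_),
        "dictionaries": [
            {"class_label": int(cd.class_label), "L": int(cd.L), "atoms": cd.atoms.tolist()}
            for cd in model.dictionaries_
        ],
        "objective_traces": [[float(v) for v in t] for t in model.objective_traces_],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> DfdlClassifier:
    payload = json.loads(Path(path).read_text())
    model = DfdlClassifier(**payload["params"])
    model.classes_ = np.array(payload["classes"])
    model.n_features_in_ = payload["n_features_in"]
    model.dictionaries_ = [
        ClassDictionary(
            atoms=np.array(d["atoms"], dtype=float), class_label=d["class_label"], L=d["L"]
        )
        for d in payload["dictionaries"]
    ]
    model.objective_traces_ = payload["objective_traces"]
    return model
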