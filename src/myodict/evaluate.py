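"""Trial-wise cross-validation, channel-subset search and comparison stats.

Cross-validation follows the recording protocol: folds partition *trials*
(never windows), so with 10 trials per gesture and 10 folds each test fold
holds exactly one held-out trial per gesture and training uses the other
nine.  Feature assembly, including per-window normalization, happens
independently per fold, so no test information leaks into training.

The channel-subset search evaluates every non-empty electrode subset
(2^n - 1 of them) with the same cross-validation plan and reports the best
subset of each cardinality; per-channel wavelet-packet blocks are computed
once per trial and re-assembled per subset, which keeps the exhaustive
search tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .features import FeatureConfig, _wpt_leaf_batch
from .preprocess import WindowSpec, apply_notch, segment_trial
from .synth import EmgRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CrossvalPlan:
    """Maps (gesture_label, trial_id) to a fold index in 0..n_folds-1."""

    n_folds: int
    assignment: dict[tuple[int, int], int]
    seed: int = 0

    def test_trials(self, fold: int) -> set[tuple[int, int]]:
        return {key for key, f in self.assignment.items() if f == fold}


def make_crossval_plan(
    dataset: list[EmgRecording], n_folds: int = 10, seed: int = 0
) -> CrossvalPlan:
    """Deal each class's trials (seeded shuffle) round-robin into folds."""
    by_class: dict[int, list[int]] = {}
    for rec in dataset:
        by_class.setdefault(rec.gesture_label, []).append(rec.trial_id)
    rng = np.random.default_rng(seed)
    assignment: dict[tuple[int, int], int] = {}
    for label in sorted(by_class):
        trials = sorted(by_class[label])
        if len(trials) < n_folds:
            raise ValueError(
                f"class {label} has {len(trials)} trials, fewer than {n_folds} folds"
            )
        order = rng.permutation(len(trials))
        for pos, idx in enumerate(order):
            assignment[(label, trials[idx])] = pos % n_folds
    return CrossvalPlan(n_folds=n_folds, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# per-trial feature blocks (computed once, sliced per channel subset)


@dataclass
class TrialFeatures:
    gesture_label: int
    trial_id: int
    blocks: np.ndarray  # (n_windows, n_channels, block_len), unnormalized


def build_trial_features(
    dataset: list[EmgRecording],
    window_spec: WindowSpec | None = None,
    feature_config: FeatureConfig | None = None,
    notch: bool = True,
) -> list[TrialFeatures]:
    if window_spec is None:
        window_spec = WindowSpec()
    if feature_config is None:
        feature_config = FeatureConfig()
    out = []
    for rec in dataset:
        rec_f = apply_notch(rec) if notch else rec
        ws = segment_trial(rec_f, window_spec)
        if not ws.windows:
            logger.info("trial (%d, %d) produced no windows", rec.gesture_label, rec.trial_id)
            continue
        stack = np.stack(ws.windows)  # (n_w, ch, samples)
        per_channel = []
        for ch in range(stack.shape[1]):
            leaves = _wpt_leaf_batch(stack[:, ch, :], feature_config)
            if feature_config.subband_energy:
                per_channel.append(np.stack([np.sum(lf**2, axis=1) for lf in leaves], axis=1))
            else:
                per_channel.append(np.concatenate(leaves, axis=1))
        out.append(
            TrialFeatures(
                gesture_label=rec.gesture_label,
                trial_id=rec.trial_id,
                blocks=np.stack(per_channel, axis=1),
            )
        )
    return out


def assemble_features(
    trials: list[TrialFeatures], channel_subset: tuple[int, ...], normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trial blocks for a channel subset into (rows X, labels y)."""
    xs, ys = [], []
    for tf in trials:
        block = tf.blocks[:, channel_subset, :].reshape(tf.blocks.shape[0], -1)
        xs.append(block)
        ys.append(np.full(block.shape[0], tf.gesture_label))
    X = np.concatenate(xs, axis=0)
    y = np.concatenate(ys)
    if normalize:
        norms = np.linalg.norm(X, axis=1)
        keep = norms > 0
        X, y, norms = X[keep], y[keep], norms[keep]
        X = X / norms[:, None]
    return X, y


# ---------------------------------------------------------------------------
# confusion matrix with per-class sensitivity/specificity


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # C x C, rows = actual, columns = predicted
    labels: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(np.sum(self.counts))

    @property
    def sensitivity(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    @property
    def specificity(self) -> np.ndarray:
        total = self.counts.sum()
        row = self.counts.sum(axis=1)
        col = self.counts.sum(axis=0)
        tn = total - row - col + np.diag(self.counts)
        with np.errstate(invalid="ignore"):
            return np.where(total - row > 0, tn / (total - row), np.nan)


def confusion_and_stats(actual, predicted, n_classes: int) -> ConfusionMatrix:
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    labels = np.arange(1, n_classes + 1)
    for arr, name in ((actual, "actual"), (predicted, "predicted")):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels out of range 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (actual - 1, predicted - 1), 1)
    return ConfusionMatrix(counts=counts, labels=labels)


# ---------------------------------------------------------------------------
# cross-validated accuracy


@dataclass
class CrossvalResult:
    fold_accuracies: list[float]
    confusions: list[ConfusionMatrix]
    channel_subset: tuple[int, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def crossval_accuracy(
    dataset_or_trials,
    estimator,
    plan: CrossvalPlan,
    channel_subset: tuple[int, ...] | None = None,
    window_spec: WindowSpec | None = None,
    feature_config: FeatureConfig | None = None,
    notch: bool = True,
) -> CrossvalResult:
    """Window-level accuracy per fold for any fit/predict estimator.

    Accepts either raw recordings or a precomputed ``build_trial_features``
    list (used by the subset search to share work across subsets).
    """
    if feature_config is None:
        feature_config = FeatureConfig()
    if dataset_or_trials and isinstance(dataset_or_trials[0], TrialFeatures):
        trials = dataset_or_trials
    else:
        trials = build_trial_features(dataset_or_trials, window_spec, feature_config, notch)
    if channel_subset is None:
        channel_subset = tuple(range(trials[0].blocks.shape[1]))
    labels = sorted({tf.gesture_label for tf in trials})
    n_classes = max(labels)
    fold_accs: list[float] = []
    confusions: list[ConfusionMatrix] = []
    for fold in range(plan.n_folds):
        test_keys = plan.test_trials(fold)
        train = [tf for tf in trials if (tf.gesture_label, tf.trial_id) not in test_keys]
        test = [tf for tf in trials if (tf.gesture_label, tf.trial_id) in test_keys]
        if not train or not test:
            raise ValueError(f"fold {fold}: empty train or test split")
        X_tr, y_tr = assemble_features(train, channel_subset, feature_config.normalize)
        X_te, y_te = assemble_features(test, channel_subset, feature_config.normalize)
        try:
            model = clone(estimator)
        except TypeError:
            model = estimator  # stubs without get_params
        try:
            model.fit(X_tr, y_tr)
            y_hat = np.asarray(model.predict(X_te))
        except Exception as exc:  # noqa: BLE001 - re-raise naming the fold
            raise RuntimeError(f"classifier failed on fold {fold}: {exc}") from exc
        cm = confusion_and_stats(y_te, y_hat, n_classes)
        fold_accs.append(cm.accuracy)
        confusions.append(cm)
    return CrossvalResult(
        fold_accuracies=fold_accs, confusions=confusions, channel_subset=tuple(channel_subset)
    )


# ---------------------------------------------------------------------------
# exhaustive channel-subset search


@dataclass
class SubsetResult:
    subset: tuple[int, ...]
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def channel_subset_search(
    dataset_or_trials,
    estimator,
    plan: CrossvalPlan,
    window_spec: WindowSpec | None = None,
    feature_config: FeatureConfig | None = None,
    notch: bool = True,
    max_channels: int = 8,
    subset_scorer=None,
) -> tuple[list[SubsetResult], dict[int, SubsetResult]]:
    """Evaluate all 2^n - 1 non-empty channel subsets; best per cardinality.

    Ties in mean accuracy go to the lexicographically smallest subset.
    ``subset_scorer`` (subset -> list of fold accuracies) replaces the full
    cross-validation when supplied; used for testing the selection logic.
    """
    if feature_config is None:
        feature_config = FeatureConfig()
    if dataset_or_trials and isinstance(dataset_or_trials[0], TrialFeatures):
        trials = dataset_or_trials
    else:
        trials = build_trial_features(dataset_or_trials, window_spec, feature_config, notch)
    n_channels = trials[0].blocks.shape[1]
    if n_channels > max_channels:
        raise ValueError(
            f"{n_channels} channels would need {2**n_channels - 1} subset evaluations; "
            "pass explicit subsets instead"
        )
    results: list[SubsetResult] = []
    for r in range(1, n_channels + 1):
        for subset in itertools.combinations(range(n_channels), r):
            if subset_scorer is not None:
                accs = list(subset_scorer(subset))
            else:
                accs = crossval_accuracy(
                    trials, estimator, plan, subset, window_spec, feature_config, notch
                ).fold_accuracies
            results.append(SubsetResult(subset=subset, fold_accuracies=accs))
    best: dict[int, SubsetResult] = {}
    for res in results:
        r = len(res.subset)
        cur = best.get(r)
        if (
            cur is None
            or res.mean_accuracy > cur.mean_accuracy + 1e-15
            or (abs(res.mean_accuracy - cur.mean_accuracy) <= 1e-15 and res.subset < cur.subset)
        ):
            best[r] = res
    return results, best


def confusion_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    """C x C counts as a labeled table (rows actual, columns predicted)."""
    idx = [f"actual_{c}" for c in cm.labels]
    cols = [f"predicted_{c}" for c in cm.labels]
    return pd.DataFrame(cm.counts, index=idx, columns=cols)


def subset_results_frame(results: list[SubsetResult]) -> pd.DataFrame:
    """Tidy table: one row per (subset, fold)."""
    rows = [
        {"subset": "+".join(map(str, res.subset)), "cardinality": len(res.subset),
         "fold": f, "accuracy": acc}
        for res in results
        for f, acc in enumerate(res.fold_accuracies)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired comparison


@dataclass
class PairedTTest:
    t: float
    p: float
    degenerate: bool = False


def paired_ttest(acc_a, acc_b) -> PairedTTest:
    """Classic paired t-test on per-dataset (or per-fold) accuracy vectors."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length accuracy vectors with n >= 2")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        return PairedTTest(t=0.0, p=1.0, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTTest(t=float(t), p=float(p))
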