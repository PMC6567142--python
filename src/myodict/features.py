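"""Wavelet-packet feature extraction for sEMG analysis windows.

Each window channel is decomposed with a level-4 wavelet packet transform
(full binary filter bank, 16 terminal sub-bands) and the terminal-node
coefficients are concatenated into one feature vector; channels are then
concatenated in channel order and the column is l2-normalized.  With the
default 4-tap Daubechies wavelet and periodization boundary handling a
100-sample window yields 7 coefficients per node (length chain
100 -> 50 -> 25 -> 13 -> 7), i.e. 112 coefficients per channel and 672 for
six channels.

Terminal nodes are emitted in frequency order: position m holds the node
whose natural (filter-bank) index is the Gray code m ^ (m >> 1), so
coefficient blocks sweep the spectrum from low to high frequency.  The
decomposition is run as batched ``pywt.dwt`` calls over all windows at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import WindowSet

logger = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    wpt_level: int = 4
    wavelet_name: str = "db2"
    boundary_mode: str = "periodization"
    normalize: bool = True
    subband_energy: bool = False

    def __post_init__(self) -> None:
        if self.wpt_level < 1:
            raise ValueError("wpt_level must be >= 1")

    def to_dict(self) -> dict:
        return {
            "wpt_level": self.wpt_level,
            "wavelet_name": self.wavelet_name,
            "boundary_mode": self.boundary_mode,
            "normalize": self.normalize,
            "subband_energy": self.subband_energy,
        }


@dataclass
class FeatureMatrix:
    """Column-per-window feature matrix with aligned gesture labels."""

    values: np.ndarray  # d x N
    labels: np.ndarray  # length N
    channel_subset: tuple[int, ...]
    config: FeatureConfig

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _wpt_leaf_batch(data: np.ndarray, config: FeatureConfig) -> list[np.ndarray]:
    """Level-`wpt_level` packet leaves of a (n_signals, n_samples) batch.

    Returns 2**level arrays of shape (n_signals, leaf_len) in frequency
    order.  The high-pass branch mirrors the spectrum, which is what the
    Gray-code reindexing of the natural filter-bank order corrects for.
    """
    wavelet = pywt.Wavelet(config.wavelet_name)
    nodes = [np.asarray(data, dtype=float)]
    for _ in range(config.wpt_level):
        nxt = []
        for node in nodes:
            a, d = pywt.dwt(node, wavelet, mode=config.boundary_mode, axis=-1)
            nxt.extend((a, d))
        nodes = nxt
    return [nodes[m ^ (m >> 1)] for m in range(len(nodes))]


def wpt_feature_length(n_samples: int, config: FeatureConfig) -> int:
    """Deterministic per-channel feature length for a given window size."""
    probe = np.zeros((1, n_samples))
    leaves = _wpt_leaf_batch(probe, config)
    if config.subband_energy:
        return len(leaves)
    return sum(leaf.shape[1] for leaf in leaves)


def wpt_coefficients(window_channel: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Concatenated terminal-node coefficients of one single-channel window."""
    if config is None:
        config = FeatureConfig()
    x = np.asarray(window_channel, dtype=float).ravel()
    if x.size < 2**config.wpt_level:
        raise ValueError(
            f"window of {x.size} samples is shorter than 2**level = {2**config.wpt_level}"
        )
    leaves = _wpt_leaf_batch(x[None, :], config)
    if config.subband_energy:
        return np.array([float(np.sum(leaf**2)) for leaf in leaves])
    return np.concatenate([leaf[0] for leaf in leaves])


class WaveletPacketFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: window arrays -> wavelet-packet feature rows.

    Input is (n_windows, n_channels, window_samples); output is
    (n_windows, d) with d = len(channel_subset) * per-channel coefficient
    count.  Rows are l2-normalized when ``normalize`` is on, which makes the
    downstream residual classifier invariant to window amplitude.
    """

    def __init__(
        self,
        wpt_level: int = 4,
        wavelet_name: str = "db2",
        boundary_mode: str = "periodization",
        normalize: bool = True,
        subband_energy: bool = False,
        channel_subset: tuple[int, ...] | None = None,
    ):
        self.wpt_level = wpt_level
        self.wavelet_name = wavelet_name
        self.boundary_mode = boundary_mode
        self.normalize = normalize
        self.subband_energy = subband_energy
        self.channel_subset = channel_subset

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            wpt_level=self.wpt_level,
            wavelet_name=self.wavelet_name,
            boundary_mode=self.boundary_mode,
            normalize=self.normalize,
            subband_energy=self.subband_energy,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (n_windows, n_channels, window_samples) input")
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (n_windows, n_channels, window_samples) input")
        n_windows, n_channels, n_samples = X.shape
        subset = (
            tuple(range(n_channels)) if self.channel_subset is None else tuple(self.channel_subset)
        )
        if len(subset) == 0 or any(not 0 <= c < n_channels for c in subset):
            raise ValueError(f"invalid channel subset {subset} for {n_channels} channels")
        config = self._config()
        blocks = []
        for ch in subset:
            leaves = _wpt_leaf_batch(X[:, ch, :], config)
            if config.subband_energy:
                blocks.append(np.stack([np.sum(leaf**2, axis=1) for leaf in leaves], axis=1))
            else:
                blocks.append(np.concatenate(leaves, axis=1))
        feats = np.concatenate(blocks, axis=1)
        if self.normalize:
            norms = np.linalg.norm(feats, axis=1, keepdims=True)
            nonzero = norms[:, 0] > 0
            feats = np.where(norms > 0, feats / np.where(norms > 0, norms, 1.0), feats)
            if not np.all(nonzero):
                logger.info("left %d all-zero windows unnormalized", int(np.sum(~nonzero)))
        return feats


def build_feature_matrix(
    windowsets: list[WindowSet],
    channel_subset: tuple[int, ...] | None = None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Assemble one labeled feature column per window across trials.

    All-zero windows (which cannot be normalized) are dropped with a logged
    count; labels stay aligned to the surviving columns.
    """
    if config is None:
        config = FeatureConfig()
    windows = [w for ws in windowsets for w in ws.windows]
    labels = np.array([ws.gesture_label for ws in windowsets for _ in ws.windows], dtype=int)
    if not windows:
        return FeatureMatrix(
            values=np.zeros((0, 0)),
            labels=labels,
            channel_subset=tuple(channel_subset or ()),
            config=config,
        )
    stack = np.stack(windows)  # (N, ch, samples)
    subset = tuple(range(stack.shape[1])) if channel_subset is None else tuple(channel_subset)
    featurizer = WaveletPacketFeaturizer(
        wpt_level=config.wpt_level,
        wavelet_name=config.wavelet_name,
        boundary_mode=config.boundary_mode,
        normalize=config.normalize,
        subband_energy=config.subband_energy,
        channel_subset=subset,
    )
    feats = featurizer.fit_transform(stack)
    keep = np.linalg.norm(feats, axis=1) > 0
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("dropped %d all-zero feature columns", dropped)
    return FeatureMatrix(
        values=feats[keep].T.copy(),
        labels=labels[keep],
        channel_subset=subset,
        config=config,
    )


def save_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Delimited container: values + labels + config echo; lossless round-trip."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "values.csv", fm.values, delimiter=",", fmt="%.17g")
    np.savetxt(path / "labels.csv", fm.labels, delimiter=",", fmt="%d")
    meta = {"channel_subset": list(fm.channel_subset), "config": fm.config.to_dict(), "d": fm.d}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_feature_matrix(path) -> FeatureMatrix:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    values = np.loadtxt(path / "values.csv", delimiter=",", ndmin=2)
    if meta["d"] == 0:
        values = values.reshape(0, 0)
    labels = np.loadtxt(path / "labels.csv", delimiter=",", dtype=int, ndmin=1)
    return FeatureMatrix(
        values=values,
        labels=labels,
        channel_subset=tuple(meta["channel_subset"]),
        config=FeatureConfig(**meta["config"]),
    )
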