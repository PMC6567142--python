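"""Synthetic surface-EMG dataset generation.

Emulates a cued-gesture recording protocol: multi-channel sEMG sampled at
500 Hz, trials of 5 s contraction followed by 3 s rest, 14 gesture classes,
6 electrode channels.  Each gesture class is given its own spectral band
within the 5-250 Hz analog bandwidth and its own pattern of per-channel
activation gains, so class separability is planted by construction and every
downstream stage (windowing, wavelet features, dictionary learning) can be
exercised without access to human recordings.

The signal model for one trial is

    x[ch, t] = gain[class, ch] * envelope(t) * bandlimited_noise[ch, t]
             + broadband_noise[ch, t] + line_amp * sin(2*pi*60*t + phase[ch])

where ``bandlimited_noise`` is white Gaussian noise band-passed to the
class band with a 4th-order zero-phase Butterworth filter, ``envelope`` is a
trapezoid (linear onset/offset ramps) covering the contraction segment, the
broadband noise floor is scaled to a target SNR in dB, and the 60 Hz term
models power-line interference.  Amplitudes are in arbitrary units; features
are l2-normalized downstream, so no microvolt calibration is attempted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

TARGETED_CHANNEL_LABELS = ("ECRL/B", "EDC", "ECU", "FCR", "FDS", "FCU")


def default_class_bands(n_classes: int, f_lo: float = 10.0, f_hi: float = 240.0) -> list[tuple[float, float]]:
    """Frequency bands tiling [f_lo, f_hi], one per class, with ~50% overlap.

    Band width is 2*(f_hi - f_lo)/(n_classes + 1) so that consecutive bands
    overlap by half their width; a single class gets the full interval.
    """
    if n_classes == 1:
        return [(f_lo, f_hi)]
    width = 2.0 * (f_hi - f_lo) / (n_classes + 1)
    step = width / 2.0
    return [(f_lo + i * step, f_lo + i * step + width) for i in range(n_classes)]


def default_channel_gains(n_classes: int, n_channels: int) -> np.ndarray:
    """Activation-gain matrix with 1-2 dominant channels per class.

    Class i (0-based) activates channel ``i % n_channels`` at gain 1.0 and the
    next channel at 0.6, over a 0.2 background.  When n_classes exceeds
    n_channels the dominant gains of later cycles are shrunk by 0.9 per cycle
    so that no two classes share an identical gain row.
    """
    gains = np.full((n_classes, n_channels), 0.2)
    for i in range(n_classes):
        cycle = i // n_channels
        scale = 0.9**cycle
        gains[i, i % n_channels] = 1.0 * scale
        if n_channels > 1:
            gains[i, (i + 1) % n_channels] = 0.6 * scale
    return gains


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording protocol.

    Defaults mirror the emulated acquisition setup: 14 gestures, 6 channels,
    10 trials per gesture, 500 Hz sampling, 5 s contraction + 3 s rest.
    """

    n_classes: int = 14
    n_channels: int = 6
    n_trials_per_class: int = 10
    sampling_rate: float = 500.0
    active_duration: float = 5.0
    rest_duration: float = 3.0
    class_bands: list[tuple[float, float]] | None = None
    channel_gains: np.ndarray | None = None
    snr_db: float = 15.0
    line_amplitude: float = 0.5
    envelope_ramp: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_bands is None:
            self.class_bands = default_class_bands(self.n_classes)
        if self.channel_gains is None:
            self.channel_gains = default_channel_gains(self.n_classes, self.n_channels)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        self.validate()

    def validate(self) -> None:
        if min(self.n_classes, self.n_channels, self.n_trials_per_class) < 1:
            raise ValueError("n_classes, n_channels and n_trials_per_class must be positive")
        if len(self.class_bands) != self.n_classes:
            raise ValueError("class_bands must have one (f_lo, f_hi) pair per class")
        for lo, hi in self.class_bands:
            if not (5.0 <= lo < hi <= 250.0):
                raise ValueError(f"class band [{lo}, {hi}] must satisfy 5 <= f_lo < f_hi <= 250")
        max_hi = max(hi for _, hi in self.class_bands)
        if self.sampling_rate < 2.0 * max_hi:
            raise ValueError("sampling_rate must be at least twice the highest band edge")
        if self.channel_gains.shape != (self.n_classes, self.n_channels):
            raise ValueError("channel_gains must be n_classes x n_channels")
        if np.any(self.channel_gains < 0):
            raise ValueError("channel_gains must be non-negative")
        rows = {tuple(row) for row in np.round(self.channel_gains, 12)}
        if len(rows) != self.n_classes:
            raise ValueError("channel_gains rows must be distinct between classes")
        if self.envelope_ramp < 0 or 2 * self.envelope_ramp > self.active_duration:
            raise ValueError("envelope_ramp must fit twice within the active segment")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * (self.active_duration + self.rest_duration)))

    @property
    def active_samples(self) -> int:
        return int(round(self.sampling_rate * self.active_duration))

    def channel_labels(self) -> list[str]:
        if self.n_channels == len(TARGETED_CHANNEL_LABELS):
            return list(TARGETED_CHANNEL_LABELS)
        return [f"ch{i + 1}" for i in range(self.n_channels)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_gains"] = self.channel_gains.tolist()
        d["class_bands"] = [list(b) for b in self.class_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if d.get("class_bands") is not None:
            d["class_bands"] = [tuple(b) for b in d["class_bands"]]
        if d.get("channel_gains") is not None:
            d["channel_gains"] = np.asarray(d["channel_gains"], dtype=float)
        return cls(**d)


@dataclass
class EmgRecording:
    """One labeled multi-channel trial: ``samples`` is channels x samples."""

    samples: np.ndarray
    sampling_rate: float
    gesture_label: int
    trial_id: int
    session_id: int = 1
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x samples array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.channel_labels and len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must equal the channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _trapezoid_envelope(n_active: int, n_total: int, ramp_samples: int) -> np.ndarray:
    env = np.zeros(n_total)
    plateau = np.ones(n_active)
    if ramp_samples > 0:
        ramp = np.linspace(0.0, 1.0, ramp_samples, endpoint=False)
        plateau[:ramp_samples] = ramp
        plateau[n_active - ramp_samples:] = ramp[::-1]
    env[:n_active] = plateau
    return env


def generate_trial(
    config: SynthConfig,
    class_label: int,
    trial_id: int,
    rng: np.random.Generator | int | None = None,
) -> EmgRecording:
    """Generate a single cued trial for one gesture class.

    The contraction occupies the first ``active_duration`` seconds, followed
    by rest; rest contains only the broadband noise floor and line
    interference.  Deterministic given the random state.
    """
    if not 1 <= class_label <= config.n_classes:
        raise ValueError(f"class_label {class_label} out of range 1..{config.n_classes}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    fs = config.sampling_rate
    n_total = config.n_samples
    n_active = config.active_samples
    lo, hi = config.class_bands[class_label - 1]
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")

    gains = config.channel_gains[class_label - 1]
    envelope = _trapezoid_envelope(n_active, n_total, int(round(config.envelope_ramp * fs)))

    white = rng.standard_normal((config.n_channels, n_total))
    band = signal.sosfiltfilt(sos, white, axis=1)
    activity = gains[:, None] * band * envelope[None, :]

    # Broadband noise floor scaled so that active-segment signal power over
    # all channels sits snr_db above the noise power; degenerate all-zero
    # gain rows fall back to unit reference power.
    sig_power = float(np.mean(activity[:, :n_active] ** 2))
    ref_power = sig_power if sig_power > 0 else 1.0
    noise_sigma = np.sqrt(ref_power / (10.0 ** (config.snr_db / 10.0)))
    noise = noise_sigma * rng.standard_normal((config.n_channels, n_total))

    sig_rms = np.sqrt(ref_power)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
    t = np.arange(n_total) / fs
    line = (
        config.line_amplitude
        * sig_rms
        * np.sin(2.0 * np.pi * 60.0 * t[None, :] + phases[:, None])
    )

    return EmgRecording(
        samples=activity + noise + line,
        sampling_rate=fs,
        gesture_label=class_label,
        trial_id=trial_id,
        channel_labels=config.channel_labels(),
    )


def generate_dataset(config: SynthConfig) -> list[EmgRecording]:
    """All trials of the protocol: n_classes x n_trials_per_class recordings.

    A master seed fans out through a SeedSequence, one child stream per
    (class, trial), so the dataset is reproducible and any single trial can
    be regenerated independently.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_classes * config.n_trials_per_class)
    out = []
    idx = 0
    for cls in range(1, config.n_classes + 1):
        for trial in range(1, config.n_trials_per_class + 1):
            rng = np.random.default_rng(children[idx])
            out.append(generate_trial(config, cls, trial, rng))
            idx += 1
    return out


def save_dataset(dataset: list[EmgRecording], path: str | Path, config: SynthConfig | None = None) -> None:
    """Write one delimited matrix per trial plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"trials": [], "config": config.to_dict() if config is not None else None}
    for rec in dataset:
        fname = f"trial_c{rec.gesture_label:03d}_t{rec.trial_id:03d}_s{rec.session_id:03d}.csv"
        np.savetxt(path / fname, rec.samples, delimiter=",", fmt="%.17g")
        manifest["trials"].append(
            {
                "file": fname,
                "gesture_label": int(rec.gesture_label),
                "trial_id": int(rec.trial_id),
                "session_id": int(rec.session_id),
                "sampling_rate": float(rec.sampling_rate),
                "channel_labels": list(rec.channel_labels),
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(path: str | Path) -> list[EmgRecording]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    out = []
    for entry in manifest["trials"]:
        samples = np.loadtxt(path / entry["file"], delimiter=",", ndmin=2)
        out.append(
            EmgRecording(
                samples=samples,
                sampling_rate=entry["sampling_rate"],
                gesture_label=entry["gesture_label"],
                trial_id=entry["trial_id"],
                session_id=entry["session_id"],
                channel_labels=entry["channel_labels"],
            )
        )
    return out
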