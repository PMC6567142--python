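"""Power-line removal and segmentation of cued trials into analysis windows.

The notch filter is a 4th-order Butterworth band-stop over 59-61 Hz applied
forward-backward (zero phase).  Windowing follows the recording protocol:
200 ms windows (100 samples at 500 Hz) advanced in 100 ms steps (50 samples,
50% overlap) over the contraction segment only; rest periods carry no gesture
and are discarded.  Set ``step_samples = window_samples`` for non-overlapping
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import EmgRecording

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Segmentation parameters; defaults give 100-sample windows, 50% overlap."""

    window_samples: int = 100
    step_samples: int = 50
    active_start: float = 0.0
    active_duration: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.step_samples <= self.window_samples:
            raise ValueError("require 0 < step_samples <= window_samples")
        if self.active_duration <= 0:
            raise ValueError("active_duration must be positive")


@dataclass
class WindowSet:
    """Windows cut from one trial; all share shape (n_channels, window_samples)."""

    windows: list[np.ndarray]
    gesture_label: int
    trial_id: int
    window_start_indices: list[int]

    def __len__(self) -> int:
        return len(self.windows)


def design_notch(
    sampling_rate: float, stop_band: tuple[float, float] = (59.0, 61.0), order: int = 4
) -> np.ndarray:
    f_lo, f_hi = stop_band
    if f_hi >= sampling_rate / 2.0:
        raise ValueError("stop band must lie below the Nyquist frequency")
    return signal.butter(order, [f_lo, f_hi], btype="bandstop", fs=sampling_rate, output="sos")


def apply_notch(
    recording: EmgRecording, stop_band: tuple[float, float] = (59.0, 61.0)
) -> EmgRecording:
    """Suppress power-line interference with a zero-phase band-stop filter.

    The squared magnitude response of the designed Butterworth band-stop
    (the steady-state equivalent of forward-backward application) is applied
    in the frequency domain.  A recursive realization of a 2 Hz-wide notch
    rings for hundreds of milliseconds and would leave much of a short cued
    trial in transient; the spectral application reaches the design
    attenuation on trial-length records, is exactly zero-phase, and removes
    a coherent line component essentially completely.  The application is
    circular; line interference is coherent across a trial, so wrap-around
    effects are confined to the sub-percent leakage of the notch itself.
    """
    sos = design_notch(recording.sampling_rate, stop_band)
    x = recording.samples
    n = x.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / recording.sampling_rate)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=recording.sampling_rate)
    gain = np.abs(h) ** 2  # |H|^2: the forward-backward magnitude response
    filtered = np.fft.irfft(np.fft.rfft(x, axis=1) * gain[None, :], n=n, axis=1)
    return replace(recording, samples=filtered)


def segment_trial(recording: EmgRecording, spec: WindowSpec | None = None) -> WindowSet:
    """Cut the contraction segment into fully contained overlapping windows.

    Window starts lie on the fixed grid {active_start + j * step}; a trailing
    partial window is discarded.  Returns an empty WindowSet when the active
    segment is shorter than one window.
    """
    if spec is None:
        spec = WindowSpec()
    fs = recording.sampling_rate
    start = int(round(spec.active_start * fs))
    n_active = int(round(spec.active_duration * fs))
    if start < 0 or start + n_active > recording.n_samples:
        raise ValueError("active segment must lie within the recording")

    w, step = spec.window_samples, spec.step_samples
    starts: list[int] = []
    windows: list[np.ndarray] = []
    if n_active >= w:
        n_windows = (n_active - w) // step + 1
        for j in range(n_windows):
            s = start + j * step
            windows.append(recording.samples[:, s : s + w].copy())
            starts.append(s)
    else:
        logger.info(
            "active segment (%d samples) shorter than window (%d): empty WindowSet",
            n_active,
            w,
        )
    return WindowSet(
        windows=windows,
        gesture_label=recording.gesture_label,
        trial_id=recording.trial_id,
        window_start_indices=starts,
    )
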