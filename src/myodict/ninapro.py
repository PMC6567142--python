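"""Adapter for NINAPRO database-3 MAT files (12-channel, 2000 Hz amputee sEMG).

Each file carries an ``emg`` sample matrix plus per-sample movement
annotations: ``stimulus`` (cue label, 0 = rest) — or the refined
``restimulus`` when present — and ``repetition`` indices.  One EmgRecording
is emitted per contiguous non-rest movement segment, labeled with the
stimulus value and the repetition as trial id.  An optional polyphase
resampling step brings the data to a target rate (e.g. 500 Hz).

This module only adapts the external file layout; no bundled data and no
network access are involved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import loadmat

from .synth import EmgRecording

NINAPRO_DB3_RATE = 2000.0


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, stop, label) runs of non-zero annotation values."""
    out = []
    lab = np.asarray(labels).ravel().astype(int)
    boundaries = np.flatnonzero(np.diff(lab) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [lab.size]])
    for s, e in zip(starts, stops):
        if lab[s] != 0:
            out.append((int(s), int(e), int(lab[s])))
    return out


def read_ninapro_db3(
    path: str | Path,
    resample_to: float | None = None,
    use_restimulus: bool = True,
) -> list[EmgRecording]:
    """One EmgRecording per movement repetition in a NINAPRO DB3 MAT file."""
    mat = loadmat(str(path), squeeze_me=False)
    if "emg" not in mat:
        raise ValueError(f"{path}: no 'emg' field; not a NINAPRO-layout MAT file")
    emg = np.asarray(mat["emg"], dtype=float)  # samples x channels
    key = "restimulus" if use_restimulus and "restimulus" in mat else "stimulus"
    if key not in mat:
        raise ValueError(f"{path}: missing stimulus annotation")
    stim = np.asarray(mat[key]).ravel().astype(int)
    rep_key = "rerepetition" if key == "restimulus" and "rerepetition" in mat else "repetition"
    reps = (
        np.asarray(mat[rep_key]).ravel().astype(int)
        if rep_key in mat
        else np.zeros_like(stim)
    )
    if emg.shape[0] != stim.size:
        raise ValueError(f"{path}: emg and {key} lengths disagree")

    recordings = []
    for start, stop, label in _segments(stim):
        samples = emg[start:stop].T  # channels x samples
        rate = NINAPRO_DB3_RATE
        if resample_to is not None and resample_to != rate:
            up, down = (np.array([resample_to, rate]) / np.gcd(int(resample_to), int(rate))).astype(int)
            samples = signal.resample_poly(samples, up, down, axis=1)
            rate = float(resample_to)
        rep_vals = reps[start:stop]
        trial_id = int(rep_vals[rep_vals > 0][0]) if np.any(rep_vals > 0) else len(recordings) + 1
        recordings.append(
            EmgRecording(
                samples=samples,
                sampling_rate=rate,
                gesture_label=label,
                trial_id=trial_id,
                channel_labels=[f"ch{i + 1}" for i in range(samples.shape[0])],
            )
        )
    return recordings
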