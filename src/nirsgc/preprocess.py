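"""Signal conditioning for continuous hemodynamic recordings.

The standard chain is: zero-phase Butterworth bandpass (0.02-0.3 Hz,
4th order) with the post-filter initial value set to zero per channel,
averaging of bidirectional-pathway signal pairs, epoching to [-5, 15) s
around each trial onset, and baseline correction by the [-5, 0) s mean.

Window membership is half-open in sample time: sample ``k`` belongs to a
window ``[a, b)`` iff ``a <= t(k) < b`` with ``t(k) = (k - onset) * dt``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import h5py
import numpy as np
from scipy import signal

from .datasets import ContinuousRecording, TrialDataset

__all__ = [
    "zero_phase_bandpass",
    "bandpass_filter",
    "average_bidirectional",
    "collapse_pathways",
    "epoch_and_baseline",
    "read_snirf",
]

logger = logging.getLogger(__name__)


def _band_sos(low_hz: float, high_hz: float, order: int, dt: float):
    nyquist = 0.5 / dt
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:.3g} Hz)"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / dt, output="sos")


def zero_phase_bandpass(
    x: np.ndarray, dt: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Forward-backward Butterworth bandpass along the last axis.

    The two-pass application squares the magnitude response (effective
    8th-order for the default 4th-order design) and cancels the phase.
    Edge transients are handled by reflective padding scaled to the slow
    cutoff, and the result is symmetrized over time reversal (the mean of
    filtering the signal and of time-reverse-filtering its reverse), so
    zero-phase behaviour holds exactly even at the record edges.  The
    input must be longer than the padding transient.
    """
    sos = _band_sos(low_hz, high_hz, order, dt)
    padlen = max(3 * (2 * order + 1), round(0.5 / (low_hz * dt)))
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"recording of {x.shape[-1]} samples is too short for stable "
            f"zero-phase filtering (needs > {padlen})"
        )
    fwd = signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)
    rev = signal.sosfiltfilt(sos, x[..., ::-1], axis=-1, padtype="even", padlen=padlen)
    return 0.5 * (fwd + rev[..., ::-1])


def bandpass_filter(
    recording: ContinuousRecording,
    low_hz: float = 0.02,
    high_hz: float = 0.3,
    order: int = 4,
    zero_initial: bool = True,
) -> ContinuousRecording:
    """Zero-phase bandpass each channel, then subtract a constant per
    channel so the first sample is exactly zero (``zero_initial``)."""
    out = zero_phase_bandpass(recording.data, recording.dt, low_hz, high_hz, order)
    if zero_initial:
        out = out - out[:, :1]
    return dataclasses.replace(recording, data=out)


def average_bidirectional(path_a: np.ndarray, path_b: np.ndarray) -> np.ndarray:
    """Element-wise mean of the two signals of a bidirectional pathway."""
    path_a = np.asarray(path_a, dtype=float)
    path_b = np.asarray(path_b, dtype=float)
    if path_a.shape != path_b.shape:
        raise ValueError("pathway signals must have equal length")
    return 0.5 * (path_a + path_b)


def collapse_pathways(recording: ContinuousRecording) -> ContinuousRecording:
    """Average rows that share a pathway id into one channel per pathway."""
    if recording.pathway is None:
        return recording
    ids = list(dict.fromkeys(recording.pathway))  # first-appearance order
    rows, names = [], []
    for pid in ids:
        members = [i for i, p in enumerate(recording.pathway) if p == pid]
        if len(members) == 1:
            rows.append(recording.data[members[0]])
        elif len(members) == 2:
            rows.append(average_bidirectional(recording.data[members[0]],
                                              recording.data[members[1]]))
        else:
            raise ValueError(f"pathway {pid!r} has {len(members)} members; expected 1 or 2")
        names.append(str(pid))
    return ContinuousRecording(
        data=np.stack(rows), dt=recording.dt, onsets=recording.onsets,
        channel_names=names, pathway=None,
    )


def window_sample_range(window_s: tuple[float, float], dt: float) -> tuple[int, int]:
    """Half-open onset-relative sample range [k0, k1) for a time window [a, b)."""
    a, b = window_s
    tol = 1e-9
    k0 = math.ceil(a / dt - tol)
    k1 = math.ceil(b / dt - tol)
    return k0, k1


def epoch_and_baseline(
    recording: ContinuousRecording,
    window_s: tuple[float, float] = (-5.0, 15.0),
    baseline_s: tuple[float, float] = (-5.0, 0.0),
    phase: str | None = None,
    hand: str | None = None,
) -> TrialDataset:
    """Epoch around each onset and subtract the baseline-window mean.

    Onsets whose full window would fall outside the recording are skipped
    with a logged warning.  The returned baseline-window mean is zero per
    channel per trial by construction.
    """
    k0, k1 = window_sample_range(window_s, recording.dt)
    b0, b1 = window_sample_range(baseline_s, recording.dt)
    if not (k0 <= b0 < b1 <= k1):
        raise ValueError("baseline window must lie within the epoch window")
    epochs = []
    for onset in recording.onsets:
        lo, hi = onset + k0, onset + k1
        if lo < 0 or hi > recording.n_samples:
            logger.warning(
                "trial at sample %d too close to a recording edge; skipped", onset
            )
            continue
        epochs.append(recording.data[:, lo:hi])
    if not epochs:
        raise ValueError("no trial admits the full epoch window")
    data = np.stack(epochs, axis=2)  # (n, T, R)
    onset_index = -k0
    bsl = data[:, b0 - k0 : b1 - k0, :].mean(axis=1, keepdims=True)
    data = data - bsl
    return TrialDataset(
        data=data,
        dt=recording.dt,
        onset_index=onset_index,
        phase=phase,
        hand=hand,
        channel_names=list(recording.channel_names),
    )


def read_snirf(path) -> ContinuousRecording:
    """Minimal reader for SNIRF-format recordings (HDF5 layout).

    Loads ``/nirs*/data1/dataTimeSeries`` with its time axis and converts
    stimulus onsets (``/nirs*/stim*/data`` first column, seconds) to sample
    indices.  Assumes a uniform sampling grid.
    """
    with h5py.File(path, "r") as fh:
        nirs_keys = sorted(k for k in fh.keys() if k.startswith("nirs"))
        if not nirs_keys:
            raise ValueError("no /nirs group found; not a SNIRF file?")
        nirs = fh[nirs_keys[0]]
        data_grp = nirs["data1"]
        series = np.asarray(data_grp["dataTimeSeries"], dtype=float)  # (T, M)
        time = np.asarray(data_grp["time"], dtype=float).ravel()
        if time.size == 2:  # SNIRF allows [start, dt]
            dt = float(time[1])
        else:
            dt = float(np.median(np.diff(time)))
        onsets_s: list[float] = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = np.atleast_2d(np.asarray(nirs[key]["data"], dtype=float))
            if stim.size:
                onsets_s.extend(stim[:, 0].tolist())
        onsets = np.unique(np.round(np.array(sorted(onsets_s)) / dt).astype(int))
    return ContinuousRecording(data=series.T, dt=dt, onsets=onsets)
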