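"""Raw-trial preprocessing: broadband filter, mains notch, baseline
correction, non-overlapping windowed epoching, reference-channel removal.

The broadband stage is a zero-phase windowed-sinc FIR bandpass (1-50 Hz by
default) applied through MNE's overlap-add filtering; mains interference
is removed with a forward-backward second-order IIR notch (Q=30).  Windows
are non-overlapping: a 30 s stimulation period cut into 5 s windows gives
6 epochs per trial.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from mne.filter import filter_data
from scipy import signal as sp_signal

from .containers import EpochSet, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "bandpass_broadband",
    "notch_mains",
    "baseline_correct",
    "epoch_windows",
    "epoch_recordings",
    "drop_reference",
    "preprocess_recording",
]


def bandpass_broadband(recording: Recording, low: float = 1.0, high: float = 50.0) -> Recording:
    """Zero-phase FIR bandpass; output length equals input length."""
    if high >= recording.fs / 2:
        raise ValueError(f"high edge {high} Hz >= Nyquist ({recording.fs / 2} Hz)")
    filtered = filter_data(
        recording.data,
        sfreq=recording.fs,
        l_freq=low,
        h_freq=high,
        method="fir",
        phase="zero",
        fir_window="hamming",
        fir_design="firwin",
        l_trans_bandwidth=min(low, 0.5),
        h_trans_bandwidth=5.0,
        verbose=False,
    )
    return recording.copy_with(filtered)


def notch_mains(recording: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Forward-backward IIR notch at the mains frequency."""
    if freq >= recording.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist")
    b, a = sp_signal.iirnotch(freq, q, fs=recording.fs)
    return recording.copy_with(sp_signal.filtfilt(b, a, recording.data, axis=-1))


def baseline_correct(recording: Recording, baseline_ms: float = 1000.0) -> Recording:
    """Subtract the per-channel mean of the pre-stimulus baseline."""
    n_base = int(round(baseline_ms * recording.fs / 1000.0))
    if recording.onset_index < n_base:
        raise ValueError(
            f"need {n_base} pre-stimulus samples, have {recording.onset_index}"
        )
    base = recording.data[:, recording.onset_index - n_base : recording.onset_index]
    return recording.copy_with(recording.data - base.mean(axis=1, keepdims=True))


def epoch_windows(
    recording: Recording,
    window_s: float = 5.0,
    span_s: tuple[float, float] = (0.0, 30.0),
) -> EpochSet:
    """Cut non-overlapping windows from the stimulation period.

    ``span_s`` is relative to stimulus onset and must divide evenly into
    windows; labels are propagated to every window.
    """
    fs = recording.fs
    span = span_s[1] - span_s[0]
    n_win = span / window_s
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(f"span {span} s not divisible by window {window_s} s")
    n_win = int(round(n_win))
    w_samp = int(round(window_s * fs))
    start = recording.onset_index + int(round(span_s[0] * fs))
    stop = start + n_win * w_samp
    if stop > recording.n_times:
        raise ValueError("recording shorter than requested span")
    windows = recording.data[:, start:stop].reshape(recording.n_channels, n_win, w_samp)
    epochs = np.transpose(windows, (1, 0, 2))
    labels = pd.DataFrame(
        {
            "subject": recording.subject,
            "modality": recording.modality,
            "emotion": recording.emotion,
            "trial": recording.trial,
            "window": np.arange(n_win),
        }
    )
    return EpochSet(
        epochs=epochs, fs=fs, labels=labels, channel_names=list(recording.channel_names)
    )


def epoch_recordings(
    recordings, window_s: float = 5.0, span_s: tuple[float, float] = (0.0, 30.0)
) -> EpochSet:
    """Epoch many recordings into one concatenated :class:`EpochSet`."""
    sets = [epoch_windows(r, window_s, span_s) for r in recordings]
    if not sets:
        raise ValueError("no recordings to epoch")
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        fs=sets[0].fs,
        labels=pd.concat([s.labels for s in sets], ignore_index=True),
        channel_names=list(sets[0].channel_names),
    )


def drop_reference(epochset: EpochSet, channel: str = "FCz") -> EpochSet:
    """Remove the reference channel; no-op with a warning if absent."""
    if channel not in epochset.channel_names:
        logger.warning("reference channel %r not in montage; nothing dropped", channel)
        return epochset
    idx = epochset.channel_names.index(channel)
    keep = [i for i in range(epochset.n_channels) if i != idx]
    return EpochSet(
        epochs=epochset.epochs[:, keep, :],
        fs=epochset.fs,
        labels=epochset.labels,
        channel_names=[epochset.channel_names[i] for i in keep],
    )


def preprocess_recording(
    recording: Recording,
    low: float = 1.0,
    high: float = 50.0,
    mains: float = 50.0,
    baseline_ms: float = 1000.0,
) -> Recording:
    """Full per-trial chain: bandpass -> notch -> baseline correction."""
    rec = bandpass_broadband(recording, low, high)
    rec = notch_mains(rec, mains)
    return baseline_correct(rec, baseline_ms)
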