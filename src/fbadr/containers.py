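"""Core in-memory containers shared across the pipeline.

A :class:`Recording` is one continuous trial (pre-stimulus baseline plus
stimulation period) for one subject/modality/emotion.  An :class:`EpochSet`
holds fixed-length analysis windows cut from many recordings, together with
an aligned label table.  :class:`BandedEpochs` is the filter-bank output:
six band-limited copies of the same epochs sharing one label table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("audio", "visual", "audiovisual")
EMOTIONS = ("pleasure", "unpleasure")

#: Columns every epoch label table carries, in canonical order.
LABEL_COLUMNS = ("subject", "modality", "emotion", "trial", "window")


@dataclass
class Recording:
    """One continuous multichannel trial.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_times)
        Amplitudes in arbitrary microvolt-like units.
    fs : float
        Sampling rate in Hz.
    onset_index : int
        Sample index of stimulus onset; samples before it are the
        pre-stimulus baseline.
    subject, modality, emotion, trial
        Trial labels. ``modality`` is one of :data:`MODALITIES`,
        ``emotion`` one of :data:`EMOTIONS`.
    channel_names : list of str, optional
        Montage channel names; defaults to ``ch00 .. chNN``.
    """

    data: np.ndarray
    fs: float
    onset_index: int
    subject: int
    modality: str
    emotion: str
    trial: int
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (channels x times)")
        if not np.isfinite(self.data).all():
            raise ValueError("Recording contains non-finite samples")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if not 0 <= self.onset_index <= self.data.shape[1]:
            raise ValueError("onset_index outside the recording")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs,
            onset_index=self.onset_index,
            subject=self.subject,
            modality=self.modality,
            emotion=self.emotion,
            trial=self.trial,
            channel_names=list(self.channel_names),
        )


@dataclass
class EpochSet:
    """Labeled fixed-length windows, ``epochs[i]`` described by ``labels.iloc[i]``."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    fs: float
    labels: pd.DataFrame
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n, channels, times)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("label table not aligned with epochs")
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"label table missing columns {sorted(missing)}")
        if not np.isfinite(self.epochs).all():
            raise ValueError("epochs contain non-finite samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.epochs.shape[1])]

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Row-subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return EpochSet(
            epochs=self.epochs[mask],
            fs=self.fs,
            labels=self.labels.iloc[mask].reset_index(drop=True),
            channel_names=list(self.channel_names),
        )


@dataclass
class BandedEpochs:
    """Filter-bank output: one EpochSet per sub-band, shared label order."""

    bands: dict[int, EpochSet]  # keyed by band index 1..6

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("no bands")
        ns = {len(es) for es in self.bands.values()}
        if len(ns) != 1:
            raise ValueError("bands disagree on epoch count")

    @property
    def labels(self) -> pd.DataFrame:
        return next(iter(self.bands.values())).labels

    @property
    def band_indices(self) -> list[int]:
        return sorted(self.bands)

    def __len__(self) -> int:
        return len(next(iter(self.bands.values())))
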