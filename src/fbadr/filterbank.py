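"""Six-band IIR filter bank splitting broadband epochs into sub-bands.

The canonical band table is delta 1-4, theta 4-8, alpha 8-13, beta1 13-20,
beta2 20-30 and gamma 30-50 Hz, with beta split in two so that attention-
and motor-related rhythms are separated.  Each band is a 4th-order
Butterworth bandpass applied forward-backward (zero phase); adjacent bands
share their nominal -3 dB edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .containers import BandedEpochs, EpochSet


@dataclass(frozen=True)
class BandDefinition:
    index: int
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 6:
            raise ValueError("band index must be 1..6")
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")


#: Canonical six-band table (Hz).
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition(1, "delta", 1.0, 4.0),
    BandDefinition(2, "theta", 4.0, 8.0),
    BandDefinition(3, "alpha", 8.0, 13.0),
    BandDefinition(4, "beta1", 13.0, 20.0),
    BandDefinition(5, "beta2", 20.0, 30.0),
    BandDefinition(6, "gamma", 30.0, 50.0),
)

FILTER_ORDER = 4


@lru_cache(maxsize=64)
def band_sos(low: float, high: float, fs: float, order: int = FILTER_ORDER) -> np.ndarray:
    """Second-order sections of one Butterworth bandpass."""
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for band edge {high} Hz")
    return signal.butter(order, [low, high], btype="bandpass", output="sos", fs=fs)


def filter_band(data: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase band filtering along the last axis."""
    sos = band_sos(band.low, band.high, fs)
    return signal.sosfiltfilt(sos, data, axis=-1)


def apply_filter_bank(epochset: EpochSet, bands: tuple[BandDefinition, ...] = BANDS) -> BandedEpochs:
    """Split every epoch into the six sub-bands.

    Returns a :class:`BandedEpochs` whose label tables are the *same
    object* across bands, so alignment is preserved bit-exactly.
    """
    if epochset.fs <= 2 * max(b.high for b in bands):
        raise ValueError("sampling rate too low for the highest band edge")
    out: dict[int, EpochSet] = {}
    for band in bands:
        filtered = filter_band(epochset.epochs, band, epochset.fs)
        out[band.index] = EpochSet(
            epochs=filtered,
            fs=epochset.fs,
            labels=epochset.labels,
            channel_names=list(epochset.channel_names),
        )
    return BandedEpochs(bands=out)
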