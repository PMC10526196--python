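"""Synthetic cross-sensory EEG generator.

The generator produces multichannel trials whose *band-specific spatial
covariance* carries the emotion label, and whose channel mixing is
perturbed per sensory modality — exactly the statistical structure the
downstream pipeline measures (Riemannian band features) and corrects
(adversarial domain adaptation).

Construction per band ``b``:

* a base symmetric matrix ``M_b`` defines the neutral (pre-stimulus)
  covariance ``expm(M_b)``;
* a unit-norm symmetric direction ``D_b`` separates the emotions in the
  matrix-log domain: ``Sigma_{b,e} = expm(M_b +/- class_sep/2 * D_b)``,
  so both classes are SPD for any separation and their Frobenius distance
  grows with ``class_sep``;
* per-subject jitter adds ``subject_jitter * J_{s,b}`` (random symmetric)
  to the log-domain matrix;
* each modality ``m`` applies an invertible mixing ``T_m = R_m G_m``
  (rotation ``expm(shift_strength*W_m)`` with skew-symmetric ``W_m`` of
  unit spectral norm, gains ``diag(exp(shift_strength*g_m))``), identity
  for the designated reference modality (audio-visual) and whenever
  ``shift_strength = 0``.

A trial is the sum over the six bands of band-limited Gaussian noise
spatially colored by the Cholesky factor of the band covariance, plus
white sensor noise and a per-channel constant offset (what baseline
correction removes).  Band-limited sources are obtained by running white
noise through the same six zero-phase Butterworth filters as the analysis
filter bank and rescaling by the filter's noise gain, so the per-band
covariance of a long trial converges to the generating matrix.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .config import GeneratorConfig
from .containers import EMOTIONS, MODALITIES, Recording
from .filterbank import BANDS, band_sos
from .riemann import expm_sym

__all__ = [
    "make_band_covariances",
    "neutral_covariance",
    "modality_transform",
    "simulate_trial",
    "simulate_dataset",
    "iter_dataset",
    "trial_manifest",
    "inject_noise",
    "realized_snr",
]

_REFERENCE_MODALITY = "audiovisual"
# log-domain scale of the base covariance; keeps condition numbers EEG-like
_BASE_SCALE = 0.15
# how much of the modality shift is a broadband (montage-level) mixing
# versus rhythm-specific; both components scale with shift_strength
_SHARED_SHIFT_FRACTION = 0.7


def _sym(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def _rng_for(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


def _band_structure(config: GeneratorConfig, band_index: int):
    """Base log-covariance M_b and unit-Frobenius emotion direction D_b."""
    g = _rng_for(config, 101, band_index)
    k = config.n_channels
    m = _sym(g.standard_normal((k, k))) * _BASE_SCALE / np.sqrt(k)
    d = _sym(g.standard_normal((k, k)))
    d /= np.linalg.norm(d, "fro")
    return m, d


def _subject_jitter(config: GeneratorConfig, band_index: int, subject: int) -> np.ndarray:
    g = _rng_for(config, 103, band_index, int(subject))
    j = _sym(g.standard_normal((config.n_channels,) * 2))
    return config.subject_jitter * j / np.linalg.norm(j, "fro")


def _check_band(band_index: int) -> None:
    if band_index not in range(1, 7):
        raise ValueError(f"band_index must be in 1..6, got {band_index}")


def make_band_covariances(
    config: GeneratorConfig, band_index: int, emotion: str, subject: int | None = None
) -> np.ndarray:
    """Generating spatial covariance for one (band, emotion[, subject]).

    Deterministic given ``config.seed``; symmetric positive definite for
    any ``class_sep >= 0``; the two emotions coincide at ``class_sep=0``.
    """
    _check_band(band_index)
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    m, d = _band_structure(config, band_index)
    sign = 1.0 if emotion == "pleasure" else -1.0
    log_cov = m + sign * (config.class_sep / 2.0) * d
    if subject is not None and config.subject_jitter > 0:
        log_cov = log_cov + _subject_jitter(config, band_index, subject)
    return expm_sym(log_cov)


def neutral_covariance(
    config: GeneratorConfig, band_index: int, subject: int | None = None
) -> np.ndarray:
    """Emotion-independent covariance used for the pre-stimulus baseline."""
    _check_band(band_index)
    m, _ = _band_structure(config, band_index)
    if subject is not None and config.subject_jitter > 0:
        m = m + _subject_jitter(config, band_index, subject)
    return expm_sym(m)


def modality_transform(config: GeneratorConfig, modality: str,
                       band_index: int = 1) -> np.ndarray:
    """Invertible channel-mixing perturbation for one (modality, band).

    Identity for the reference modality (audio-visual) and for
    ``shift_strength = 0``.  The perturbation differs per frequency band:
    sensory-modality effects on EEG are rhythm-specific, so the domain
    shift the adapter must remove is not a single broadband mixing.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    _check_band(band_index)
    k = config.n_channels
    if modality == _REFERENCE_MODALITY or config.shift_strength == 0:
        return np.eye(k)

    def _component(key: int, strength: float) -> np.ndarray:
        g = _rng_for(config, 105, MODALITIES.index(modality), key)
        w = g.standard_normal((k, k))
        w = (w - w.T) / 2.0
        w /= np.linalg.norm(w, 2)
        gains = g.normal(0.0, 0.2, size=k)
        return _expm_skew(strength * w) @ np.diag(np.exp(strength * gains))

    # shared (broadband) component times a rhythm-specific one
    shared = _SHARED_SHIFT_FRACTION * config.shift_strength
    per_band = (1.0 - _SHARED_SHIFT_FRACTION) * config.shift_strength
    return _component(0, shared) @ _component(band_index, per_band)


def _expm_skew(w: np.ndarray) -> np.ndarray:
    """Matrix exponential of a skew-symmetric matrix (orthogonal result)."""
    from scipy.linalg import expm

    return expm(w)


@lru_cache(maxsize=64)
def _band_noise_gain(low: float, high: float, fs: float) -> float:
    """Std of unit white noise after zero-phase (forward-backward) filtering.

    sosfiltfilt applies the magnitude response twice, so the output
    variance is the mean of |H(f)|^4 over the Nyquist range.
    """
    sos = band_sos(low, high, fs)
    _, h = sp_signal.sosfreqz(sos, worN=4096, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def simulate_trial(
    config: GeneratorConfig,
    subject: int,
    modality: str,
    emotion: str,
    rng: np.random.Generator,
) -> Recording:
    """Simulate one trial (baseline + stimulation period)."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    k, fs = config.n_channels, config.fs
    n_total, onset = config.n_times, config.onset_index

    data = np.zeros((k, n_total))
    for band, weight in zip(BANDS, config.band_weights):
        if weight == 0.0:
            continue
        t_mod = modality_transform(config, modality, band.index)
        cov_stim = make_band_covariances(config, band.index, emotion, subject)
        cov_pre = neutral_covariance(config, band.index, subject)
        l_stim = np.linalg.cholesky(t_mod @ cov_stim @ t_mod.T)
        l_pre = np.linalg.cholesky(t_mod @ cov_pre @ t_mod.T)
        white = rng.standard_normal((k, n_total))
        sos = band_sos(band.low, band.high, fs)
        u = sp_signal.sosfiltfilt(sos, white, axis=-1)
        u /= _band_noise_gain(band.low, band.high, fs)
        data[:, :onset] += weight * (l_pre @ u[:, :onset])
        data[:, onset:] += weight * (l_stim @ u[:, onset:])

    if config.sensor_noise > 0:
        data += config.sensor_noise * rng.standard_normal((k, n_total))
    if config.dc_offset > 0:
        data += rng.normal(0.0, config.dc_offset, size=(k, 1))

    return Recording(
        data=data,
        fs=fs,
        onset_index=onset,
        subject=int(subject),
        modality=modality,
        emotion=emotion,
        trial=0,
    )


def trial_manifest(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic listing of every trial the dataset contains."""
    rows = [
        (s, m, e, t)
        for s in range(config.n_subjects)
        for m in MODALITIES
        for e in EMOTIONS
        for t in range(config.n_trials)
    ]
    return pd.DataFrame(rows, columns=["subject", "modality", "emotion", "trial"])


def iter_dataset(config: GeneratorConfig):
    """Yield every trial lazily, reproducibly from ``config.seed``.

    Each trial draws from its own seed stream keyed by its labels, so any
    subset can be regenerated without simulating the rest.
    """
    for row in trial_manifest(config).itertuples(index=False):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [
                    int(config.seed),
                    3,
                    int(row.subject),
                    MODALITIES.index(row.modality),
                    EMOTIONS.index(row.emotion),
                    int(row.trial),
                ]
            )
        )
        rec = simulate_trial(config, row.subject, row.modality, row.emotion, rng)
        rec.trial = int(row.trial)
        yield rec


def simulate_dataset(config: GeneratorConfig) -> list[Recording]:
    """Materialize the full dataset (use :func:`iter_dataset` at scale)."""
    return list(iter_dataset(config))


def inject_noise(signal: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Add zero-mean Gaussian noise at a requested SNR in dB.

    The noise variance is ``P_signal / 10**(snr_db/10)`` with the signal
    power taken as the mean square over all channels and samples, so
    ``10*log10(P_signal/P_noise) = snr_db`` in expectation.
    """
    signal = np.asarray(signal, dtype=np.float64)
    p_signal = float(np.mean(signal**2))
    if p_signal == 0.0:
        raise ValueError("signal has zero power; SNR undefined")
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    return signal + rng.normal(0.0, sigma, size=signal.shape)


def realized_snr(clean: np.ndarray, noised: np.ndarray) -> float:
    """Empirical SNR (dB) of a noised signal against its clean original."""
    noise = np.asarray(noised) - np.asarray(clean)
    p_noise = float(np.mean(noise**2))
    p_signal = float(np.mean(np.asarray(clean) ** 2))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * np.log10(p_signal / p_noise)
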