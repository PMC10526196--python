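"""Statistical structure and determinism of the synthetic EEG generator."""

import dataclasses

import numpy as np
import pytest

from fbadr.config import GeneratorConfig
from fbadr.synthetic import (
    inject_noise,
    iter_dataset,
    make_band_covariances,
    modality_transform,
    neutral_covariance,
    realized_snr,
    simulate_dataset,
    simulate_trial,
    trial_manifest,
)


class TestBandCovariances:
    def test_zero_separation_collapses_classes(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, class_sep=0.0)
        for band in (1, 4, 6):
            a = make_band_covariances(cfg, band, "pleasure")
            b = make_band_covariances(cfg, band, "unpleasure")
            np.testing.assert_allclose(a, b)

    def test_spd(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_channels=4, class_sep=1.0, seed=0)
        cov = make_band_covariances(cfg, 2, "pleasure")
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_separation_monotone_in_class_sep(self, tiny_config):
        def dist(sep):
            cfg = dataclasses.replace(tiny_config, class_sep=sep)
            a = make_band_covariances(cfg, 3, "pleasure")
            b = make_band_covariances(cfg, 3, "unpleasure")
            return np.linalg.norm(a - b, "fro")

        assert dist(2.0) > dist(1.0) > dist(0.0) == 0.0

    def test_deterministic(self, tiny_config):
        a = make_band_covariances(tiny_config, 5, "pleasure", subject=0)
        b = make_band_covariances(tiny_config, 5, "pleasure", subject=0)
        np.testing.assert_array_equal(a, b)

    def test_invalid_band(self, tiny_config):
        with pytest.raises(ValueError):
            make_band_covariances(tiny_config, 7, "pleasure")


class TestModalityTransform:
    def test_reference_modality_is_identity(self, tiny_config):
        t = modality_transform(tiny_config, "audiovisual", 1)
        np.testing.assert_array_equal(t, np.eye(tiny_config.n_channels))

    def test_zero_shift_is_identity_everywhere(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, shift_strength=0.0)
        for mod in ("audio", "visual", "audiovisual"):
            np.testing.assert_array_equal(
                modality_transform(cfg, mod, 2), np.eye(cfg.n_channels)
            )

    def test_invertible(self, tiny_config):
        t = modality_transform(tiny_config, "audio", 3)
        assert abs(np.linalg.det(t)) > 1e-6


class TestSimulateTrial:
    def test_shape_matches_published_design(self):
        """31 channels, (1+30) s at 500 Hz = 15500 samples per trial."""
        cfg = GeneratorConfig(seed=0)
        rng = np.random.default_rng(0)
        rec = simulate_trial(cfg, 0, "audio", "pleasure", rng)
        assert rec.data.shape == (31, 15500)
        assert rec.onset_index == 500

    def test_single_band_covariance_convergence(self):
        """Long single-band trial reproduces its generating covariance."""
        cfg = GeneratorConfig(
            n_subjects=1, n_trials=1, trial_s=60.0, pre_s=1.0, fs=128.0,
            n_channels=5, class_sep=0.5, shift_strength=0.0,
            sensor_noise=0.0, subject_jitter=0.0, dc_offset=0.0,
            band_weights=(0, 0, 0, 0, 0, 1.0), seed=3,
        )
        rng = np.random.default_rng(5)
        rec = simulate_trial(cfg, 0, "audio", "pleasure", rng)
        stim = rec.data[:, rec.onset_index :]
        emp = stim @ stim.T / stim.shape[1]
        gen = make_band_covariances(cfg, 6, "pleasure", subject=0)
        rel = np.linalg.norm(emp - gen, "fro") / np.linalg.norm(gen, "fro")
        assert rel < 0.10

    def test_no_shift_makes_modalities_exchangeable(self):
        """Same-emotion covariances agree across modalities without shift."""
        cfg = GeneratorConfig(
            n_subjects=1, n_trials=1, trial_s=40.0, fs=128.0, n_channels=4,
            shift_strength=0.0, sensor_noise=0.0, subject_jitter=0.0,
            dc_offset=0.0, band_weights=(0, 0, 1.0, 0, 0, 0), seed=9,
        )
        covs = []
        for mod in ("audio", "visual"):
            rng = np.random.default_rng(11)  # same noise stream
            rec = simulate_trial(cfg, 0, mod, "pleasure", rng)
            stim = rec.data[:, rec.onset_index :]
            covs.append(stim @ stim.T / stim.shape[1])
        np.testing.assert_allclose(covs[0], covs[1], rtol=1e-10)

    def test_prestimulus_uses_neutral_covariance(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, trial_s=40.0, pre_s=40.0, sensor_noise=0.0,
            dc_offset=0.0, subject_jitter=0.0, shift_strength=0.0,
            band_weights=(0, 0, 0, 0, 1.0, 0.0),
        )
        rng = np.random.default_rng(2)
        rec = simulate_trial(cfg, 0, "audio", "pleasure", rng)
        pre = rec.data[:, : rec.onset_index]
        emp = pre @ pre.T / pre.shape[1]
        neutral = neutral_covariance(cfg, 5, subject=0)
        rel = np.linalg.norm(emp - neutral, "fro") / np.linalg.norm(neutral, "fro")
        assert rel < 0.25  # 40 s of a 10-Hz-wide band


class TestDataset:
    def test_manifest_published_layout(self):
        """Default design: 20 subjects x 3 modalities x 2 emotions x 10 trials."""
        assert len(trial_manifest(GeneratorConfig())) == 1200

    def test_minimal_dataset_has_six_trials(self):
        cfg = GeneratorConfig(
            n_subjects=1, n_trials=1, trial_s=5.0, fs=128.0, n_channels=3, seed=0
        )
        assert len(simulate_dataset(cfg)) == 6

    def test_same_seed_bit_identical(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_trials=1, trial_s=5.0)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        for r1, r2 in zip(d1, d2):
            np.testing.assert_array_equal(r1.data, r2.data)
            assert (r1.subject, r1.modality, r1.emotion, r1.trial) == (
                r2.subject, r2.modality, r2.emotion, r2.trial)

    def test_lazy_iteration_matches_materialized(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_trials=1, trial_s=5.0)
        lazy = [r.data for r in iter_dataset(cfg)]
        full = [r.data for r in simulate_dataset(cfg)]
        for a, b in zip(lazy, full):
            np.testing.assert_array_equal(a, b)


class TestInjectNoise:
    def test_zero_db_gives_unit_variance_on_unit_power(self, rng):
        sig = np.ones(200_000)
        noised = inject_noise(sig, 0.0, rng)
        assert abs(np.var(noised - sig) - 1.0) < 0.02

    def test_ten_db_gives_tenth_variance(self, rng):
        sig = np.ones(200_000)
        noised = inject_noise(sig, 10.0, rng)
        assert abs(np.var(noised - sig) - 0.1) < 0.005

    def test_realized_snr_converges(self, rng):
        """Monte-Carlo realized SNR within 0.1 dB at 1e6 samples."""
        sig = rng.standard_normal(1_000_000)
        noised = inject_noise(sig, 30.0, rng)
        assert abs(realized_snr(sig, noised) - 30.0) < 0.1

    def test_zero_power_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_noise(np.zeros(100), 10.0, rng)
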