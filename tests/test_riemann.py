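"""Riemannian feature extraction against independent oracles.

Brute-force loop implementations and scipy.linalg's Schur/Pade-based
matrix functions serve as independent references for the eigh-based
implementations in the package.
"""

import numpy as np
import pytest
import scipy.linalg

from fbadr.containers import BandedEpochs, EpochSet
from fbadr.filterbank import apply_filter_bank
from fbadr.riemann import (
    band_covariances,
    covariance,
    expm_sym,
    extract_features,
    fit_references,
    log_euclidean_mean,
    logm_spd,
    oas_regularize,
    tangent_project,
    tangent_retract,
)

from conftest import random_spd


def brute_force_covariance(x: np.ndarray) -> np.ndarray:
    """Direct transcription of C = sum_i x_i x_i^T / (N-1)."""
    k, n = x.shape
    c = np.zeros((k, k))
    for i in range(n):
        col = x[:, i : i + 1]
        c += col @ col.T
    return c / (n - 1)


class TestCovariance:
    def test_hand_case(self):
        x = np.array([[1.0, -1.0], [1.0, -1.0]])
        np.testing.assert_allclose(covariance(x), [[2.0, 2.0], [2.0, 2.0]])

    def test_zero_epoch(self):
        np.testing.assert_array_equal(covariance(np.zeros((3, 10))), np.zeros((3, 3)))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.standard_normal((5, 40))
            np.testing.assert_allclose(
                covariance(x), brute_force_covariance(x), atol=1e-10
            )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            covariance(np.zeros((3, 1)))


class TestOAS:
    def test_identity_fixed_point(self):
        np.testing.assert_allclose(oas_regularize(np.eye(4), 100), np.eye(4))

    def test_rank_deficient_becomes_spd(self, rng):
        x = rng.standard_normal((3, 2))  # rank-2 covariance of a K=3 epoch
        cov = covariance(x)
        out = oas_regularize(cov, 2)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_large_n_limit(self, rng):
        cov = random_spd(rng, 4)
        out = oas_regularize(cov, 10**9)
        np.testing.assert_allclose(out, cov, rtol=1e-5)

    def test_convex_combination_structure(self, rng):
        """Output lies on the segment between the input and mu*I."""
        cov = random_spd(rng, 5)
        n = 30
        out = oas_regularize(cov, n)
        mu = np.trace(cov) / 5
        # solve for rho from one off-diagonal entry, then check all entries
        rho = 1.0 - out[0, 1] / cov[0, 1]
        recon = (1 - rho) * cov + rho * mu * np.eye(5)
        assert 0.0 <= rho <= 1.0
        np.testing.assert_allclose(out, recon, atol=1e-10)

    def test_zero_trace_warns(self):
        with pytest.warns(UserWarning):
            out = oas_regularize(np.zeros((3, 3)), 10)
        assert np.linalg.eigvalsh(out).min() > 0


class TestMatrixFunctions:
    def test_logm_identity(self):
        np.testing.assert_allclose(logm_spd(np.eye(3)), np.zeros((3, 3)), atol=1e-12)

    def test_expm_zero(self):
        np.testing.assert_allclose(expm_sym(np.zeros((3, 3))), np.eye(3))

    def test_against_scipy(self, rng):
        for _ in range(20):
            a = random_spd(rng, 6)
            np.testing.assert_allclose(
                logm_spd(a), scipy.linalg.logm(a), atol=1e-8
            )
            s = (lambda m: (m + m.T) / 2)(rng.standard_normal((6, 6)))
            np.testing.assert_allclose(
                expm_sym(s), scipy.linalg.expm(s), rtol=1e-8, atol=1e-8
            )

    def test_round_trip(self, rng):
        a = random_spd(rng, 8)
        err = np.linalg.norm(expm_sym(logm_spd(a)) - a, "fro")
        assert err / np.linalg.norm(a, "fro") < 1e-8

    def test_logm_rejects_indefinite(self):
        with pytest.raises(ValueError):
            logm_spd(np.diag([1.0, -1.0]))


class TestLogEuclideanMean:
    def test_identical_inputs(self, rng):
        a = random_spd(rng, 4)
        np.testing.assert_allclose(log_euclidean_mean([a, a, a]), a, rtol=1e-10)

    def test_scalar_geometric_mean(self):
        out = log_euclidean_mean([np.diag([1.0, 1.0]), np.diag([4.0, 4.0])])
        np.testing.assert_allclose(out, np.diag([2.0, 2.0]), rtol=1e-12)

    def test_permutation_invariance(self, rng):
        mats = [random_spd(rng, 5) for _ in range(4)]
        m1 = log_euclidean_mean(mats)
        m2 = log_euclidean_mean(mats[::-1])
        np.testing.assert_allclose(m1, m2, atol=1e-10)
        assert np.linalg.eigvalsh(m1).min() > 0

    def test_empty_list(self):
        with pytest.raises(ValueError):
            log_euclidean_mean([])


class TestTangentSpace:
    def test_projection_at_self_is_zero(self, rng):
        a = random_spd(rng, 5)
        np.testing.assert_allclose(tangent_project(a, a), np.zeros((5, 5)), atol=1e-10)

    def test_scalar_case(self):
        s = tangent_project(np.array([[4.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(s, [[np.log(4.0)]])
        back = tangent_retract(np.array([[np.log(4.0)]]), np.array([[1.0]]))
        np.testing.assert_allclose(back, [[4.0]])

    def test_retract_zero_gives_reference(self, rng):
        ref = random_spd(rng, 4)
        np.testing.assert_allclose(
            tangent_retract(np.zeros((4, 4)), ref), ref, rtol=1e-10
        )

    def test_round_trip_many(self, rng):
        """Project/retract are mutual inverses at random references."""
        for _ in range(100):
            k = int(rng.integers(2, 9))
            cov = random_spd(rng, k)
            ref = random_spd(rng, k)
            back = tangent_retract(tangent_project(cov, ref), ref)
            rel = np.linalg.norm(back - cov, "fro") / np.linalg.norm(cov, "fro")
            assert rel < 1e-8

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            tangent_project(random_spd(rng, 3), random_spd(rng, 4))


class TestFeatureExtraction:
    def _banded(self, rng, k=4, n=6, t=64):
        import pandas as pd

        labels = pd.DataFrame(
            {
                "subject": 0,
                "modality": "audio",
                "emotion": ["pleasure", "unpleasure"] * (n // 2),
                "trial": range(n),
                "window": 0,
            }
        )
        es = EpochSet(
            epochs=rng.standard_normal((n, k, t)), fs=128.0, labels=labels
        )
        return BandedEpochs(bands={1: es})

    def test_feature_length_is_k_squared(self, rng):
        """31 channels give 961-dimensional flattened tangent vectors."""
        covs = {1: np.stack([random_spd(rng, 31) for _ in range(3)])}
        refs = fit_references(covs)
        feats = extract_features(covs, refs)
        assert feats[1].shape == (3, 961)

    def test_reference_defining_epoch_maps_near_zero(self, rng):
        cov = random_spd(rng, 4)
        feats = extract_features({1: cov[None]}, {1: cov})
        np.testing.assert_allclose(feats[1], 0.0, atol=1e-10)

    def test_channel_permutation_equivariance(self, rng):
        covs = np.stack([random_spd(rng, 5) for _ in range(4)])
        perm = rng.permutation(5)
        p = np.eye(5)[perm]
        covs_p = np.einsum("ij,njk,lk->nil", p, covs, p)
        refs = fit_references({1: covs})
        refs_p = fit_references({1: covs_p})
        np.testing.assert_allclose(refs_p[1], p @ refs[1] @ p.T, atol=1e-8)
        f = extract_features({1: covs}, refs)[1]
        f_p = extract_features({1: covs_p}, refs_p)[1]
        for i in range(len(covs)):
            s = f[i].reshape(5, 5)
            s_p = f_p[i].reshape(5, 5)
            np.testing.assert_allclose(s_p, p @ s @ p.T, atol=1e-8)

    def test_missing_reference_errors(self, rng):
        covs = {1: np.stack([random_spd(rng, 3)])}
        with pytest.raises(ValueError):
            extract_features(covs, {})

    def test_band_covariances_are_spd(self, rng):
        banded = self._banded(rng)
        covs = band_covariances(banded)
        for mat in covs[1]:
            assert np.allclose(mat, mat.T)
            assert np.linalg.eigvalsh(mat).min() > 0
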