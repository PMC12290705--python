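"""Matrix composition, low-rank reconstruction and the trial pipeline."""

import numpy as np
import pytest
from scipy import signal

from pcdenoise import (
    PCDConfig,
    PhaseCouplingDecomposition,
    TrialConfig,
    TrialEpoch,
    analytic_signal,
    itpc,
    loading_cosine_similarity,
    preprocess,
    run_pcd_trial,
    simulate_trial,
    transform_ssd,
)
from pcdenoise.model import compose_unmixing, lowrank_reconstruct, mixing_from_unmixing


class TestComposeUnmixing:
    def test_neutral_blocks_reduce_to_ssd(self):
        W_ssd = np.random.default_rng(0).standard_normal((5, 5))
        W = compose_unmixing(np.eye(3), W_ssd, np.eye(3), k=3)
        np.testing.assert_allclose(W, W_ssd)

    def test_path_equivalence_with_sequential_stages(self, realistic_trial, fitted_results):
        """W_pcd^T X equals SSD -> whiten -> PCO applied in sequence."""
        res = fitted_results
        X = res._X_pre[:, res.fit_slice]
        direct = res.W_pcd.T @ X
        ssd_proj = transform_ssd(X, res.ssd)
        seq_top = res.pco.W.T @ (res.pco.M_white @ ssd_proj)
        rel = np.linalg.norm(direct[: res.k] - seq_top) / np.linalg.norm(seq_top)
        assert rel < 1e-6

    def test_channel_permutation_permutes_rows(self):
        rng = np.random.default_rng(1)
        W_ssd = rng.standard_normal((5, 5))
        M, W_pco = rng.standard_normal((2, 2)), rng.standard_normal((2, 2))
        W = compose_unmixing(M, W_ssd, W_pco, k=2)
        perm = np.array([4, 2, 0, 1, 3])
        W_perm = compose_unmixing(M, W_ssd[perm], W_pco, k=2)
        np.testing.assert_allclose(W_perm, W[perm])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_unmixing(np.eye(3), np.eye(5), np.eye(2), k=3)


class TestMixingFromUnmixing:
    def test_orthonormal_unmixing_maps_to_itself(self):
        q, _ = np.linalg.qr(np.random.default_rng(2).standard_normal((4, 4)))
        np.testing.assert_allclose(mixing_from_unmixing(q), q, atol=1e-12)

    def test_round_trip_on_well_conditioned_matrix(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        A = mixing_from_unmixing(W)
        X = rng.standard_normal((6, 500))
        rel = np.linalg.norm(A @ W.T @ X - X) / np.linalg.norm(X)
        assert rel < 1e-8

    def test_rank_deficient_round_trip_is_rowspace_projection(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((4, 2)) @ rng.standard_normal((2, 4))  # rank 2
        A = mixing_from_unmixing(W)
        X = rng.standard_normal((4, 300))
        P = A @ W.T  # projector onto the rank-2 subspace
        np.testing.assert_allclose(P @ P, P, atol=1e-8)
        np.testing.assert_allclose(A @ W.T @ (P @ X), P @ X, atol=1e-8)


class TestLowrankReconstruct:
    def test_m_zero_is_identity(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        A = mixing_from_unmixing(W)
        X = rng.standard_normal((5, 200))
        rel = np.linalg.norm(lowrank_reconstruct(X, W, A, 0) - X) / np.linalg.norm(X)
        assert rel < 1e-8

    def test_rank_contract(self):
        rng = np.random.default_rng(6)
        W = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        A = mixing_from_unmixing(W)
        X = rng.standard_normal((4, 200))
        with pytest.raises(ValueError):
            lowrank_reconstruct(X, W, A, 4)
        out = lowrank_reconstruct(X, W, A, 3)
        assert np.linalg.matrix_rank(out) == 1

    def test_denoising_removes_inband_power_only(self):
        """Band-power oracle: >=10 dB in-SAFB drop, <1 dB out-of-band change.

        The mixture includes a slow (10-40 Hz) neural source so the
        out-of-band power being preserved is real signal, not filter skirt.
        """
        from pcdenoise import GammaParams, TrialEpoch
        from pcdenoise.simulate import AudioParams, gen_audio, gen_gamma_source, mix_sources

        fs = 1000.0
        gamma = [
            gen_gamma_source(GammaParams(envelope="gaussian_burst", mu=m, seed=s), 3.0, fs)
            for m, s in ((0.75, 1), (1.75, 2), (2.75, 3))
        ]
        slow = gen_gamma_source(
            GammaParams(band_lo=10.0, band_hi=40.0, Ap=0.0, seed=4), 3.0, fs
        )
        audio = gen_audio(AudioParams(scenario="mcas", seed=5)).data
        # strong contamination: the SAFB content is then artifact-dominated,
        # so the removable in-band power is well above 10 dB
        rec, truth = mix_sources(
            np.vstack(gamma + [slow]), audio, 15.0, n_channels=16, fs=fs, seed=6
        )
        trial = TrialEpoch(rec.data, audio, 500, fs)
        X_den, res = run_pcd_trial(trial)
        X_con = res._X_pre[:, res.wide_slice]
        band = res.band

        def band_power(X, lo, hi):
            sos = signal.butter(4, (lo, hi), "bandpass", fs=fs, output="sos")
            return np.mean(signal.sosfiltfilt(sos, X, axis=-1) ** 2)

        drop = 10 * np.log10(
            band_power(X_con, band.lo, band.hi) / band_power(X_den, band.lo, band.hi)
        )
        out_change = abs(
            10 * np.log10(band_power(X_con, 10.0, 50.0) / band_power(X_den, 10.0, 50.0))
        )
        assert drop >= 10.0
        assert out_change < 1.0


class TestPreprocess:
    def test_dc_offset_removed(self):
        X = np.full((2, 3000), 5.0) + np.random.default_rng(0).standard_normal((2, 3000)) * 0.01
        out = preprocess(X, 1000.0)
        assert abs(out.mean()) < 5e-3

    def test_line_noise_notched(self):
        # steady-state attenuation, away from zero-phase boundary ringing
        t = np.arange(5000) / 1000.0
        X = np.sin(2 * np.pi * 60.0 * t + 0.7)[None, :]
        out = preprocess(X, 1000.0)[:, 1000:-1000]
        assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(np.mean(X**2))

    def test_passband_preserved(self):
        t = np.arange(3000) / 1000.0
        X = np.sin(2 * np.pi * 100.0 * t)[None, :]
        out = preprocess(X, 1000.0)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(np.sqrt(np.mean(X**2)), rel=0.05)

    def test_notch_above_nyquist_skipped(self):
        X = np.random.default_rng(1).standard_normal((2, 2000))
        out = preprocess(X, 300.0)  # 180/240 Hz notches impossible
        assert np.all(np.isfinite(out))


class TestRunPcdTrial:
    def test_itpc_contamination_decreases(self):
        """ITPC before/after oracle over a simulated session."""
        n_trials = 20
        raw, den = [], []
        for i in range(n_trials):
            trial, _ = simulate_trial(
                TrialConfig(scenario="realistic", seed=100 + i, agr_db=0.0, mix_seed=55)
            )
            X_den, res = run_pcd_trial(trial)
            sl = res.wide_slice
            raw.append(TrialEpoch(trial.X[:, sl], trial.audio[sl], 0, trial.fs))
            den.append(TrialEpoch(X_den, trial.audio[sl], 0, trial.fs))
        frac_before = np.mean(itpc(raw).significant)
        frac_after = np.mean(itpc(den).significant)
        assert frac_after < frac_before

    def test_artifact_free_data_is_preserved(self):
        """Neural-preservation oracle: PCA loadings survive the pipeline."""
        trial, truth = simulate_trial(TrialConfig(scenario="realistic", seed=1, agr_db=-60.0))
        X_den, res = run_pcd_trial(trial)
        gt = truth.clean_mixture()[:, res.wide_slice]
        _, cs = loading_cosine_similarity(gt, X_den)
        assert cs >= 0.95

    def test_deterministic_given_config_and_seed(self, realistic_trial):
        trial, _ = realistic_trial
        cfg = PCDConfig(seed=4)
        X1, _ = run_pcd_trial(trial, cfg)
        X2, _ = run_pcd_trial(trial, cfg)
        np.testing.assert_array_equal(X1, X2)

    def test_fewer_than_three_channels_rejected(self):
        with pytest.raises(ValueError):
            PhaseCouplingDecomposition(np.zeros((2, 1000)), np.zeros(1000), 1000.0)


class TestPipelineInvariants:
    def test_energy_never_increases_with_removal(self):
        """Removing components should not add variance on most channels."""
        ok, total = 0, 0
        for seed in range(10):
            trial, _ = simulate_trial(TrialConfig(scenario="realistic", seed=200 + seed))
            _, res = run_pcd_trial(trial)
            X_con = res._X_pre[:, res.wide_slice]
            X_den = res.denoise()
            ok += np.sum(np.var(X_den, axis=1) <= np.var(X_con, axis=1) * (1 + 1e-9))
            total += X_con.shape[0]
        assert ok / total >= 0.9

    def test_audio_sign_flip_leaves_denoised_unchanged(self, realistic_trial):
        """Antiphase equivalence: the reconstruction ignores the z sign."""
        trial, _ = realistic_trial
        cfg = PCDConfig(seed=0)
        X1, _ = run_pcd_trial(trial, cfg)
        flipped = TrialEpoch(trial.X, -trial.audio, trial.onset_index, trial.fs)
        X2, _ = run_pcd_trial(flipped, cfg)
        np.testing.assert_allclose(X1, X2, atol=1e-6 * np.abs(X1).max())

    def test_unmixing_mixing_consistency(self, fitted_results):
        res = fitted_results
        ident = res.A_pcd @ res.W_pcd.T
        assert np.max(np.abs(ident - np.eye(ident.shape[0]))) < 1e-6

    def test_summary_mentions_key_fields(self, fitted_results):
        text = fitted_results.summary()
        for token in ("SAFB", "SSD components", "removed", "MVL"):
            assert token in text
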