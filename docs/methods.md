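# Methods

## The problem

During overt speech, acoustic vibrations propagate through cables and
connectors of the acquisition chain and appear in intracranial recordings
(ECoG, DBS-lead and microelectrode LFP) as a narrow-band artifact centered
on the speaker's voice fundamental F0 (roughly 70–240 Hz).  Because this
range overlaps high-gamma activity — the main carrier of speech
information in intracranial signals — the artifact can silently drive
speech-decoding models.  The artifact is assumed to be (i) narrow-band
around F0, (ii) common across simultaneously recorded modalities, and
(iii) well approximated in waveform by the microphone's produced-audio
trace `z`.

## The model

Recordings follow the linear forward model `X = A S` with `X` the
channels × samples data, `S` the sources and `A` an unknown mixing
matrix.  Phase-coupling decomposition (PCD) estimates an unmixing matrix
whose leading components are the acoustic-induced sources, in four steps:

1. **Band estimation.**  The speech-artifact frequency band (SAFB) is
   `Fc ± ΔFc`, obtained from the Welch spectrum of the detrended audio
   (1 s Hann segments, 50% overlap): the largest peak inside 50–250 Hz
   that exceeds the in-band median by 6 dB gives F0; a Gaussian-plus-floor
   fit around it gives the center `Fc` and `ΔFc` = fitted FWHM, floored at
   two frequency bins.  If the fit does not converge the band falls back
   to `F0 ± 5 Hz`.

2. **Spatiospectral decomposition (SSD).**  `X` is split into a zero-phase
   Butterworth band-pass over the SAFB (signal) and the band-stop
   complement (noise), both order 4 per pass.  The generalized eigenvalue
   problem `Σ_signal w = λ Σ_noise w` on the channel covariances
   (`Σ = X_band X_bandᵀ / Ns`, noise side ridge-regularized by
   `1e-6 · trace/Nc`) yields filters sorted by decreasing in-band SNR λ.
   The retained rank is the participation ratio
   `k = ⌊(Σλ)²/Σλ²⌋`, clamped to `[1, Nc]`.

3. **Phase-coupling optimization (PCO).**  The analytic signal
   `Y = X_ssd + i·H(X_ssd)` of the k retained components is whitened
   (PCA whitening of the real part, rank-truncated at condition 1e8) and
   real-valued filters `w` maximize the mean vector length
   `MVL(w) = |mean_t z_t · (wᵀy_t)/|wᵀy_t||` against the z-scored audio.
   The objective is differentiable but not concave: each component is the
   best of `n_restarts = 10` L-BFGS ascents (analytic gradient, tolerance
   1e-8, ≤ 500 iterations) from seeded random unit starts; subsequent
   components are restricted to the orthogonal complement of previous
   filters in the whitened space; a 1e-12 guard protects the phasor
   division.  Filters are sorted by achieved MVL.  Sign is deliberately
   left free — `w` and `−w` are equivalent, so the recovered source may be
   in phase or antiphase with the audio, and all downstream metrics treat
   0 and π symmetrically.

4. **Reconstruction.**  The composed unmixing is
   `W_pcd = W_ssd · blockdiag(Mᵀ W_pco, I)`, i.e. the whitened PCO
   solution embedded on the first k SSD components, identity on the rest.
   The mixing matrix is the Moore–Penrose pseudoinverse taken so the
   forward/backward pair is self-consistent (`A = pinv(Wᵀ)`, hence
   `A Wᵀ = I` at full rank).  The number of artifactual components `m` is
   the elbow (largest discrete second difference) of the descending MVL
   trace, clamped to `[1, k−1]`; `m = 1` when `k ≤ 2`.  Denoising zeroes
   the first `m` columns of both matrices:
   `X_denoised = Ã W̃ᵀ X`.

Because F0 drifts across trials, the model is fitted per trial on an
epoch around the produced-speech onset (default −0.5 s to +2 s,
configurable) after a zero-phase 2 Hz high-pass and 60/120/180/240 Hz
notches (Q = 30), and the learned transform is applied to a wider
epoch (±6 s, clipped to the recording).  All recording modalities are
stacked into one sensor space before fitting, consistent with an artifact
entering the shared acquisition chain.

## Synthetic data

The simulator provides ground truth the pipeline can be scored against.

*Artifact/audio sources.*  Three scenarios: a sinusoid at F0 with additive
white noise (SAS); colored noise, i.e. white noise band-passed over
`F0 ± dF` with a zero-phase Butterworth of configurable order, default 25
(CAS); and the colored noise gated by a syllable activation pattern — 1
inside each 0.5 s syllable window, 0 elsewhere (MCAS), emulating the
nonstationary audio of a syllable-repetition task.  Defaults: F0 = 150 Hz,
dF = 8 Hz, fs = 1000 Hz, 3 s, syllable onsets at 0.5/1.5/2.5 s.

*Neural sources.*  Surrogate broadband-gamma sources: Gaussian noise
band-limited to 60–200 Hz (unit-RMS carrier) multiplied by an amplitude
envelope — either sustained-plus-periodic `As + Ap·sin(2πfp t + φp)` or a
speech-locked Gaussian burst `A·exp(−(t−μ)²/(2(FWHM/2.355)²))` (default
FWHM 0.4 s, centered on syllable midpoints), optionally modulated by
`1 + d·cos(2π f_pac t)` to add phase–amplitude coupling.  These are
statistical surrogates: they reproduce the spectral content, speech-locked
envelope and PAC of physiological gamma, not the biophysics that generates
it.  Sources in a multi-source trial get distinct amplitudes
(`1/(1+0.5j)`) so the ground-truth PCA ordering is identifiable; equal
powers would make loading directions degenerate and any loading-based
comparison ill-posed.

*Mixing.*  `X = A [S_neural; s_artifact]` with i.i.d. standard-normal `A`
(rank-checked, redrawn from the next substream if degenerate).  The
artifact is rescaled so the artifact-to-physiological-gamma ratio,
`AGR = 10·log10(P_a / P̄_γ)` with powers measured in 60–200 Hz, hits the
requested value.  No sensor noise is added, so mixing is exactly linear
and a trial with AGR → −∞ equals the artifact-free mixture.  Within a
multi-trial session the mixing matrix can be fixed (`mix_seed`) to
emulate a stable montage — intertrial phase consistency only accumulates
under a stable artifact propagation path — or redrawn per trial to stress
source recovery.

What the simulations do *not* contain: spectral distortion or delay
between audio and artifact, 1/f background, sensor noise, montage drift.
Passing these benchmarks therefore demonstrates correctness of the
algorithm under its own assumptions, not performance on clinical data.

## Evaluation metrics

- `chi2_similarity`: per-channel mean squared deviation over ground-truth
  variance.
- `msce`: Welch magnitude-squared coherence; `normalized_mse`: MSE after
  dividing each signal by its maximum absolute value; `plv`:
  phase-locking value of analytic phases.
- `loading_cosine_similarity`: absolute cosine similarity of the first
  three PCA loadings, PCA fitted independently per dataset.
- `itpc`: per trial the complex phase estimate
  `φ_e = Σ y_t z_t / (‖y‖‖z‖)` (`y` analytic band-passed channel, `z`
  band-passed audio, 70–240 Hz); across trials
  `ITPC = |mean φ| / std(φ)` with the std taken as the RMS deviation of
  the complex values about their mean.  Channels at or above 3.08 are
  flagged contaminated.
- `artifact_summary`: homogeneity `1 − Nc·var(ϑ/‖ϑ‖)` (uniform
  contamination → 1, one-hot → 1/Nc) and strength `mean(ϑ)`;
  `clean_electrode_gain`: change in the percentage of clean channels.

## Baselines

CAR is the projector `I − J/Nc` applied per modality.  The PCA+ICA
pipeline high-passes at 2 Hz, z-scores, reduces to 99% explained variance,
unmixes with a seeded FastICA (≤ 500 iterations, tol 1e-7;
non-convergence is flagged and the best iterate used), scores components
by PLV against the SAFB-filtered audio, and removes the top components
using the same elbow rule as PCD so the two low-rank pipelines are
comparable.

## Numerical choices and edge cases

- All temporal filters are zero-phase (forward–backward); notch residuals
  concentrate in boundary ringing, so steady-state attenuation is the
  meaningful figure on short epochs.
- SSD filter signs are normalized (largest-magnitude entry positive) and
  scaled to `wᵀΣ_noise w = 1`; eigenvalue ties make individual filters
  arbitrary within the eigenspace, but the retained subspace is stable.
- Degenerate inputs raise: single-channel CAR/SSD, all-zero eigenvalues,
  zero-variance ground truth, zero-max signals, constant audio.
- With `k = 1` the PCO stage is a sign choice and the elbow clamps to
  `m = 1`; rank-deficient whitening directions are zeroed rather than
  amplified.

## Problem sizes

The packaged experiments use desk-scale versions of the study conditions:
sessions of 10–20 trials, 3 s at 1 kHz, 8–32 channels, 3 neural sources
plus 1 artifact source, AGR in [−20, 20] dB.  One trial fits in tens of
milliseconds, so a full session including all benchmarks runs in seconds.

## Known limitations

- Performance degrades for broadband artifacts (an SSD limitation); the
  colored-noise scenarios use dF = 8 Hz half-bandwidth where recovery is
  reliable.
- The audio is assumed to be an undistorted, delay-free proxy of the
  artifact source; systematic distortions are not modeled.
- Per-trial fitting is required because the artifact's phase relation to
  the audio is not stable across trials; no online/streaming mode.
- The elbow rule needs at least one removable component; on genuinely
  artifact-free data PCD still removes the top phase-coupled component
  (use the `fixed_m` override or the AGR → −∞ benchmark to quantify the
  cost, which the preservation tests show to be small).
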