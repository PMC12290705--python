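# pcdenoise

Removal of acoustic-induced speech-vibration artifacts from multichannel
intracranial electrophysiology by **phase-coupling decomposition (PCD)**.

During overt speech, mechanical vibrations enter the recording chain and
show up in ECoG/LFP channels as a narrow-band artifact at the speaker's
voice fundamental F0 — squarely inside the high-gamma band (60–250 Hz)
that speech decoding relies on.  Because the artifact is coherent with
the produced audio, it can inflate apparent "neural" decoding
performance.  This package is for researchers working with intracranial
recordings of speech tasks who need to remove that artifact without
destroying the overlapping physiological gamma activity.

## Method

Given a recording `X ∈ R^{Nc×Ns}` and a synchronized audio trace
`z ∈ R^{Ns}`, PCD builds a spatial unmixing matrix in four steps:

1. **SAFB estimation** — find F0 as the dominant peak of the audio Welch
   spectrum in 50–250 Hz, and fit a Gaussian to get the speech-artifact
   frequency band `Fc ± ΔFc`;
2. **SSD** — solve `Σ_signal w = λ Σ_noise w` (band-passed vs band-stopped
   covariances) and keep `k = ⌊(Σλ)²/Σλ²⌋` components;
3. **PCO** — in the whitened analytic SSD space, find filters maximizing
   the mean vector length
   `MVL(w) = |1/Ns Σ_t z_t · (wᵀy_t)/|wᵀy_t||`
   by multi-restart quasi-Newton ascent with deflation;
4. **Low-rank reconstruction** — compose
   `W_pcd = W_ssd · blockdiag(Mᵀ W_pco, I)`, take `A_pcd = pinv(W_pcdᵀ)`,
   pick the number of artifact components `m` at the elbow of the MVL
   trace, and reconstruct `X_denoised = Ã_pcd W̃_pcdᵀ X` with those
   components zeroed.

The package also ships the baseline denoisers used for comparison (CAR as
an explicit spatial projector, and a PCA+ICA low-rank pipeline with
audio-phase component scoring), the evaluation metrics (coherence, PLV,
PCA-loading cosine similarity, intertrial phase consistency with the 3.08
contamination threshold), and a ground-truth simulator of contaminated
sessions.  See `docs/methods.md` for the full model description.

## Worked example

```python
import pcdenoise as pcd
from pcdenoise.metrics import band_mean_msce, loading_cosine_similarity

# a simulated 16-channel trial: 3 gamma-burst sources + 1 audio-like
# artifact mixed at 0 dB artifact-to-gamma ratio, with known ground truth
trial, truth = pcd.simulate_trial(
    pcd.TrialConfig(scenario="realistic", seed=3, agr_db=0.0)
)

model = pcd.PhaseCouplingDecomposition.from_trial(trial)
res = model.fit()
print(res.summary())

s_hat = res.artifact_source()                 # recovered artifact source
X_denoised = res.denoise()                    # cleaned wide epoch

s_true = truth.s_artifact[res.wide_slice]
print(band_mean_msce(s_true, s_hat, trial.fs, res.band.lo, res.band.hi))
gt = truth.clean_mixture()[:, res.wide_slice]
print(loading_cosine_similarity(gt, X_denoised)[1])
```

Output:

```
Phase-Coupling Decomposition Results
================================================
channels:            16
SAFB (Hz):           137.93 - 157.51  (Fc=147.72, dFc=9.79)
SSD components (k):  1  [participation ratio]
removed (m):         1  [elbow]
PCO restarts:        10  (seed 0)
------------------------------------------------
comp   SSD eigval      MVL
   1        23.55     0.4129
================================================
0.9999
0.9998
```

The summary reads: the audio spectrum placed the artifact band at
roughly 138–158 Hz; one spatial component dominated the in-band SNR
(participation ratio k = 1, eigenvalue 23.6) and was phase-coupled to the
audio (MVL 0.41), so one component was removed.  The two numbers below
are the evaluation against ground truth: the recovered artifact source is
nearly identical to the true one inside the artifact band (coherence
0.9999), and the denoised data's leading PCA subspace matches the
artifact-free ground truth (cosine similarity 0.9998) — the artifact is
gone and the simulated gamma activity is intact.

A command-line interface wraps the same pipeline:

```sh
pcdenoise simulate --scenario realistic --n-trials 10 --agr-db 0 --seed 1 --out session.h5
pcdenoise denoise --in session.h5 --method pcd --out denoised.h5
pcdenoise evaluate --raw session.h5 --denoised denoised.h5 --out report.json
```

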