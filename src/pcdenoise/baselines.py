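"""Reference denoisers: common average reference and PCA+ICA.

CAR subtracts the per-sample channel mean — an idempotent spatial
projector ``I - J/Nc``.  The PCA+ICA pipeline high-passes, z-scores,
reduces to the components explaining 99% of variance, unmixes them with a
seeded ICA, scores each independent component by its phase locking to the
audio inside the speech-artifact band, removes the top-scoring components
(same elbow rule as PCD, for comparability) and reconstructs back to
channel space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import ArtifactBand
from .metrics import plv
from .pco import select_artifact_components

__all__ = ["car", "car_matrix", "ica_denoise", "IcaReport"]


def car_matrix(n_channels: int) -> np.ndarray:
    """The CAR projector ``I - J/Nc`` (J the all-ones matrix)."""
    if n_channels < 2:
        raise ValueError("CAR needs at least 2 channels")
    return np.eye(n_channels) - np.ones((n_channels, n_channels)) / n_channels


def car(X: np.ndarray) -> np.ndarray:
    """Common average reference: remove the per-sample channel mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("CAR needs at least 2 channels")
    return X - X.mean(axis=0, keepdims=True)


@dataclass
class IcaReport:
    """Per-component audio PLVs and the indices removed."""

    plvs: np.ndarray
    removed: list[int]
    n_pca: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "plvs": [float(v) for v in self.plvs],
            "removed": [int(i) for i in self.removed],
            "n_pca": int(self.n_pca),
            "converged": bool(self.converged),
        }


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, (lo, hi), "bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def ica_denoise(
    X: np.ndarray,
    audio: np.ndarray,
    fs: float,
    band: ArtifactBand,
    seed: int = 0,
    n_remove: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple[np.ndarray, IcaReport]:
    """PCA+ICA low-rank denoising with audio-phase component scoring.

    Returns the denoised channels-x-samples data (on the original scale)
    and a report with the per-component PLVs and removed indices.
    ``n_remove=None`` applies the same elbow rule as PCD to the sorted
    PLV trace; ``n_remove=0`` is the round-trip (nothing removed).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    audio = np.asarray(audio, dtype=float).ravel()
    if X.shape[0] < 3:
        raise ValueError("PCA+ICA needs at least 3 channels")
    if audio.size != X.shape[1]:
        raise ValueError("audio and recording lengths differ")

    sos = signal.butter(4, 2.0, "highpass", fs=fs, output="sos")
    Xh = signal.sosfiltfilt(sos, X, axis=-1)
    mu = Xh.mean(axis=1, keepdims=True)
    sd = Xh.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xz = (Xh - mu) / sd

    pca = PCA(n_components=0.99, svd_solver="full")
    scores = pca.fit_transform(Xz.T)  # samples x n_pca
    n_pca = scores.shape[1]

    converged = True
    ica = FastICA(
        n_components=n_pca,
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(scores)  # samples x n_pca
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "ICA did not converge; using best iterate", stacklevel=2
            )

    audio_band = _bandpass(audio, fs, band.lo, band.hi)
    plvs = np.array(
        [plv(_bandpass(S[:, j], fs, band.lo, band.hi), audio_band) for j in range(n_pca)]
    )
    order = np.argsort(plvs)[::-1]
    if n_remove is None:
        n_remove = select_artifact_components(plvs[order]).m
    removed = [int(i) for i in order[:n_remove]]

    S_clean = S.copy()
    S_clean[:, removed] = 0.0
    scores_clean = ica.inverse_transform(S_clean)
    Xz_clean = pca.inverse_transform(scores_clean).T
    X_clean = Xz_clean * sd + mu
    report = IcaReport(plvs=plvs, removed=removed, n_pca=n_pca, converged=converged)
    return X_clean, report
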