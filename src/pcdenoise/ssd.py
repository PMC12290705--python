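"""Spatiospectral decomposition (SSD).

SSD finds spatial filters ``w`` that maximize narrow-band power against
the power everywhere else, by solving the generalized eigenvalue problem

    Sigma_signal w = lambda Sigma_noise w,

where ``Sigma_signal`` is the channel covariance of the band-passed data
(the SAFB here) and ``Sigma_noise`` the covariance of the band-stopped
data (all frequencies except the SAFB).  Eigenvalues are in-band SNR
ratios; filters are returned sorted by decreasing eigenvalue.  The number
of components worth keeping is chosen by the participation ratio of the
eigenvalue spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .containers import ArtifactBand

__all__ = [
    "SSDModel",
    "split_signal_noise",
    "fit_ssd",
    "participation_ratio",
    "transform_ssd",
]

#: Butterworth order per pass (zero-phase doubles the effective order)
FILTER_ORDER = 4
#: Tikhonov ridge applied to the noise covariance, relative to trace/Nc
RIDGE = 1e-6


@dataclass
class SSDModel:
    """Fitted SSD: filters, eigenvalue spectrum, band and retained rank."""

    W: np.ndarray  # channels x channels, columns sorted by decreasing eigval
    eigvals: np.ndarray
    band: ArtifactBand
    k: int

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def W_k(self) -> np.ndarray:
        """The retained filters (first ``k`` columns)."""
        return self.W[:, : self.k]


def _bandpass_sos(band: ArtifactBand, fs: float, order: int):
    return signal.butter(order, (band.lo, band.hi), "bandpass", fs=fs, output="sos")


def _bandstop_sos(band: ArtifactBand, fs: float, order: int):
    return signal.butter(order, (band.lo, band.hi), "bandstop", fs=fs, output="sos")


def _stable_filtfilt(make_sos, x: np.ndarray, order: int) -> np.ndarray:
    """Zero-phase filter, stepping the order down to 2 if unstable."""
    for o in range(order, 1, -1):
        sos = make_sos(o)
        y = signal.sosfiltfilt(sos, x, axis=-1)
        if np.all(np.isfinite(y)):
            return y
    raise RuntimeError("could not realize a stable filter at order >= 2")


def split_signal_noise(
    X: np.ndarray, band: ArtifactBand, fs: float, order: int = FILTER_ORDER
) -> tuple[np.ndarray, np.ndarray]:
    """Separate in-band and out-of-band contributions of ``X``.

    ``X_signal`` is the zero-phase band-pass over ``[lo, hi]``; ``X_noise``
    the band-stop complement at the same edges.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    band.validate(fs)
    x_sig = _stable_filtfilt(lambda o: _bandpass_sos(band, fs, o), X, order)
    x_noi = _stable_filtfilt(lambda o: _bandstop_sos(band, fs, o), X, order)
    return x_sig, x_noi


def fit_ssd(
    X: np.ndarray, band: ArtifactBand, fs: float, order: int = FILTER_ORDER
) -> SSDModel:
    """Fit SSD on ``channels x samples`` data for the given band.

    The noise covariance receives a small Tikhonov ridge
    (``1e-6 * trace / Nc``) before the symmetric-definite GEVD is solved.
    Filter signs are normalized so each column's largest-magnitude entry is
    positive; scaling is unit norm in the whitened metric
    ``w^T Sigma_noise w = 1``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    nc, ns = X.shape
    if nc < 2:
        raise ValueError("SSD needs at least 2 channels")
    x_sig, x_noi = split_signal_noise(X, band, fs, order)
    cov_s = x_sig @ x_sig.T / ns
    cov_n = x_noi @ x_noi.T / ns
    ridge = RIDGE * np.trace(cov_n) / nc
    cov_n_r = cov_n + ridge * np.eye(nc)
    try:
        eigvals, W = linalg.eigh(cov_s, cov_n_r)
    except linalg.LinAlgError as exc:
        rank = np.linalg.matrix_rank(cov_n_r)
        raise linalg.LinAlgError(
            f"noise covariance singular after ridge (rank {rank}/{nc})"
        ) from exc
    idx = np.argsort(eigvals)[::-1]
    eigvals, W = eigvals[idx], W[:, idx]
    # eigh(cov_s, cov_n_r) already yields w^T cov_n_r w = 1 per column
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(nc)])
    signs[signs == 0] = 1.0
    W = W * signs
    k = participation_ratio(np.clip(eigvals, 0.0, None))
    return SSDModel(W=W, eigvals=eigvals, band=band, k=k)


def participation_ratio(eigvals: np.ndarray) -> int:
    """Effective dimensionality: ``floor((sum l)^2 / sum l^2)``, in [1, Nc]."""
    lam = np.asarray(eigvals, dtype=float)
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    s2 = float(np.sum(lam**2))
    if s2 == 0.0:
        raise ValueError("all-zero eigenvalue spectrum")
    pr = int(np.floor(float(np.sum(lam)) ** 2 / s2))
    return int(np.clip(pr, 1, lam.size))


def transform_ssd(X: np.ndarray, model: SSDModel, k: int | None = None) -> np.ndarray:
    """Project data onto the first ``k`` SSD components: ``W_k^T X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != model.n_channels:
        raise ValueError(
            f"channel mismatch: data has {X.shape[0]}, model {model.n_channels}"
        )
    k = model.k if k is None else k
    return model.W[:, :k].T @ X
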