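"""Evaluation metrics: signal agreement, neural preservation and
intertrial phase consistency (ITPC) artifact quantification.

Agreement between a denoised signal and its ground truth is measured in
the time domain (variance-normalized chi-square, max-normalized MSE), the
frequency domain (magnitude-squared coherence) and the phase domain
(phase-locking value).  Neural preservation compares PCA loading
directions through the absolute cosine similarity.  Artifact presence per
channel is quantified by the ITPC of the channel's analytic phase against
the audio across trials; channels at or above 3.08 count as contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .containers import TrialEpoch
from .pco import analytic_signal

__all__ = [
    "ItpcReport",
    "chi2_similarity",
    "msce",
    "plv",
    "loading_cosine_similarity",
    "itpc",
    "artifact_summary",
    "clean_electrode_gain",
    "normalized_mse",
    "ITPC_THRESHOLD",
    "ITPC_BAND",
]

#: ITPC significance threshold flagging a contaminated channel
ITPC_THRESHOLD = 3.08
#: plausible SAFB range (Hz) used for the ITPC band-pass
ITPC_BAND = (70.0, 240.0)


@dataclass
class ItpcReport:
    """Per-channel ITPC values and session-level artifact summaries."""

    itpc: np.ndarray
    significant: np.ndarray
    pct_clean: float
    homogeneity: float
    strength: float

    def to_dict(self) -> dict:
        return {
            "itpc": [float(v) for v in self.itpc],
            "significant": [bool(v) for v in self.significant],
            "pct_clean": float(self.pct_clean),
            "homogeneity": float(self.homogeneity),
            "strength": float(self.strength),
            "threshold": ITPC_THRESHOLD,
        }


def chi2_similarity(X: np.ndarray, X_gt: np.ndarray) -> np.ndarray:
    """Per-channel mean squared deviation over ground-truth variance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X_gt = np.atleast_2d(np.asarray(X_gt, dtype=float))
    if X.shape != X_gt.shape:
        raise ValueError("shapes differ")
    var = np.var(X_gt, axis=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance ground-truth channel")
    return np.mean((X - X_gt) ** 2, axis=1) / var


def msce(
    a: np.ndarray, b: np.ndarray, fs: float, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence ``|P_ab|^2 / (P_aa P_bb)`` on a Welch grid.

    Returns ``(freqs, coherence)``; bins with zero power report 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("lengths differ")
    if nperseg is None:
        nperseg = min(256, a.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        f, coh = signal.coherence(a, b, fs=fs, nperseg=nperseg)
    return f, np.nan_to_num(coh, nan=0.0)


def band_mean_msce(
    a: np.ndarray, b: np.ndarray, fs: float, lo: float, hi: float, **kw
) -> float:
    """Mean coherence over ``[lo, hi]`` Hz."""
    f, coh = msce(a, b, fs, **kw)
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise ValueError("no coherence bins inside the requested band")
    return float(np.mean(coh[sel]))


def plv(a: np.ndarray, b: np.ndarray) -> float:
    """Phase-locking value from the instantaneous analytic phases."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("lengths differ")
    pa = np.angle(analytic_signal(a))
    pb = np.angle(analytic_signal(b))
    return float(np.abs(np.mean(np.exp(1j * (pa - pb)))))


def loading_cosine_similarity(
    X_gt: np.ndarray, X_test: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, float]:
    """Absolute cosine similarity of leading PCA loadings, fitted separately.

    PCA runs on each dataset independently (channels are the variables);
    returns the per-component similarities and their mean.  The absolute
    value removes the arbitrary loading sign.
    """
    X_gt = np.atleast_2d(np.asarray(X_gt, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_gt.shape[0] != X_test.shape[0]:
        raise ValueError("channel counts differ")
    if X_gt.shape[0] < n_components:
        raise ValueError("fewer channels than requested components")
    L_gt = PCA(n_components=n_components).fit(X_gt.T).components_
    L_ts = PCA(n_components=n_components).fit(X_test.T).components_
    num = np.abs(np.sum(L_gt * L_ts, axis=1))
    den = np.linalg.norm(L_gt, axis=1) * np.linalg.norm(L_ts, axis=1)
    cs = num / den
    return cs, float(np.mean(cs))


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, (lo, hi), "bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def trial_phase(
    X: np.ndarray, audio: np.ndarray, fs: float, band=ITPC_BAND
) -> np.ndarray:
    """Per-channel complex audio-phase estimate of one trial.

    ``phi = sum_t y_t z_t / (||y|| ||z||)`` with ``y`` the band-passed
    analytic channel and ``z`` the band-passed audio.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = analytic_signal(_bandpass(X, fs, *band))
    z = _bandpass(np.asarray(audio, dtype=float).ravel(), fs, *band)
    num = y @ z
    den = np.linalg.norm(y, axis=1) * np.linalg.norm(z)
    return num / den


def itpc(trials: list[TrialEpoch], band=ITPC_BAND) -> ItpcReport:
    """Intertrial phase consistency of each channel with the audio.

    Per trial the complex phase estimate ``phi_e`` is computed; across
    trials ``ITPC = |mean(phi)| / std(phi)`` with the std taken as the RMS
    deviation of the complex values about their mean.  Channels with
    ITPC >= 3.08 are flagged contaminated; identical phases across trials
    give infinite ITPC (flagged).
    """
    if not trials:
        raise ValueError("no trials")
    phis = np.stack(
        [trial_phase(t.X, t.audio, t.fs, band) for t in trials], axis=0
    )  # trials x channels
    mean_phi = phis.mean(axis=0)
    dev = np.sqrt(np.mean(np.abs(phis - mean_phi[None, :]) ** 2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.abs(mean_phi) / dev
    vals = np.where(dev == 0, np.inf, vals)
    sig = vals >= ITPC_THRESHOLD
    pct_clean = 100.0 * float(np.mean(~sig))
    finite = vals[np.isfinite(vals)]
    if finite.size and np.any(finite > 0):
        hom, stren = artifact_summary(finite)
    else:  # all-infinite pathological case
        hom, stren = 1.0, float("inf")
    return ItpcReport(
        itpc=vals,
        significant=sig,
        pct_clean=pct_clean,
        homogeneity=hom,
        strength=stren,
    )


def artifact_summary(itpc_values: np.ndarray) -> tuple[float, float]:
    """Artifact homogeneity ``1 - Nc*var(v/||v||)`` and strength ``mean(v)``.

    A unit vector over ``Nc`` entries has variance in ``[0, 1/Nc]``;
    scaling by ``Nc`` maps uniform contamination to homogeneity 1 and a
    single contaminated channel to ``1/Nc``.
    """
    v = np.asarray(itpc_values, dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("ITPC values must be nonempty and nonnegative")
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("all-zero ITPC vector")
    homogeneity = 1.0 - v.size * float(np.var(v / nrm))
    return homogeneity, float(np.mean(v))


def clean_electrode_gain(before: ItpcReport, after: ItpcReport) -> float:
    """Change in percentage of clean channels, after minus before."""
    if before.itpc.size != after.itpc.size:
        raise ValueError("channel sets differ")
    if before.itpc.size == 0:
        raise ValueError("empty report")
    return float(after.pct_clean - before.pct_clean)


def normalized_mse(a: np.ndarray, b: np.ndarray) -> float:
    """MSE after dividing each signal by its maximum absolute value."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ma, mb = np.max(np.abs(a)), np.max(np.abs(b))
    if ma == 0 or mb == 0:
        raise ValueError("zero-max input")
    return float(np.mean((a / ma - b / mb) ** 2))
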