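"""Phase-coupling decomposition (PCD): model, results and trial pipeline.

PCD composes two spatial-filtering stages into a single unmixing matrix:
SSD isolates the speech-artifact frequency band (SAFB) spatially, PCO then
finds, inside the retained SSD subspace, the directions maximally
phase-coupled to the produced audio.  Denoising is low-rank
reconstruction: the top-MVL components are zeroed from the factorization

    S_hat      = W_pcd^T X
    X_denoised = A_pcd[:, m:] @ W_pcd[:, m:]^T @ X,

with ``A_pcd`` the Moore-Penrose pseudoinverse chosen so the forward and
backward models are mutually consistent (``A_pcd @ W_pcd^T = I`` for full
rank).

The user-facing surface follows the model/results convention:
``PhaseCouplingDecomposition(X, audio, fs, onset_index).fit()`` returns a
:class:`PCDResults` holding the matrices, the per-component diagnostics
and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .containers import ArtifactBand, TrialEpoch
from .pco import (
    ArtifactSelection,
    PCOModel,
    analytic_signal,
    fit_pco,
    select_artifact_components,
)
from .safband import estimate_safband
from .ssd import SSDModel, fit_ssd, transform_ssd
from .containers import AudioTrace

__all__ = [
    "PCDConfig",
    "PhaseCouplingDecomposition",
    "PCDResults",
    "preprocess",
    "compose_unmixing",
    "mixing_from_unmixing",
    "lowrank_reconstruct",
    "denoise",
    "run_pcd_trial",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCDConfig:
    """Tunable pipeline parameters.

    ``fit_window`` bounds the epoch (seconds relative to speech onset) the
    model is fitted on; ``wide_window`` the epoch the learned transform is
    applied to.  ``fixed_m`` overrides the elbow rule for the number of
    removed components.
    """

    fit_window: tuple[float, float] = (-0.5, 2.0)
    wide_window: tuple[float, float] = (-6.0, 6.0)
    n_restarts: int = 10
    seed: int = 0
    filter_order: int = 4
    search_band: tuple[float, float] = (50.0, 250.0)
    fixed_m: int | None = None
    preprocess: bool = True

    def __post_init__(self) -> None:
        if self.fit_window[0] >= self.fit_window[1]:
            raise ValueError("fit window must be well ordered")
        if self.wide_window[0] >= self.wide_window[1]:
            raise ValueError("wide window must be well ordered")

    @classmethod
    def from_dict(cls, d: dict) -> "PCDConfig":
        d = dict(d)
        for key in ("fit_window", "wide_window", "search_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def preprocess(X: np.ndarray, fs: float) -> np.ndarray:
    """Standard conditioning: 2 Hz high-pass plus 60 Hz line-notch comb.

    Zero-phase throughout; notches at 60, 120, 180 and 240 Hz (a notch at
    or above Nyquist is skipped with a log message).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sos = signal.butter(4, 2.0, "highpass", fs=fs, output="sos")
    Y = signal.sosfiltfilt(sos, X, axis=-1)
    for f0 in (60.0, 120.0, 180.0, 240.0):
        if f0 >= fs / 2:
            logger.info("skipping notch at %g Hz (>= Nyquist)", f0)
            continue
        b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
        Y = signal.filtfilt(b, a, Y, axis=-1)
    return Y


def compose_unmixing(
    M_white: np.ndarray, W_ssd: np.ndarray, W_pco: np.ndarray, k: int
) -> np.ndarray:
    """Compose the full-channel PCD unmixing matrix.

    The k-dimensional whitened PCO solution is embedded block-diagonally:
    PCO (through its whitening) acts on the first ``k`` SSD components,
    the identity on the remainder, so that
    ``W_pcd^T X = blockdiag(W_pco^T M, I) @ W_ssd^T X``.
    """
    W_ssd = np.asarray(W_ssd, dtype=float)
    nc = W_ssd.shape[0]
    M_white = np.asarray(M_white, dtype=float)
    W_pco = np.asarray(W_pco, dtype=float)
    if not (M_white.shape == (k, k) and W_pco.shape == (k, k)):
        raise ValueError("whitening and PCO blocks must be k x k")
    if k > nc:
        raise ValueError("k cannot exceed the channel count")
    block = np.eye(nc)
    block[:k, :k] = M_white.T @ W_pco
    return W_ssd @ block


def mixing_from_unmixing(W_pcd: np.ndarray) -> np.ndarray:
    """Mixing matrix via the Moore-Penrose pseudoinverse.

    Defined so that the forward/backward pair ``X = A S``, ``S = W^T X``
    is self-consistent: ``A = pinv(W^T)``, which reduces to ``A = W`` for
    orthonormal ``W``.
    """
    W_pcd = np.asarray(W_pcd, dtype=float)
    if not np.all(np.isfinite(W_pcd)):
        raise ValueError("non-finite unmixing matrix")
    return np.linalg.pinv(W_pcd.T)


def lowrank_reconstruct(
    X: np.ndarray, W: np.ndarray, A: np.ndarray, m: int
) -> np.ndarray:
    """Reconstruct ``X`` with the first ``m`` components zeroed."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    nc = W.shape[0]
    if not 0 <= m < nc:
        raise ValueError("m must satisfy 0 <= m < channels")
    return A[:, m:] @ (W[:, m:].T @ X)


@dataclass
class PCDResults:
    """Fitted PCD pipeline: matrices, submodels and diagnostics.

    Attributes
    ----------
    W_pcd, A_pcd : channel-space unmixing and mixing matrices, columns
        ordered artifact-first (descending MVL inside the SSD block).
    ssd, pco : the fitted stage models.
    selection : number of components removed at reconstruction.
    band : the estimated speech-artifact frequency band.
    """

    W_pcd: np.ndarray
    A_pcd: np.ndarray
    ssd: SSDModel
    pco: PCOModel
    selection: ArtifactSelection
    band: ArtifactBand
    config: PCDConfig
    fs: float
    fit_slice: slice = field(default_factory=lambda: slice(None))
    wide_slice: slice = field(default_factory=lambda: slice(None))
    _X_pre: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.ssd.k

    @property
    def m(self) -> int:
        return self.selection.m

    @property
    def mvls(self) -> np.ndarray:
        return self.pco.mvls

    def sources(self, X: np.ndarray | None = None) -> np.ndarray:
        """Estimated component time courses ``S_hat = W_pcd^T X``.

        Defaults to the preprocessed wide-window data the model was fitted
        from; row 0 is the strongest phase-coupled (artifact) component.
        """
        X = self._default_X(X)
        return self.W_pcd.T @ X

    def artifact_source(self, X: np.ndarray | None = None) -> np.ndarray:
        """Top phase-coupled component time course (the artifact estimate)."""
        return self.sources(X)[0]

    def denoise(self, X: np.ndarray | None = None, m: int | None = None) -> np.ndarray:
        """Low-rank reconstruction with the top ``m`` components removed."""
        X = self._default_X(X)
        m = self.m if m is None else m
        return lowrank_reconstruct(X, self.W_pcd, self.A_pcd, m)

    def _default_X(self, X: np.ndarray | None) -> np.ndarray:
        if X is not None:
            return np.atleast_2d(np.asarray(X, dtype=float))
        if self._X_pre is None:
            raise ValueError("no data attached; pass X explicitly")
        return self._X_pre[:, self.wide_slice]

    def summary(self) -> str:
        lines = [
            "Phase-Coupling Decomposition Results",
            "=" * 48,
            f"channels:            {self.ssd.n_channels}",
            f"SAFB (Hz):           {self.band.lo:.2f} - {self.band.hi:.2f}"
            f"  (Fc={self.band.fc:.2f}, dFc={self.band.dfc:.2f})",
            f"SSD components (k):  {self.k}  [participation ratio]",
            f"removed (m):         {self.m}  [{self.selection.method}]",
            f"PCO restarts:        {self.pco.n_restarts}  (seed {self.pco.seed})",
            "-" * 48,
            "comp   SSD eigval      MVL",
        ]
        for i in range(self.k):
            lines.append(
                f"{i + 1:>4}   {self.ssd.eigvals[i]:>10.4g}   {self.mvls[i]:>8.4f}"
            )
        lines.append("=" * 48)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "band": self.band.to_dict(),
            "k": int(self.k),
            "m": int(self.m),
            "selection_method": self.selection.method,
            "eigvals": [float(v) for v in self.ssd.eigvals],
            "mvls": [float(v) for v in self.mvls],
            "n_restarts": int(self.pco.n_restarts),
            "seed": int(self.pco.seed),
            "fit_window": list(self.config.fit_window),
            "wide_window": list(self.config.wide_window),
        }


class PhaseCouplingDecomposition:
    """Supervised spatial-filter model of acoustic contamination.

    Parameters
    ----------
    X : array, channels x samples
        Multichannel recording (all modalities stacked as one sensor
        space).
    audio : array, samples
        Synchronized produced-audio trace (the artifact-source proxy).
    fs : float
        Sampling rate, Hz.
    onset_index : int, optional
        Produced-speech onset sample; fitting and application windows are
        placed relative to it.  Defaults to sample 0 with windows clipped
        to the recording.
    config : PCDConfig, optional
    """

    def __init__(
        self,
        X: np.ndarray,
        audio: np.ndarray,
        fs: float,
        onset_index: int | None = None,
        config: PCDConfig | None = None,
    ) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.audio = np.asarray(audio, dtype=float).ravel()
        if self.audio.size != self.X.shape[1]:
            raise ValueError("audio and recording lengths differ")
        if self.X.shape[0] < 3:
            raise ValueError("PCD needs at least 3 channels")
        self.fs = float(fs)
        self.onset_index = 0 if onset_index is None else int(onset_index)
        self.config = config or PCDConfig()

    @classmethod
    def from_trial(
        cls, trial: TrialEpoch, config: PCDConfig | None = None
    ) -> "PhaseCouplingDecomposition":
        return cls(trial.X, trial.audio, trial.fs, trial.onset_index, config)

    def _window(self, bounds: tuple[float, float]) -> slice:
        n = self.X.shape[1]
        start = self.onset_index + int(round(bounds[0] * self.fs))
        stop = self.onset_index + int(round(bounds[1] * self.fs))
        return slice(max(start, 0), min(stop, n))

    def fit(self, seed: int | None = None) -> PCDResults:
        """Run the four pipeline stages and return the fitted results.

        1. estimate the SAFB from the audio spectrum;
        2. SSD on the preprocessed fit-window data, rank ``k`` by
           participation ratio;
        3. PCO of the analytic SSD projection against the z-scored audio;
        4. compose unmixing/mixing matrices and select ``m`` by the elbow
           of the MVL trace.
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        fit_sl = self._window(cfg.fit_window)
        wide_sl = self._window(cfg.wide_window)
        if fit_sl.stop - fit_sl.start < 16:
            raise ValueError("fit window too short")

        audio_fit = self.audio[fit_sl]
        band = estimate_safband(AudioTrace(audio_fit, self.fs))

        X_pre = preprocess(self.X, self.fs) if cfg.preprocess else self.X
        X_fit = X_pre[:, fit_sl]

        ssd = fit_ssd(X_fit, band, self.fs, order=cfg.filter_order)
        k = ssd.k

        mu, sd = float(np.mean(audio_fit)), float(np.std(audio_fit))
        if sd == 0:
            raise ValueError("audio is constant over the fit window")
        z = (audio_fit - mu) / sd

        Y_ssd = analytic_signal(transform_ssd(X_fit, ssd, k))
        pco = fit_pco(Y_ssd, z, n_restarts=cfg.n_restarts, seed=cfg.seed)

        if cfg.fixed_m is not None:
            selection = select_artifact_components(
                pco.mvls, method="fixed", fixed_m=cfg.fixed_m
            )
        else:
            selection = select_artifact_components(pco.mvls)

        W_pcd = compose_unmixing(pco.M_white, ssd.W, pco.W, k)
        A_pcd = mixing_from_unmixing(W_pcd)
        return PCDResults(
            W_pcd=W_pcd,
            A_pcd=A_pcd,
            ssd=ssd,
            pco=pco,
            selection=selection,
            band=band,
            config=cfg,
            fs=self.fs,
            fit_slice=fit_sl,
            wide_slice=wide_sl,
            _X_pre=X_pre,
        )


def denoise(
    X: np.ndarray, results: PCDResults, m: int | None = None
) -> np.ndarray:
    """Functional form of :meth:`PCDResults.denoise` for explicit data."""
    return results.denoise(X, m=m)


def run_pcd_trial(
    trial: TrialEpoch, cfg: PCDConfig | None = None
) -> tuple[np.ndarray, PCDResults]:
    """Fit PCD on one trial and denoise its wide application epoch.

    Returns the denoised wide-window data (channels x samples, clipped to
    the trial bounds) and the fitted results.
    """
    model = PhaseCouplingDecomposition.from_trial(trial, cfg)
    res = model.fit()
    return res.denoise(), res
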