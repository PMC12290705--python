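"""Core data containers shared across the pipeline.

Conventions: data arrays are ``channels x samples`` float64; sample indices
are 0-based; epochs are half-open ``[start, stop)``; times are seconds
relative to the produced-speech onset where an onset is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "AudioTrace",
    "ArtifactBand",
    "TrialEpoch",
    "SimTruth",
]


@dataclass
class Recording:
    """Multichannel voltage time series (``channels x samples``)."""

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)
    modalities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.n_channels)]
        if not self.modalities:
            self.modalities = ["generic"] * self.n_channels
        if len(self.ch_names) != self.n_channels:
            raise ValueError("channel-name count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class AudioTrace:
    """Single-channel produced-audio waveform, time-aligned to a Recording."""

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class ArtifactBand:
    """Speech-artifact frequency band (SAFB): ``Fc +/- dFc`` in Hz.

    ``dFc`` is the fitted full width at half maximum of the audio-spectrum
    peak around the voice fundamental, so the total band width is 2*FWHM.
    """

    fc: float
    dfc: float

    def __post_init__(self) -> None:
        if self.dfc <= 0:
            raise ValueError("band half-extent must be positive")
        if self.fc - self.dfc <= 0:
            raise ValueError("band lower edge must be positive")

    @property
    def lo(self) -> float:
        return self.fc - self.dfc

    @property
    def hi(self) -> float:
        return self.fc + self.dfc

    def validate(self, fs: float) -> "ArtifactBand":
        if self.hi >= fs / 2:
            raise ValueError(
                f"band upper edge {self.hi:g} Hz exceeds Nyquist {fs / 2:g} Hz"
            )
        return self

    def to_dict(self) -> dict:
        return {"fc": self.fc, "dfc": self.dfc, "lo": self.lo, "hi": self.hi}


@dataclass
class TrialEpoch:
    """One trial: recording + aligned audio + produced-speech onset sample."""

    X: np.ndarray
    audio: np.ndarray
    onset_index: int
    fs: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.audio = np.asarray(self.audio, dtype=float).ravel()
        if self.audio.size != self.X.shape[1]:
            raise ValueError("audio and recording lengths differ")
        if not 0 <= self.onset_index < self.X.shape[1]:
            raise ValueError("onset index out of bounds")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.X.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]


@dataclass
class SimTruth:
    """Ground truth of a simulated trial: sources and mixing matrix.

    The mixed model is ``X = A_mix @ [S_neural; s_artifact]`` with the
    artifact source stored last.  ``agr_db`` is the achieved
    artifact-to-physiological-gamma ratio in dB (in-band 60-200 Hz power of
    the artifact over the mean in-band power of the neural sources).
    """

    S_neural: np.ndarray
    s_artifact: np.ndarray
    A_mix: np.ndarray
    agr_db: float
    fs: float

    def __post_init__(self) -> None:
        self.S_neural = np.atleast_2d(np.asarray(self.S_neural, dtype=float))
        self.s_artifact = np.asarray(self.s_artifact, dtype=float).ravel()
        n_sources = self.S_neural.shape[0] + 1
        if self.A_mix.shape[1] != n_sources:
            raise ValueError("mixing matrix columns != number of sources")

    @property
    def n_sources(self) -> int:
        return self.S_neural.shape[0] + 1

    def clean_mixture(self) -> np.ndarray:
        """Artifact-free mixture: neural sources through their mixing columns."""
        return self.A_mix[:, :-1] @ self.S_neural

    def artifact_projection(self) -> np.ndarray:
        """Channel-space footprint of the artifact source alone."""
        return np.outer(self.A_mix[:, -1], self.s_artifact)
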