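"""Speech-artifact frequency band (SAFB) estimation from produced audio.

The vibration artifact concentrates around the fundamental frequency of the
speaker's voice.  The band is estimated from the audio power spectrum:
find the dominant peak inside the voice-pitch search range (50-250 Hz by
default), then fit a Gaussian-plus-floor to the spectrum around it.  The
band is ``Fc +/- dFc`` with ``Fc`` the fitted mean and ``dFc`` the fitted
full width at half maximum.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize, signal

from .containers import ArtifactBand, AudioTrace

__all__ = ["estimate_f0", "estimate_safband", "NoF0PeakError"]

logger = logging.getLogger(__name__)

#: voice-pitch search range, Hz
SEARCH_BAND = (50.0, 250.0)
#: Welch settings: 1 s Hann segments, 50% overlap, linear detrend
WELCH_SEGMENT_S = 1.0
#: a peak must exceed the in-band median PSD by this many dB
PROMINENCE_DB = 6.0
#: fallback band half-extent when the Gaussian fit fails, Hz
FALLBACK_DFC = 5.0


class NoF0PeakError(RuntimeError):
    """No prominent spectral peak found in the voice-pitch search band."""


def audio_psd(audio: AudioTrace) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of the detrended audio (1 s Hann segments, 50% overlap)."""
    nperseg = min(int(round(WELCH_SEGMENT_S * audio.fs)), audio.n_samples)
    f, pxx = signal.welch(
        signal.detrend(audio.data),
        fs=audio.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
    )
    return f, pxx


def estimate_f0(
    audio: AudioTrace,
    search_lo: float = SEARCH_BAND[0],
    search_hi: float = SEARCH_BAND[1],
) -> float:
    """Voice fundamental: frequency of the largest prominent PSD peak.

    Raises :class:`NoF0PeakError` when no local maximum inside the search
    band exceeds the in-band median PSD by the prominence threshold.
    """
    if not 0 < search_lo < search_hi < audio.fs / 2:
        raise ValueError("search band must lie within (0, Nyquist)")
    f, pxx = audio_psd(audio)
    sel = (f >= search_lo) & (f <= search_hi)
    if sel.sum() < 3:
        raise ValueError("audio too short: fewer than 3 bins in search band")
    fb, pb = f[sel], pxx[sel]
    floor = np.median(pb)
    peaks, _ = signal.find_peaks(pb, height=floor * 10.0 ** (PROMINENCE_DB / 10.0))
    if peaks.size == 0:
        raise NoF0PeakError(
            f"no F0 peak: no spectral maximum in [{search_lo:g}, {search_hi:g}] Hz "
            f"exceeds the in-band median by {PROMINENCE_DB:g} dB"
        )
    return float(fb[peaks[np.argmax(pb[peaks])]])


def _gaussian_floor(f, amp, mu, sd, floor):
    return amp * np.exp(-((f - mu) ** 2) / (2 * sd**2)) + floor


def fit_gaussian_peak(
    f: np.ndarray, pxx: np.ndarray, f0_hint: float, half_window: float = 20.0
) -> tuple[float, float]:
    """Fit Gaussian + constant floor to a PSD around ``f0_hint``.

    Returns ``(Fc, FWHM)`` of the fitted peak.  Raises ``RuntimeError`` on
    non-convergence.
    """
    sel = (f >= f0_hint - half_window) & (f <= f0_hint + half_window)
    fw, pw = f[sel], pxx[sel]
    if fw.size < 5:
        raise RuntimeError("too few PSD bins around the F0 hint")
    floor0 = float(np.median(pw))
    amp0 = float(pw.max() - floor0)
    p0 = (max(amp0, 1e-300), f0_hint, 2.0, floor0)
    bounds = (
        [0.0, fw[0], 1e-6, 0.0],
        [np.inf, fw[-1], half_window, np.inf],
    )
    popt, _ = optimize.curve_fit(
        _gaussian_floor, fw, pw, p0=p0, bounds=bounds, maxfev=10000
    )
    amp, mu, sd, _ = popt
    if amp <= 0:
        raise RuntimeError("degenerate Gaussian fit (non-positive amplitude)")
    return float(mu), float(2.355 * sd)


def estimate_safband(audio: AudioTrace, f0_hint: float | None = None) -> ArtifactBand:
    """Estimate the SAFB from the audio spectrum.

    ``dFc`` equals the fitted FWHM, floored at two Welch frequency bins.
    Falls back to ``(f0_hint, 5 Hz)`` with a warning when the fit does not
    converge.
    """
    if f0_hint is None:
        f0_hint = estimate_f0(audio)
    f, pxx = audio_psd(audio)
    bin_width = float(f[1] - f[0])
    try:
        fc, fwhm = fit_gaussian_peak(f, pxx, f0_hint)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        logger.warning("Gaussian SAFB fit failed (%s); using fallback band", exc)
        fc, fwhm = float(f0_hint), FALLBACK_DFC
    dfc = max(fwhm, 2.0 * bin_width)
    return ArtifactBand(fc, dfc).validate(audio.fs)
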