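"""Stationary-noise reduction by magnitude-domain spectral subtraction.

Room recordings of sleep breathing carry stationary background noise (wideband
hiss, mains hum). The classic remedy is spectral subtraction: estimate the
noise magnitude spectrum from the quietest stretches of the recording itself,
subtract it frame-by-frame from the STFT magnitude, floor the result to avoid
musical noise, and resynthesize with the original phase.

Denoising runs at speech-processing resolution (512-point FFT, Hanning, 50%
overlap), independent of the coarser 0.5 s feature framing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal
from .config import DenoiseConfig
from .errors import ValidationError


@dataclass
class NoiseProfile:
    """Per-bin noise magnitude estimate (one-sided spectrum, nfft/2+1 bins)."""

    magnitude_spectrum: np.ndarray
    nfft: int
    rate_hz: int

    def __post_init__(self) -> None:
        self.magnitude_spectrum = np.asarray(self.magnitude_spectrum, dtype=np.float64)
        if self.magnitude_spectrum.shape != (self.nfft // 2 + 1,):
            raise ValidationError(
                f"noise profile must have nfft/2+1 = {self.nfft // 2 + 1} bins"
            )
        if np.any(self.magnitude_spectrum < 0):
            raise ValidationError("noise magnitudes must be non-negative")


def _stft(x: np.ndarray, rate_hz: int, nfft: int):
    return sps.stft(
        x, fs=rate_hz, window="hann", nperseg=nfft, noverlap=nfft // 2,
        boundary="zeros", padded=True,
    )


def estimate_noise_profile(
    signal: AudioSignal, quantile: float = 0.1, nfft: int = 512
) -> NoiseProfile:
    """Estimate the stationary noise spectrum from the quietest frames.

    The per-bin magnitude is the mean STFT magnitude over the ``quantile``
    lowest-energy frames — stretches where breathing (and any intermittent
    foreground sound) is absent, leaving only the background process.
    """
    if not (0 < quantile <= 1):
        raise ValidationError("quantile must be in (0, 1]")
    if len(signal) <= nfft:
        raise ValidationError("signal must be longer than one FFT frame")
    _, _, Z = _stft(signal.samples, signal.rate_hz, nfft)
    mag = np.abs(Z)                       # (bins, frames)
    frame_energy = (mag**2).sum(axis=0)
    n_keep = max(1, int(round(quantile * mag.shape[1])))
    quiet = np.argsort(frame_energy, kind="stable")[:n_keep]
    return NoiseProfile(mag[:, quiet].mean(axis=1), nfft, signal.rate_hz)


def spectral_subtract(
    signal: AudioSignal,
    profile: NoiseProfile,
    oversubtraction: float = 1.0,
    floor: float = 0.01,
) -> AudioSignal:
    """Subtract a noise profile from a signal's STFT magnitude.

    Per frame the output magnitude is
    ``min(|X|, max(|X| - oversubtraction*noise, floor*noise))``; the outer
    ``min`` guarantees subtraction never amplifies a bin. Phase is kept and
    the frame stream is overlap-added back to the input length.
    """
    if profile.rate_hz != signal.rate_hz:
        raise ValidationError(
            f"profile rate {profile.rate_hz} != signal rate {signal.rate_hz}"
        )
    if oversubtraction < 0:
        raise ValidationError("oversubtraction must be >= 0")
    nfft = profile.nfft
    _, _, Z = _stft(signal.samples, signal.rate_hz, nfft)
    mag = np.abs(Z)
    noise = profile.magnitude_spectrum[:, None]
    out_mag = np.minimum(mag, np.maximum(mag - oversubtraction * noise, floor * noise))
    Z_out = out_mag * np.exp(1j * np.angle(Z))
    _, x = sps.istft(
        Z_out, fs=signal.rate_hz, window="hann", nperseg=nfft, noverlap=nfft // 2,
        boundary=True,
    )
    n = len(signal)
    if len(x) < n:
        x = np.pad(x, (0, n - len(x)))
    return AudioSignal(x[:n], signal.rate_hz, signal.subject_id)


def denoise(signal: AudioSignal, cfg: DenoiseConfig) -> AudioSignal:
    """Convenience wrapper: estimate the profile and subtract it, per config."""
    if not cfg.enabled:
        return signal
    profile = estimate_noise_profile(signal, quantile=cfg.quantile, nfft=cfg.nfft)
    return spectral_subtract(
        signal, profile, oversubtraction=cfg.oversubtraction, floor=cfg.floor
    )
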