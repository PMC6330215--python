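"""Band-limited wavelet coherence between pairs of BOLD-like signals.

Magnitude-squared coherence from the continuous Morlet transform,

    R^2 = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) ),

where ``W_x`` is the complex Morlet CWT of ``x``, ``W_xy = W_x conj(W_y)``
the cross-spectrum, ``s`` the scale, and ``S`` a smoothing operator acting
along time (Gaussian with standard deviation matched to the scale) and
along scale (boxcar spanning a fixed number of octaves).  Without the
smoothing the ratio is identically 1; the smoothing window is what gives
the estimator its statistical meaning.

The transform is computed once on the full-length series; windowed
network edges are obtained downstream by averaging the coherence map over
the frequency band and the samples of each sliding window.  At the slow
frequencies of interest (0.02-0.08 Hz) a 20-sample window is shorter than
one period, so a per-window transform would be ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = ["CoherenceConfig", "cwt_morlet", "smooth_spectrum",
           "wavelet_coherence_map"]


@dataclass
class CoherenceConfig:
    """Parameters of the windowed coherence estimator.

    tr_seconds : sampling interval of the series, in seconds.
    band_low, band_high : analysis band in Hz (default 0.02-0.08, the
        canonical low-frequency BOLD band).
    window_len : sliding-window length in samples (default 20).
    overlap_frac : fractional overlap of consecutive windows (default 0.9).
    wavelet_omega0 : Morlet center frequency (dimensionless, default 6 --
        the standard choice balancing time and frequency resolution).
    dj : scale resolution in octaves.
    scale_smoothing_octaves : width of the boxcar smoothing across scales.
    band_margin : multiplicative margin extending the scale range beyond
        the analysis band so smoothing has support at the band edges.
    """

    tr_seconds: float = 3.0
    band_low: float = 0.02
    band_high: float = 0.08
    window_len: int = 20
    overlap_frac: float = 0.9
    wavelet_omega0: float = 6.0
    dj: float = 1.0 / 12.0
    scale_smoothing_octaves: float = 0.6
    band_margin: float = 1.5

    def __post_init__(self):
        nyquist = 0.5 / self.tr_seconds
        if not (0 < self.band_low < self.band_high < nyquist):
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz must lie inside "
                f"(0, {nyquist}) Hz for TR={self.tr_seconds}s")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")

    @property
    def wavelet_name(self) -> str:
        # pywt cmorB-C: psi(t) ~ exp(-t^2/B) exp(2*pi*i*C*t); B=2, C=omega0/2pi
        # matches the analytic Morlet with unit-variance Gaussian envelope.
        return f"cmor2.0-{self.wavelet_omega0 / (2 * np.pi):.10f}"

    def scales(self) -> np.ndarray:
        """Geometric scale grid (in samples) covering the widened band."""
        c = self.wavelet_omega0 / (2 * np.pi)
        f_hi = self.band_high * self.band_margin
        f_lo = self.band_low / self.band_margin
        n_oct = np.log2(f_hi / f_lo)
        n_scales = int(np.ceil(n_oct / self.dj)) + 1
        freqs = f_hi * 2.0 ** (-self.dj * np.arange(n_scales))
        return c / (freqs * self.tr_seconds)

    def frequencies(self) -> np.ndarray:
        """Fourier frequency (Hz) of each scale."""
        c = self.wavelet_omega0 / (2 * np.pi)
        return c / (self.scales() * self.tr_seconds)

    def band_mask(self) -> np.ndarray:
        f = self.frequencies()
        return (f >= self.band_low) & (f <= self.band_high)


def cwt_morlet(x: np.ndarray, cfg: CoherenceConfig) -> np.ndarray:
    """Complex Morlet CWT, shape (n_scales, n_samples)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    coef, _ = pywt.cwt(x, cfg.scales(), cfg.wavelet_name,
                       sampling_period=cfg.tr_seconds, method="fft")
    return coef


def smooth_spectrum(field: np.ndarray, cfg: CoherenceConfig) -> np.ndarray:
    """Smoothing operator S: scale-matched Gaussian in time, boxcar in scale.

    ``field`` has scales on the leading axis and time on the last axis;
    any number of batch axes may sit in between (scales, ..., time).
    Complex input is smoothed componentwise.
    """
    scales = cfg.scales()
    if np.iscomplexobj(field):
        return (smooth_spectrum(field.real, cfg)
                + 1j * smooth_spectrum(field.imag, cfg))
    out = np.empty_like(field, dtype=float)
    for i, s in enumerate(scales):
        out[i] = gaussian_filter1d(field[i], sigma=s, axis=-1, mode="reflect")
    width = max(int(round(cfg.scale_smoothing_octaves / cfg.dj)), 1)
    return uniform_filter1d(out, size=width, axis=0, mode="nearest")


def _is_degenerate(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0)


def wavelet_coherence_map(x: np.ndarray, y: np.ndarray,
                          cfg: CoherenceConfig) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency magnitude-squared coherence map in [0, 1].

    Returns ``(coherence, frequencies)`` with coherence of shape
    (n_scales, n_samples).  A constant input series has zero spectral
    power; the map is then defined as 0 everywhere (degenerate case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 2 * cfg.window_len:
        raise ValueError("series shorter than two windows")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    freqs = cfg.frequencies()
    if _is_degenerate(x) or _is_degenerate(y):
        return np.zeros((freqs.size, x.size)), freqs

    s = cfg.scales()[:, None]
    Wx = cwt_morlet(x, cfg)
    Wy = cwt_morlet(y, cfg)
    sxx = smooth_spectrum(np.abs(Wx) ** 2 / s, cfg)
    syy = smooth_spectrum(np.abs(Wy) ** 2 / s, cfg)
    sxy = smooth_spectrum(Wx * np.conj(Wy) / s, cfg)
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / denom, 0.0)
    return np.clip(coh, 0.0, 1.0), freqs
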