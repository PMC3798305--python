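"""Fractional-Brownian-motion synthesis by spectral (Fourier) filtering.

A 1-D fBm profile with Hurst exponent H has power spectrum ~ f^-(2H+1); a
2-D fBm surface has isotropic spectrum ~ f^-(2H+2).  White complex Gaussian
noise is shaped by the corresponding amplitude filter and inverse-transformed.
Two refinements keep the lattice structure function close to the ideal r^2H
law at pixel scale: the power spectrum is alias-folded (spectral replicas
beyond the Nyquist frequency are summed back in, restoring the sub-pixel
power a plain truncated filter discards), and fields are synthesized on a
doubled domain and cropped to weaken FFT periodicity.  Outputs are zero-mean
with unit standard deviation.
"""

from __future__ import annotations

import numpy as np

_N_ALIAS = 2  # spectral replicas folded per axis


def _check_hurst(hurst: float) -> None:
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {hurst}")


def fbm_profile(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """1-D fBm sample path of length ``n``, unit variance."""
    _check_hurst(hurst)
    m = 2 * n
    freqs = np.fft.fftfreq(m)
    psd = np.zeros(m)
    for k in range(-_N_ALIAS, _N_ALIAS + 1):
        f = np.abs(freqs + k)
        with np.errstate(divide="ignore"):
            psd += np.where(f > 0, f ** (-(2.0 * hurst + 1.0)), 0.0)
    amp = np.sqrt(psd)
    amp[0] = 0.0
    noise = rng.normal(size=m) + 1j * rng.normal(size=m)
    path = np.real(np.fft.ifft(noise * amp))[:n]
    path -= path.mean()
    sd = path.std()
    return path / sd if sd > 0 else path


def fbm_surface(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """2-D fBm surface of shape ``(n, n)``, unit variance."""
    _check_hurst(hurst)
    m = 2 * n
    fx = np.fft.fftfreq(m)
    psd = np.zeros((m, m))
    for kx in range(-_N_ALIAS, _N_ALIAS + 1):
        for ky in range(-_N_ALIAS, _N_ALIAS + 1):
            r = np.hypot(fx[:, None] + kx, fx[None, :] + ky)
            with np.errstate(divide="ignore"):
                psd += np.where(r > 0, r ** (-(2.0 * hurst + 2.0)), 0.0)
    amp = np.sqrt(psd)
    amp[0, 0] = 0.0
    noise = rng.normal(size=(m, m)) + 1j * rng.normal(size=(m, m))
    surf = np.real(np.fft.ifft2(noise * amp))[:n, :n]
    surf -= surf.mean()
    sd = surf.std()
    return surf / sd if sd > 0 else surf


def fbm_surface_image(
    n: int, hurst: float, rng: np.random.Generator, levels: int = 256
) -> np.ndarray:
    """fBm surface mapped affinely onto integer gray levels [0, levels-1]."""
    surf = fbm_surface(n, hurst, rng)
    lo, hi = surf.min(), surf.max()
    scaled = (surf - lo) / (hi - lo) * (levels - 1)
    return np.round(scaled).astype(np.int64)
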