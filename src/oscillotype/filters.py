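"""Frequency-domain ("FFT") filtering.

The acquisition software used in slice electrophysiology applies band filters
as a frequency-domain mask: forward FFT of the whole segment, zero the
out-of-band bins, inverse FFT.  A raised-cosine taper (default 1 Hz wide) at
each band edge avoids ringing from a brick-wall mask.  This class of filter is
zero-phase by construction, which matters for event timing (sharp-wave maxima,
ripple troughs, spike times).
"""

from __future__ import annotations

import numpy as np


def _edge_mask(freqs: np.ndarray, lo: float | None, hi: float | None,
               taper_hz: float) -> np.ndarray:
    """Band mask over non-negative frequencies with raised-cosine edges."""
    f = np.abs(freqs)
    mask = np.ones_like(f)
    if lo is not None and lo > 0:
        below = f < lo - taper_hz
        ramp = (f >= lo - taper_hz) & (f < lo)
        mask[below] = 0.0
        if taper_hz > 0:
            mask[ramp] *= 0.5 * (1 - np.cos(np.pi * (f[ramp] - (lo - taper_hz)) / taper_hz))
    if hi is not None:
        above = f > hi + taper_hz
        ramp = (f > hi) & (f <= hi + taper_hz)
        mask[above] = 0.0
        if taper_hz > 0:
            mask[ramp] *= 0.5 * (1 + np.cos(np.pi * (f[ramp] - hi) / taper_hz))
    return mask


def fft_bandpass(x: np.ndarray, fs: float, lo: float | None, hi: float | None,
                 taper_hz: float = 1.0) -> np.ndarray:
    """Zero-phase band-pass via spectral masking.

    Parameters
    ----------
    x : 1-D signal.
    fs : sampling rate, Hz.
    lo, hi : band edges in Hz; ``None`` leaves that side open
        (``lo=None`` → low-pass at ``hi``; ``hi=None`` → high-pass at ``lo``).
    taper_hz : width of the raised-cosine transition at each edge.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nyq = fs / 2.0
    if hi is not None and hi >= nyq:
        hi = None  # band extends to Nyquist: nothing to cut above
    spec *= _edge_mask(freqs, lo, hi, taper_hz)
    return np.fft.irfft(spec, n=n)


def fft_lowpass(x: np.ndarray, fs: float, cut_hz: float,
                taper_hz: float = 1.0) -> np.ndarray:
    return fft_bandpass(x, fs, None, cut_hz, taper_hz)
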