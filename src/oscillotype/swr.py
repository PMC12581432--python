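"""Sharp wave-ripple (SW-R) detection and quantification.

Sharp waves are found on the ≤45 Hz low-passed trace as local maxima above
mean + 3·SD of the filtered segment, with maxima closer than 100 ms merged to
the larger.  SW area integrates the filtered trace between the mean-crossings
flanking the maximum.  The ripple component is isolated in a 125 ms window
centered on the SW maximum, band-passed at 120–300 Hz and gated at 3·SD of
the band-passed window; ripple troughs inside [−15, +10] ms around the SW
maximum are measured by triple-point-minimax amplitude (mean of the flanking
maxima minus the trough) with an asymmetry cap, and ripple frequency is the
mean reciprocal inter-trough interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .filters import fft_bandpass, fft_lowpass
from .io_core import AnalysisConfig, Recording


@dataclass
class SwrEvent:
    """One detected sharp-wave complex and its ripple measurements."""

    t_max: float
    peak_mV: float
    sw_area: Optional[float] = None      # mV·ms; None when edge-clipped
    start_s: Optional[float] = None
    end_s: Optional[float] = None
    edge_clipped: bool = False
    ripple_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_trough_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_freq_hz: Optional[float] = None

    @property
    def n_ripples(self) -> int:
        return int(self.ripple_amplitudes.size)


@dataclass
class SwrSummary:
    incidence_hz: float
    n_events: int
    mean_sw_area: Optional[float]
    mean_ripple_amp: Optional[float]
    mean_ripple_freq: Optional[float]


def detect_sharp_waves(seg: Recording, cfg: AnalysisConfig | None = None
                       ) -> tuple[list[SwrEvent], np.ndarray]:
    """Sharp-wave candidates on the low-passed trace.

    Returns (events, low-passed trace).  Threshold = mean + 3·SD with the SD
    taken over the entire filtered segment, events included (an optional
    median/MAD baseline is available for heavily event-laden traces).
    Candidates closer than 100 ms are merged, keeping the larger maximum.
    """
    cfg = cfg or AnalysisConfig()
    lp = fft_lowpass(seg.samples, seg.fs, cfg.sw_lowpass_hz, cfg.filter_taper_hz)
    lp = lp * cfg.sw_polarity
    if cfg.sw_robust_baseline:
        center = float(np.median(lp))
        spread = float(np.median(np.abs(lp - center)) / 0.6745)
    else:
        center = float(lp.mean())
        spread = float(lp.std())
    thresh = center + cfg.sw_sd_mult * spread

    min_sep = max(1, int(round(cfg.sw_min_sep_ms * seg.fs / 1000.0)))
    peaks, props = sps.find_peaks(lp, height=thresh, distance=min_sep)
    events = [SwrEvent(t_max=seg.t0 + p / seg.fs, peak_mV=float(lp[p]))
              for p in peaks]
    return events, lp * cfg.sw_polarity


def sw_area(lp_trace: np.ndarray, fs: float, event: SwrEvent, t0: float = 0.0,
            polarity: int = 1) -> SwrEvent:
    """SW area under curve (mV·ms) between the mean-crossings flanking t_max.

    Trapezoidal integral of (trace − mean); an event whose flanking crossing
    falls outside the segment is flagged edge-clipped with missing area.
    """
    lp = np.asarray(lp_trace, dtype=np.float64) * polarity
    mean = lp.mean()
    dev = lp - mean
    k = int(round((event.t_max - t0) * fs))
    k = min(max(k, 0), dev.size - 1)
    if dev[k] <= 0:
        raise ValueError("event maximum must lie above the trace mean")

    below_left = np.flatnonzero(dev[:k + 1] <= 0)
    below_right = np.flatnonzero(dev[k:] <= 0)
    if below_left.size == 0 or below_right.size == 0:
        event.edge_clipped = True
        event.sw_area = None
        return event
    a = int(below_left[-1])       # last sample at/below mean before the peak
    b = k + int(below_right[0])   # first sample at/below mean after the peak
    area = float(np.trapezoid(np.clip(dev[a:b + 1], 0, None), dx=1.0 / fs)) * 1000.0
    event.sw_area = area
    event.start_s = t0 + a / fs
    event.end_s = t0 + b / fs
    return event


def _triple_point_amplitude(bp: np.ndarray, trough_idx: int,
                            asym_max: float, asym_mode: str
                            ) -> Optional[float]:
    """Triple-point-minimax amplitude of one ripple trough, or None.

    Points: preceding local maximum M1, trough m, following local maximum M2.
    amplitude = mean(M1, M2) − m; rising r = M1 − m, falling f = M2 − m.
    Inclusion: |r − f| / max(r, f) < asym_max (default reading), or the
    alternative reading min(r,f)/max(r,f) ≥ 1 − asym_max via ``ratio`` mode.
    """
    left = None
    for i in range(trough_idx - 1, 0, -1):
        if bp[i] >= bp[i - 1] and bp[i] >= bp[i + 1]:
            left = i
            break
    right = None
    for i in range(trough_idx + 1, bp.size - 1):
        if bp[i] >= bp[i - 1] and bp[i] >= bp[i + 1]:
            right = i
            break
    if left is None or right is None:
        return None
    m = bp[trough_idx]
    r = bp[left] - m
    f = bp[right] - m
    if r <= 0 or f <= 0:
        return None
    if asym_mode == "ratio":
        ok = (min(r, f) / max(r, f)) >= (1.0 - asym_max)
    else:
        ok = abs(r - f) / max(r, f) < asym_max
    if not ok:
        return None
    return float(0.5 * (bp[left] + bp[right]) - m)


def extract_ripples(seg: Recording, event: SwrEvent,
                    cfg: AnalysisConfig | None = None) -> SwrEvent:
    """Measure the ripple component of one sharp-wave event in place.

    A 125 ms window centered on the SW maximum is band-passed at 120–300 Hz;
    troughs within [t_max − 15 ms, t_max + 10 ms] whose triple-point
    amplitude exceeds 3·SD of the band-passed window (and pass the asymmetry
    rule) are kept.  Events without the full window margin are skipped
    (ripple fields left empty).
    """
    cfg = cfg or AnalysisConfig()
    half = int(round(cfg.ripple_win_ms / 2.0 * seg.fs / 1000.0))
    k = int(round((event.t_max - seg.t0) * seg.fs))
    if k - half < 0 or k + half >= seg.n:
        return event  # insufficient margin; event keeps SW metrics only
    win = seg.samples[k - half:k + half + 1]
    bp = fft_bandpass(win, seg.fs, *cfg.ripple_band, cfg.filter_taper_hz)
    gate = cfg.ripple_sd_mult * float(bp.std())

    pre = int(round(cfg.ripple_pre_ms * seg.fs / 1000.0))
    post = int(round(cfg.ripple_post_ms * seg.fs / 1000.0))
    lo, hi = half - pre, half + post
    troughs, _ = sps.find_peaks(-bp)
    troughs = troughs[(troughs >= lo) & (troughs <= hi)]

    amps, times = [], []
    for t in troughs:
        amp = _triple_point_amplitude(bp, t, cfg.ripple_asym_max,
                                      cfg.ripple_asym_mode)
        if amp is not None and amp > gate:
            # parabolic sub-sample refinement of the trough time
            y0, y1, y2 = bp[t - 1], bp[t], bp[t + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            amps.append(amp)
            times.append(event.t_max + (t + shift - half) / seg.fs)
    event.ripple_amplitudes = np.array(amps)
    event.ripple_trough_times = np.array(times)
    event.ripple_freq_hz = ripple_frequency(event)
    return event


def ripple_frequency(event: SwrEvent) -> Optional[float]:
    """Mean of 1/Δt over consecutive included ripple troughs; None if < 2."""
    t = event.ripple_trough_times
    if t.size < 2:
        return None
    return float(np.mean(1.0 / np.diff(t)))


def analyze_swr(seg: Recording, cfg: AnalysisConfig | None = None
                ) -> tuple[list[SwrEvent], SwrSummary]:
    """Full detector: sharp waves → areas → ripples → segment summary."""
    cfg = cfg or AnalysisConfig()
    events, lp = detect_sharp_waves(seg, cfg)
    for ev in events:
        sw_area(lp, seg.fs, ev, t0=seg.t0, polarity=cfg.sw_polarity)
        extract_ripples(seg, ev, cfg)
    return events, swr_summary(events, seg.duration)


def swr_summary(events: list[SwrEvent], duration_s: float) -> SwrSummary:
    """Per-segment aggregates; missing means when no event defines a metric."""
    areas = [ev.sw_area for ev in events if ev.sw_area is not None]
    ramps = [float(ev.ripple_amplitudes.mean()) for ev in events
             if ev.ripple_amplitudes.size]
    rfreqs = [ev.ripple_freq_hz for ev in events if ev.ripple_freq_hz is not None]
    return SwrSummary(
        incidence_hz=len(events) / duration_s,
        n_events=len(events),
        mean_sw_area=float(np.mean(areas)) if areas else None,
        mean_ripple_amp=float(np.mean(ramps)) if ramps else None,
        mean_ripple_freq=float(np.mean(rfreqs)) if rfreqs else None,
    )
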