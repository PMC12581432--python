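"""Evoked field-potential (fEPSP) metrics.

A Schaffer-collateral stimulus evokes, at the CA1 recording site, a brief
stimulus artifact, a presynaptic fiber volley (FV) and the postsynaptic fEPSP.
Synaptic strength is indexed by the fEPSP slope — a least-squares line over
the rising (onset) limb where the deflection lies between 20% and 80% of its
amplitude, in V/s.  Transmission rate is the per-sweep slope/FV ratio
averaged per slice (units: (V/s)/mV = ms⁻¹).  The paired-pulse ratio is
slope₂/slope₁; at short inter-stimulus intervals the mono-exponential tail of
the first response is fitted and subtracted before measuring the second.

Windows (1.5 ms artifact blanking; FV 1.5–3.5 ms; fEPSP 4–20 ms post-stimulus)
follow standard CA3→CA1 latencies and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .io_core import AnalysisConfig


@dataclass(frozen=True)
class Sweep:
    """One evoked-response sweep with stimulus timestamps."""

    samples: np.ndarray  # mV
    fs: float
    stim_times: tuple[float, ...]  # s within sweep
    stim_intensity_uA: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = samples.size / self.fs
        for t in self.stim_times:
            if not (0 <= t < dur):
                raise ValueError(f"stimulus time {t} outside sweep [0, {dur})")
        object.__setattr__(self, "samples", samples)


@dataclass
class EvokedMetrics:
    fv_amp_mV: Optional[float] = None
    fepsp_slope_V_per_s: Optional[float] = None
    fepsp_amp_mV: Optional[float] = None
    ppr: Optional[float] = None
    clipped: bool = False


def _baseline(sweep: Sweep, stim_idx: int, cfg: AnalysisConfig) -> float:
    """Mean over the 5 ms preceding the stimulus (0.5 ms pre-trigger guard
    against artifact bleed)."""
    t_stim = sweep.stim_times[stim_idx]
    i1 = int(round((t_stim - 0.0005) * sweep.fs))
    i0 = max(0, i1 - int(round(cfg.baseline_ms * sweep.fs / 1000.0)))
    if i1 <= i0:
        return float(sweep.samples[0])
    return float(sweep.samples[i0:i1].mean())


def _window(sweep: Sweep, stim_idx: int, lo_ms: float, hi_ms: float
            ) -> tuple[np.ndarray, int]:
    t_stim = sweep.stim_times[stim_idx]
    i0 = int(round((t_stim + lo_ms / 1000.0) * sweep.fs))
    i1 = int(round((t_stim + hi_ms / 1000.0) * sweep.fs))
    i0 = max(i0, 0)
    i1 = min(i1, sweep.samples.size)
    return sweep.samples[i0:i1], i0


def fepsp_slope(sweep: Sweep, stim_idx: int = 0,
                cfg: AnalysisConfig | None = None,
                noise_floor_mV: float = 0.05,
                _samples_override: np.ndarray | None = None
                ) -> EvokedMetrics:
    """20–80% slope of the fEPSP deflection after one stimulus.

    Amplitude is baseline-to-extremum inside the fEPSP window (negative-going
    by default); the slope is the least-squares line over the onset-limb
    samples whose deflection lies between 20% and 80% of that amplitude.
    mV/ms is numerically V/s.  Returns missing metrics when the deflection
    is below the noise floor, and flags a deflection clipped at the window
    edge.
    """
    cfg = cfg or AnalysisConfig()
    work = sweep if _samples_override is None else Sweep(
        _samples_override, sweep.fs, sweep.stim_times, sweep.stim_intensity_uA)
    base = _baseline(work, stim_idx, cfg)
    win, i0 = _window(work, stim_idx, *cfg.fepsp_window_ms)
    out = EvokedMetrics()
    if win.size < 4:
        return out
    dev = (win - base) * cfg.fepsp_polarity  # deflection now positive-going
    k = int(np.argmax(dev))
    amp = dev[k]
    if amp < noise_floor_mV:
        return out
    if k == 0 or k == dev.size - 1:
        out.clipped = True
        out.fepsp_amp_mV = float(amp)
        return out
    lo, hi = 0.2 * amp, 0.8 * amp
    onset = dev[:k + 1]
    sel = np.flatnonzero((onset >= lo) & (onset <= hi))
    if sel.size >= 2:
        # keep only the contiguous run ending at the extremum's rise
        breaks = np.flatnonzero(np.diff(sel) > 1)
        if breaks.size:
            sel = sel[breaks[-1] + 1:]
    if sel.size < 2:
        out.fepsp_amp_mV = float(amp)
        return out
    t_ms = sel * 1000.0 / work.fs
    y = dev[sel]
    slope_mv_per_ms = float(np.polyfit(t_ms, y, 1)[0])
    out.fepsp_amp_mV = float(amp)
    out.fepsp_slope_V_per_s = slope_mv_per_ms * cfg.fepsp_polarity
    return out


def fiber_volley_amplitude(sweep: Sweep, stim_idx: int = 0,
                           cfg: AnalysisConfig | None = None,
                           noise_floor_mV: float = 0.01) -> Optional[float]:
    """Baseline-to-extremum amplitude in the fiber-volley window (1.5–4 ms).

    The FV is the first fast deflection after artifact blanking; measured as
    |extremum − baseline| regardless of polarity.  Returns ``None`` when no
    deflection clears the noise floor.
    """
    cfg = cfg or AnalysisConfig()
    base = _baseline(sweep, stim_idx, cfg)
    win, _ = _window(sweep, stim_idx, *cfg.fv_window_ms)
    if win.size == 0:
        return None
    amp = float(np.max(np.abs(win - base)))
    return amp if amp >= noise_floor_mV else None


def transmission_rate(slopes: Sequence[float], fvs: Sequence[float]
                      ) -> Optional[float]:
    """Per-slice mean of per-sweep |slope|/FV ratios, in ms⁻¹.

    Sweeps with non-positive or missing FV are excluded.  Returns ``None``
    when no sweep survives.
    """
    if len(slopes) != len(fvs):
        raise ValueError("slopes and FVs must be paired per sweep")
    ratios = [abs(s) / f for s, f in zip(slopes, fvs)
              if s is not None and f is not None and f > 0]
    return float(np.mean(ratios)) if ratios else None


def _doe(t_ms: np.ndarray, amp: float, onset_ms: float,
         tau_r: float, tau_d: float) -> np.ndarray:
    """Difference-of-exponentials fEPSP template, peak-normalized amplitude."""
    rel = t_ms - onset_ms
    out = np.zeros_like(rel)
    pos = rel > 0
    raw = np.exp(-rel[pos] / tau_d) - np.exp(-rel[pos] / tau_r)
    t_pk = np.log(tau_d / tau_r) / (1 / tau_r - 1 / tau_d)
    peak = np.exp(-t_pk / tau_d) - np.exp(-t_pk / tau_r)
    out[pos] = amp * raw / peak
    return out


def _subtract_first_response_tail(sweep: Sweep, cfg: AnalysisConfig
                                  ) -> np.ndarray:
    """Fit response 1 with an fEPSP template and subtract its extrapolation
    (superposition correction for short paired-pulse intervals).

    A difference-of-exponentials template is fitted over the first response's
    window up to just before stimulus 2 — at the shortest intervals only a
    few ms of decay exist, where a bare mono-exponential extrapolates poorly;
    the template constrains the tail through the rising limb as well.  Falls
    back to a mono-exponential tail fit if the template fit fails.
    """
    t1, t2 = sweep.stim_times[:2]
    base = _baseline(sweep, 0, cfg)
    i_on = int(round((t1 + cfg.fepsp_window_ms[0] / 1000.0) * sweep.fs))
    i2 = int(round((t2 - 0.0002) * sweep.fs))
    fit_end = min(i2, sweep.samples.size)
    if fit_end - i_on < 10:
        return sweep.samples  # nothing usable to fit; leave untouched
    t_ms = np.arange(i_on, fit_end) / sweep.fs * 1000.0
    y = (sweep.samples[i_on:fit_end] - base) * cfg.fepsp_polarity
    if np.max(y) <= 0:
        return sweep.samples
    k = int(np.argmax(y))
    amp0 = float(y[k])
    onset0 = float(t_ms[0])

    corrected = sweep.samples.copy()
    tail_ms = np.arange(i_on, sweep.samples.size) / sweep.fs * 1000.0
    try:
        popt, _ = optimize.curve_fit(
            _doe, t_ms, y,
            p0=(amp0, onset0, 1.0, 10.0),
            bounds=([0.0, onset0 - 3.0, 0.1, 1.0],
                    [10 * amp0 + 1e-6, t_ms[min(k, t_ms.size - 1)], 5.0, 80.0]),
            maxfev=5000)
        corrected[i_on:] -= cfg.fepsp_polarity * _doe(tail_ms, *popt)
        return corrected
    except RuntimeError:
        pass
    # mono-exponential fall-back on the post-peak decay
    peak_idx = i_on + k
    if fit_end - peak_idx < 5:
        return sweep.samples
    t_tail = np.arange(peak_idx, fit_end) / sweep.fs
    y_tail = (sweep.samples[peak_idx:fit_end] - base) * cfg.fepsp_polarity

    def mono(tt, a, tau):
        return a * np.exp(-(tt - t_tail[0]) / tau)

    try:
        popt, _ = optimize.curve_fit(mono, t_tail, y_tail,
                                     p0=(max(y_tail[0], 1e-3), 0.01),
                                     bounds=([0, 1e-4], [np.inf, 0.1]),
                                     maxfev=2000)
    except RuntimeError:
        return sweep.samples
    tail_t = np.arange(peak_idx, sweep.samples.size) / sweep.fs
    corrected[peak_idx:] -= cfg.fepsp_polarity * mono(tail_t, *popt)
    return corrected


def paired_pulse_ratio(sweep: Sweep, cfg: AnalysisConfig | None = None,
                       overlap_threshold_ms: float = 60.0
                       ) -> Optional[float]:
    """Slope of the second fEPSP divided by the first (two-stimulus sweep).

    When the inter-stimulus interval is short enough for the first response
    to overlap the second (< ``overlap_threshold_ms``), the fitted tail of
    response 1 is subtracted before measuring response 2.
    """
    cfg = cfg or AnalysisConfig()
    if len(sweep.stim_times) != 2:
        raise ValueError("paired-pulse sweep needs exactly 2 stimuli")
    interval_ms_full = (sweep.stim_times[1] - sweep.stim_times[0]) * 1000.0
    # response 1 must be measured before stimulus 2 arrives
    cfg1 = cfg
    if interval_ms_full - 0.5 < cfg.fepsp_window_ms[1]:
        from dataclasses import replace as _replace
        cfg1 = _replace(cfg, fepsp_window_ms=(
            cfg.fepsp_window_ms[0], interval_ms_full - 0.5))
    m1 = fepsp_slope(sweep, 0, cfg1)
    if m1.fepsp_slope_V_per_s is None or m1.fepsp_slope_V_per_s == 0:
        return None
    interval_ms = (sweep.stim_times[1] - sweep.stim_times[0]) * 1000.0
    samples2 = (_subtract_first_response_tail(sweep, cfg)
                if interval_ms < overlap_threshold_ms else None)
    m2 = fepsp_slope(sweep, 1, cfg, _samples_override=samples2)
    if m2.fepsp_slope_V_per_s is None:
        return None
    return float(m2.fepsp_slope_V_per_s / m1.fepsp_slope_V_per_s)


def io_curve(sweeps: Sequence[Sweep], cfg: AnalysisConfig | None = None):
    """Input–output table: (intensity µA, FV mV, slope V/s) per sweep,
    plus the slice-exclusion flag (fEPSP amplitude < 1 mV at the maximum
    intensity)."""
    import pandas as pd

    cfg = cfg or AnalysisConfig()
    rows = []
    for sw in sweeps:
        m = fepsp_slope(sw, 0, cfg)
        fv = fiber_volley_amplitude(sw, 0, cfg)
        rows.append({"intensity_uA": sw.stim_intensity_uA,
                     "fv_amp_mV": fv,
                     "fepsp_slope_V_per_s": m.fepsp_slope_V_per_s,
                     "fepsp_amp_mV": m.fepsp_amp_mV})
    df = pd.DataFrame(rows).sort_values("intensity_uA").reset_index(drop=True)
    max_row = df.iloc[-1] if len(df) else None
    flag = bool(max_row is not None and (max_row["fepsp_amp_mV"] is None
                or np.isnan(max_row["fepsp_amp_mV"])
                or max_row["fepsp_amp_mV"] < 1.0))
    return df, flag
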