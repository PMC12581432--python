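"""Seeded generators emulating the statistical structure of slice recordings.

Each generator is a pure function of its config (seed included) and returns a
:class:`~oscillotype.io_core.Recording` together with a ground-truth object,
so every pipeline stage can be tested as a parameter-recovery problem.

* Gamma LFP — a gamma-band oscillation built cycle by cycle (so the true
  phase of every sample is known exactly) with cycle-period jitter, an
  Ornstein–Uhlenbeck amplitude envelope whose correlation time sets the
  autocorrelation decay constant, and 1/f^α background noise.  With zero
  jitter the expected normalized autocorrelation is exp(−lag/τ)·cos(2πf·lag)
  up to the noise-power dilution of the zero-lag normalization.
* Phase-locked units — spike times drawn with a von Mises phase density on
  the gamma cycle, biphasic extracellular templates added to the trace.
* SW-R train — renewal-process event times (exponential gaps plus a 200 ms
  dead time, gap mean adjusted so the rate equals the configured incidence),
  each event a Gaussian sharp-wave transient with a flat-top ripple tone
  burst at its maximum, on 1/f^2 background noise.
* fEPSP sweeps — stimulus artifact, fiber-volley template and a
  difference-of-exponentials fEPSP whose amplitudes scale linearly with
  stimulus intensity; paired-pulse sweeps apply a configured facilitation.

Defaults mirror the study's conditions: 5 kHz sampling, two-minute windows,
gamma peak frequencies in the mid-30s Hz, envelope correlation times of a
few tens of ms, 10–50 µA intensity grids and 10–500 ms paired-pulse
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .io_core import Recording
from .evoked import Sweep


# --------------------------------------------------------------------------
# gamma LFP


@dataclass(frozen=True)
class GammaSimConfig:
    fs: float = 5000.0
    duration_s: float = 120.0
    peak_f_hz: float = 34.0          # cholinergic-gamma-like default
    amplitude_uV: float = 100.0      # RMS of the oscillation envelope
    phase_jitter: float = 0.02       # cycle-period SD as a fraction of period
    decay_tau_ms: float = 25.0       # envelope correlation time
    noise_exponent: float = 1.5      # 1/f^α background slope
    noise_uV: float = 20.0           # background RMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 < self.peak_f_hz < 80.0):
            raise ValueError("peak_f_hz must lie inside the 20-80 Hz band")
        for name in ("fs", "duration_s", "amplitude_uV", "decay_tau_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GammaTruth:
    peak_f_hz: float
    band_power_uV2: float            # expected oscillation band power, σ_env²/2
    tau_ms: float
    phase_deg: np.ndarray            # effective per-sample phase, trough = 0°
    unwrapped_phase_rad: np.ndarray  # monotone nominal phase (spike placement)
    envelope_mV: np.ndarray          # signed OU envelope (sign flips shift the
                                     # physical phase by half a cycle)


def _pink_noise(n: int, exponent: float, rms: float, rng: np.random.Generator,
                fs: float = 1.0, hp_hz: float = 0.0) -> np.ndarray:
    """1/f^α Gaussian noise, optionally high-passed at ``hp_hz`` (the
    AC-coupled recording chain removes sub-Hz content from real traces)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    if hp_hz > 0:
        scale[f < hp_hz] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def gen_gamma_lfp(cfg: GammaSimConfig) -> tuple[Recording, GammaTruth]:
    """Synthesize a gamma-band LFP with exact per-sample phase ground truth.

    The oscillation is a zero-mean OU envelope (SD = ``amplitude_uV``,
    correlation time ``decay_tau_ms``) multiplying cos(φ(t)); φ advances
    2π per cycle over periods jittered by ``phase_jitter``.  Expected
    oscillation band power is amplitude_uV²/2.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    dt = 1.0 / cfg.fs
    period0 = 1.0 / cfg.peak_f_hz

    # concatenated jittered cycles -> piecewise-linear unwrapped phase
    est_cycles = int(np.ceil(cfg.duration_s / period0)) + 10
    periods = period0 * np.clip(
        1.0 + cfg.phase_jitter * rng.standard_normal(est_cycles), 0.2, 5.0)
    while periods.sum() < cfg.duration_s + period0:
        extra = period0 * np.clip(
            1.0 + cfg.phase_jitter * rng.standard_normal(16), 0.2, 5.0)
        periods = np.concatenate([periods, extra])
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) * dt
    cyc = np.searchsorted(boundaries, t, side="right") - 1
    frac = (t - boundaries[cyc]) / periods[cyc]
    unwrapped = 2.0 * np.pi * (cyc + frac)

    # OU envelope, stationary init
    rho = np.exp(-dt * 1000.0 / cfg.decay_tau_ms)
    amp_mv = cfg.amplitude_uV / 1000.0
    env = np.empty(n)
    env[0] = rng.standard_normal() * amp_mv
    innov = rng.standard_normal(n - 1) * amp_mv * np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        env[i] = rho * env[i - 1] + innov[i - 1]
    # The raw OU process has 1/f² spectral tails that would bleed into the
    # 500+ Hz unit band; a 150 Hz low-pass removes ~2% of envelope power and
    # leaves the exponential AC at gamma-period lags essentially untouched.
    from .filters import fft_lowpass
    env = fft_lowpass(env, cfg.fs, 150.0, taper_hz=20.0)

    # phase convention: trough = 0°, so the oscillation is -cos(phase)
    osc = env * (-np.cos(unwrapped))
    noise = _pink_noise(n, cfg.noise_exponent, cfg.noise_uV / 1000.0, rng,
                        fs=cfg.fs, hp_hz=1.0)
    rec = Recording(osc + noise, fs=cfg.fs, label=f"sim-gamma-{cfg.peak_f_hz:g}Hz")
    eff_phase = (np.degrees(unwrapped) + np.where(env < 0, 180.0, 0.0)) % 360.0
    truth = GammaTruth(
        peak_f_hz=cfg.peak_f_hz,
        band_power_uV2=cfg.amplitude_uV ** 2 / 2.0,
        tau_ms=cfg.decay_tau_ms,
        phase_deg=eff_phase,
        unwrapped_phase_rad=unwrapped,
        envelope_mV=env,
    )
    return rec, truth


# --------------------------------------------------------------------------
# phase-locked units


@dataclass(frozen=True)
class UnitSimConfig:
    rate_hz: float = 5.0
    pref_phase_deg: float = 270.0    # late-cycle preference, as in the data
    kappa: float = 2.0               # von Mises concentration (0 = uniform)
    template_height_mV: float = 0.05
    template_halfwidth_ms: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class UnitTruth:
    times: np.ndarray
    phases_deg: np.ndarray
    template: np.ndarray


def spike_template(fs: float, height_mV: float, halfwidth_ms: float) -> np.ndarray:
    """Biphasic extracellular spike (derivative-of-Gaussian), negative lobe
    normalized to ``height_mV``.  Its spectral energy sits near
    1/(2π·σ), inside the 500–3000 Hz unit band for sub-millisecond σ."""
    sigma_ms = halfwidth_ms / 1.2  # empirical: lobe half-width ≈ 1.2 σ
    sigma = sigma_ms / 1000.0
    half = int(round(4 * sigma * fs))
    tt = (np.arange(-half, half + 1)) / fs
    shape = -(tt / sigma) * np.exp(0.5 - tt ** 2 / (2 * sigma ** 2))
    return shape * (height_mV / np.max(np.abs(shape)))


def gen_locked_units(rec: Recording, truth: GammaTruth, cfg: UnitSimConfig
                     ) -> tuple[Recording, UnitTruth]:
    """Add von Mises phase-locked spikes to a synthetic gamma trace.

    Spike count is Poisson(rate·duration); each spike draws a phase from
    vonmises(μ=pref_phase, κ) — uniform when κ=0 — lands in a uniformly
    chosen gamma cycle, and deposits a biphasic template at that time.
    """
    rng = np.random.default_rng(cfg.seed)
    n_spikes = rng.poisson(cfg.rate_hz * rec.duration)
    unwrapped = truth.unwrapped_phase_rad
    n_cycles = int(unwrapped[-1] // (2 * np.pi))
    mu = np.radians(cfg.pref_phase_deg)
    if cfg.kappa == 0:
        theta = rng.uniform(0, 2 * np.pi, n_spikes)
    else:
        theta = rng.vonmises(mu, cfg.kappa, n_spikes) % (2 * np.pi)
    cycles = rng.integers(0, n_cycles, n_spikes)
    target = 2 * np.pi * cycles + theta
    idx = np.clip(np.searchsorted(unwrapped, target), 0, rec.n - 1)
    # where the OU envelope is negative the physical waveform is phase-
    # shifted half a cycle; move the spike so it sits at the drawn phase of
    # the cycle as actually emitted
    flip = truth.envelope_mV[idx] < 0
    target = target + np.where(flip, np.pi, 0.0)
    idx = np.clip(np.searchsorted(unwrapped, target), 0, rec.n - 1)
    order = np.argsort(idx)
    idx, theta = idx[order], theta[order]

    tmpl = spike_template(rec.fs, cfg.template_height_mV, cfg.template_halfwidth_ms)
    half = tmpl.size // 2
    samples = rec.samples.copy()
    for k in idx:
        a, b = k - half, k + half + 1
        src0 = max(0, -a)
        a, b = max(a, 0), min(b, samples.size)
        samples[a:b] += tmpl[src0:src0 + (b - a)]
    out = rec.with_samples(samples)
    return out, UnitTruth(times=rec.t0 + idx / rec.fs,
                          phases_deg=np.degrees(theta) % 360.0,
                          template=tmpl)


# --------------------------------------------------------------------------
# sharp wave-ripple trains


@dataclass(frozen=True)
class SwrSimConfig:
    fs: float = 5000.0
    duration_s: float = 120.0
    incidence_hz: float = 0.5
    sw_amp_mV: float = 0.2
    sw_sigma_ms: float = 10.0
    ripple_f_hz: float = 200.0
    ripple_cycles: int = 5
    ripple_amp_mV: float = 0.05
    noise_mV: float = 0.01           # background SD (1/f^2, AC-coupled)
    min_sep_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.incidence_hz < 0:
            raise ValueError("incidence_hz must be non-negative")
        if not (120.0 < self.ripple_f_hz < 300.0):
            raise ValueError("ripple_f_hz must lie inside the 120-300 Hz band")


@dataclass
class SwrTruth:
    times: np.ndarray                # SW maxima, s
    sw_amp_mV: float
    sw_sigma_ms: float
    ripple_f_hz: float
    expected_area_mV_ms: float       # untruncated Gaussian area a·σ·√(2π)


def gen_swr_train(cfg: SwrSimConfig) -> tuple[Recording, SwrTruth]:
    """Synthesize a spontaneous SW-R trace with known event times.

    Event gaps are ``min_sep_s`` plus an exponential with mean
    1/incidence − min_sep_s, so the long-run event rate equals the
    configured incidence while respecting the separation floor.
    """
    if cfg.incidence_hz > 0 and 1.0 / cfg.incidence_hz <= cfg.min_sep_s:
        raise ValueError("incidence too high for the minimum separation")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    x = _pink_noise(n, 2.0, cfg.noise_mV, rng, fs=cfg.fs, hp_hz=1.0)

    times = []
    if cfg.incidence_hz > 0:
        mean_gap = 1.0 / cfg.incidence_hz - cfg.min_sep_s
        t = cfg.min_sep_s + rng.exponential(mean_gap)
        margin = 4 * cfg.sw_sigma_ms / 1000.0 + 0.08
        while t < cfg.duration_s - margin:
            if t > margin:
                times.append(t)
            t += cfg.min_sep_s + rng.exponential(mean_gap)
    times_a = np.array(times)

    sigma = cfg.sw_sigma_ms / 1000.0
    burst_dur = cfg.ripple_cycles / cfg.ripple_f_hz
    for t_ev in times_a:
        k = int(round(t_ev * cfg.fs))
        half = int(round(4 * sigma * cfg.fs))
        tt = (np.arange(k - half, k + half + 1)) / cfg.fs - t_ev
        x[k - half:k + half + 1] += cfg.sw_amp_mV * np.exp(-tt ** 2 / (2 * sigma ** 2))
        rhalf = int(round(burst_dur / 2 * cfg.fs))
        rt = (np.arange(k - rhalf, k + rhalf + 1)) / cfg.fs - t_ev
        # flat-top (Tukey) envelope: amplitude modulation at the burst edges
        # shifts trough times and would bias the inter-trough frequency
        taper = 0.4
        u = np.abs(rt) / (burst_dur / 2)
        envl = np.where(u < 1 - taper, 1.0,
                        0.5 * (1 + np.cos(np.pi * (u - (1 - taper)) / taper)))
        envl[u > 1] = 0.0
        x[k - rhalf:k + rhalf + 1] += cfg.ripple_amp_mV * envl * np.cos(
            2 * np.pi * cfg.ripple_f_hz * rt)

    rec = Recording(x, fs=cfg.fs, label="sim-swr")
    truth = SwrTruth(times=times_a, sw_amp_mV=cfg.sw_amp_mV,
                     sw_sigma_ms=cfg.sw_sigma_ms, ripple_f_hz=cfg.ripple_f_hz,
                     expected_area_mV_ms=cfg.sw_amp_mV * cfg.sw_sigma_ms
                     * np.sqrt(2 * np.pi))
    return rec, truth


# --------------------------------------------------------------------------
# evoked fEPSP sweeps


@dataclass(frozen=True)
class FepspSimConfig:
    fs: float = 5000.0
    sweep_dur_s: float = 0.25
    stim_time_s: float = 0.05
    intensities_uA: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    fv_gain_mV_per_uA: float = 0.006
    fepsp_gain_mV_per_uA: float = 0.04
    fv_latency_ms: float = 2.4
    fepsp_onset_ms: float = 4.5
    tau_rise_ms: float = 1.5
    tau_decay_ms: float = 8.0
    noise_mV: float = 0.005
    artifact_amp_mV: float = 2.0
    pp_intervals_ms: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0, 500.0)
    pp_facilitation: tuple[float, ...] = (1.6, 1.7, 1.5, 1.3, 1.15, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fv_gain_mV_per_uA < 0 or self.fepsp_gain_mV_per_uA < 0:
            raise ValueError("gains must be non-negative")
        if len(self.pp_intervals_ms) != len(self.pp_facilitation):
            raise ValueError("pp_intervals_ms and pp_facilitation must pair up")


@dataclass
class FepspTruth:
    fv_amps_mV: dict
    fepsp_amps_mV: dict
    ppr: dict                        # interval_ms -> facilitation factor


def fepsp_shape(t_ms: np.ndarray, tau_rise_ms: float, tau_decay_ms: float
                ) -> np.ndarray:
    """Difference-of-exponentials waveform, peak normalized to 1; zero for
    t < 0.  Exposed so tests can compute dense-grid slope oracles."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    raw = np.exp(-t[pos] / tau_decay_ms) - np.exp(-t[pos] / tau_rise_ms)
    t_peak = (np.log(tau_decay_ms / tau_rise_ms)
              / (1 / tau_rise_ms - 1 / tau_decay_ms))
    peak = np.exp(-t_peak / tau_decay_ms) - np.exp(-t_peak / tau_rise_ms)
    out[pos] = raw / peak
    return out


def _one_sweep(cfg: FepspSimConfig, rng: np.random.Generator,
               intensity: float, stim_times: Sequence[float],
               amp_scales: Sequence[float]) -> Sweep:
    # sweep must hold the last response plus its decay
    dur = max(cfg.sweep_dur_s, max(stim_times) + 0.1)
    n = int(round(dur * cfg.fs))
    x = rng.standard_normal(n) * cfg.noise_mV
    t_ms = np.arange(n) * 1000.0 / cfg.fs
    for t_stim, scale in zip(stim_times, amp_scales):
        rel = t_ms - t_stim * 1000.0
        # brief biphasic stimulus artifact (0.4 ms, starting at the trigger)
        art = (rel >= 0) & (rel < 0.4)
        x[art] += cfg.artifact_amp_mV * np.sign(0.2 - rel[art])
        # fiber volley: narrow negative Gaussian
        fv_amp = cfg.fv_gain_mV_per_uA * intensity
        x += -fv_amp * np.exp(-(rel - cfg.fv_latency_ms) ** 2 / (2 * 0.3 ** 2))
        # fEPSP: negative-going difference of exponentials
        fep_amp = cfg.fepsp_gain_mV_per_uA * intensity * scale
        x += -fep_amp * fepsp_shape(rel - cfg.fepsp_onset_ms,
                                    cfg.tau_rise_ms, cfg.tau_decay_ms)
    return Sweep(x, fs=cfg.fs, stim_times=tuple(stim_times),
                 stim_intensity_uA=intensity)


def gen_fepsp_sweeps(cfg: FepspSimConfig
                     ) -> tuple[list[Sweep], list[Sweep], FepspTruth]:
    """Input–output sweeps (one per intensity) and paired-pulse sweeps
    (one per interval, at the maximum intensity), with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    io_sweeps = [
        _one_sweep(cfg, rng, inten, (cfg.stim_time_s,), (1.0,))
        for inten in cfg.intensities_uA
    ]
    top = max(cfg.intensities_uA) if cfg.intensities_uA else 0.0
    pp_sweeps = [
        _one_sweep(cfg, rng, top,
                   (cfg.stim_time_s, cfg.stim_time_s + iv / 1000.0),
                   (1.0, fac))
        for iv, fac in zip(cfg.pp_intervals_ms, cfg.pp_facilitation)
    ]
    truth = FepspTruth(
        fv_amps_mV={i: cfg.fv_gain_mV_per_uA * i for i in cfg.intensities_uA},
        fepsp_amps_mV={i: cfg.fepsp_gain_mV_per_uA * i for i in cfg.intensities_uA},
        ppr=dict(zip(cfg.pp_intervals_ms, cfg.pp_facilitation)),
    )
    return io_sweeps, pp_sweeps, truth
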