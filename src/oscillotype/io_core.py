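"""Time-series data model, file I/O, segment handling and analysis configuration.

The package works on single-channel extracellular voltage traces recorded in
hippocampal slices.  Internally everything is millivolts and seconds; spectral
power is reported in µV² (the slice-inclusion rule is stated in µV², so the
mV→µV conversion happens once, inside the spectrum computation).

Two on-disk formats are supported:

* CSV — either two columns ``time_s,voltage_mV`` or a single ``voltage_mV``
  column with the sampling rate carried in a ``# fs=<Hz>`` header comment.
* raw little-endian float32 with a JSON sidecar ``{"fs_hz": ..., "units":
  "mV", "t0_s": ...}`` stored next to the binary under ``<path>.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class SegmentPurpose(str, Enum):
    GAMMA = "gamma"
    SWR = "swr"
    MUA = "mua"
    EVOKED = "evoked"


#: Default analysis-window length (s) for spontaneous/oscillation segments.
DEFAULT_SEGMENT_S = 120.0


@dataclass(frozen=True)
class Recording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    fs : float
        Sampling rate in Hz (the study's acquisition rate is 5 kHz).
    t0 : float
        Start time in seconds.
    label : str
        Free-text channel/condition tag.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError("sampling rate must be positive and finite")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Same timing/label, new voltage values (e.g. a filtered trace)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class Segment:
    """An analysis window cut from a recording, tagged by analysis purpose."""

    recording: Recording
    purpose: SegmentPurpose
    duration_s: float = DEFAULT_SEGMENT_S

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.duration_s > self.recording.duration + 1e-9:
            raise ValueError(
                f"duration_s={self.duration_s} exceeds recording duration "
                f"{self.recording.duration:.6g} s"
            )


@dataclass
class AnalysisConfig:
    """Every numeric constant of the analysis pipeline in one place.

    Defaults reproduce the study's stated parameters: 4096-sample FFT blocks
    at 5 kHz (1.221 Hz resolution), the 20–80 Hz gamma band, 15–45 Hz phase
    band, 500–3000 Hz unit band, 120–300 Hz ripple band, 45 Hz sharp-wave
    low-pass, the 10 µV²/20 Hz slice-inclusion rule, the 0.0125 mV unit
    amplitude floor, 3·SD event thresholds, 100 ms sharp-wave separation,
    125 ms ripple windows and the 75% ripple-asymmetry cap.
    """

    nfft: int = 4096
    window_name: str = "hann"
    overlap_frac: float = 0.5
    gamma_band: tuple[float, float] = (20.0, 80.0)
    mua_gamma_band: tuple[float, float] = (15.0, 45.0)
    unit_band: tuple[float, float] = (500.0, 3000.0)
    ripple_band: tuple[float, float] = (120.0, 300.0)
    sw_lowpass_hz: float = 45.0
    inclusion_peak_power_uV2: float = 10.0
    inclusion_peak_f_hz: float = 20.0
    unit_amp_floor_mV: float = 0.0125
    unit_refractory_ms: float = 1.0
    unit_snippet_ms: float = 2.0
    sw_sd_mult: float = 3.0
    ripple_sd_mult: float = 3.0
    sw_min_sep_ms: float = 100.0
    ripple_win_ms: float = 125.0
    ripple_pre_ms: float = 15.0
    ripple_post_ms: float = 10.0
    ripple_asym_max: float = 0.75
    ripple_asym_mode: str = "normdiff"  # or "ratio": f/r < cap
    filter_taper_hz: float = 1.0
    min_band_f_hz: float = 1.0
    n_phase_bins: int = 20
    ac2_at_two_periods: bool = False
    tau_n_peaks: int = 8
    sw_robust_baseline: bool = False
    sw_polarity: int = 1
    fepsp_polarity: int = -1
    artifact_blank_ms: float = 1.5
    fv_window_ms: tuple[float, float] = (1.5, 3.5)
    fepsp_window_ms: tuple[float, float] = (4.0, 20.0)
    baseline_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_band", "mua_gamma_band", "unit_band", "ripple_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        for name in (
            "sw_lowpass_hz", "inclusion_peak_power_uV2", "inclusion_peak_f_hz",
            "unit_amp_floor_mV", "sw_sd_mult", "ripple_sd_mult",
            "sw_min_sep_ms", "ripple_win_ms", "ripple_asym_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.nfft < 2:
            raise ValueError("nfft must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gamma_band", "mua_gamma_band", "unit_band", "ripple_band",
                    "fv_window_ms", "fepsp_window_ms"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted as a voltage trace."""


_ALLOWED_UNITS = {"mv", "millivolt", "millivolts"}


def _parse_csv_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip().lower()] = val.strip()
    return meta


def load_timeseries(path: str | Path, format: str | None = None) -> Recording:
    """Load a voltage trace from CSV or raw float32 + JSON sidecar.

    The sampling rate must be present (CSV ``# fs=`` header, a ``time_s``
    column, or the sidecar); unknown voltage units are rejected rather than
    silently rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "raw_f32"

    if format == "csv":
        meta = _parse_csv_header(path)
        units = meta.get("units", "mV").lower()
        if units not in _ALLOWED_UNITS:
            raise FormatError(f"unknown voltage units {units!r}; expected mV")
        try:
            df = pd.read_csv(path, comment="#", float_precision="round_trip")
        except ValueError as exc:
            raise FormatError(f"CSV parse error in {path}: {exc}") from exc
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        for col in cols:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(f"non-numeric value in column {col!r} at data row {row}")
        if "voltage_mv" in cols:
            volts = df["voltage_mv"].to_numpy(dtype=float)
        elif len(cols) == 1:
            volts = df[cols[0]].to_numpy(dtype=float)
        else:
            raise FormatError(f"cannot identify voltage column among {cols}")
        if "time_s" in cols:
            t = df["time_s"].to_numpy(dtype=float)
            if t.size < 2:
                raise FormatError("time_s column needs >= 2 rows to infer fs")
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise FormatError("time_s column is not uniformly sampled")
            fs = 1.0 / dt[0]
            t0 = float(t[0])
        elif "fs" in meta:
            fs = float(meta["fs"])
            t0 = float(meta.get("t0", 0.0))
        else:
            raise FormatError("sampling rate missing: no fs header and no time_s column")
        return Recording(volts, fs=fs, t0=t0, label=meta.get("label", path.stem))

    if format in ("raw_f32", "raw_f32+sidecar"):
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"sidecar {sidecar} missing")
        with open(sidecar) as fh:
            meta = json.load(fh)
        if "fs_hz" not in meta:
            raise FormatError("sampling rate missing from sidecar")
        units = str(meta.get("units", "mV")).lower()
        if units not in _ALLOWED_UNITS:
            raise FormatError(f"unknown voltage units {units!r}; expected mV")
        samples = np.fromfile(path, dtype="<f4").astype(np.float64)
        return Recording(samples, fs=float(meta["fs_hz"]),
                         t0=float(meta.get("t0_s", 0.0)),
                         label=str(meta.get("label", path.stem)))

    raise ValueError(f"unknown format {format!r}")


def write_timeseries(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording; inverse of :func:`load_timeseries` (exact for raw,
    value-preserving for CSV via full-precision repr)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "raw_f32"
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs={float(rec.fs)!r}\n# t0={float(rec.t0)!r}\n# units=mV\n")
            if rec.label:
                fh.write(f"# label={rec.label}\n")
            fh.write("voltage_mV\n")
            for v in rec.samples:
                fh.write(f"{float(v)!r}\n")
    elif format in ("raw_f32", "raw_f32+sidecar"):
        rec.samples.astype("<f4").tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"fs_hz": rec.fs, "units": "mV", "t0_s": rec.t0,
                       "label": rec.label}, fh)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def extract_segment(rec: Recording, t_start: float, duration: float) -> Recording:
    """Cut a contiguous sub-recording [t_start, t_start+duration); no resampling.

    The study analyses two-minute artefact-free windows extracted from the
    plateau of each recording; window choice is the caller's responsibility.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if t_start < rec.t0 - 1e-12:
        raise ValueError(f"t_start={t_start} precedes recording start {rec.t0}")
    i0 = int(round((t_start - rec.t0) * rec.fs))
    n = int(round(duration * rec.fs))
    if i0 + n > rec.n:
        raise ValueError(
            f"window [{t_start}, {t_start + duration}) exceeds recording end "
            f"{rec.t0 + rec.duration:.6g}"
        )
    return replace(rec, samples=rec.samples[i0:i0 + n], t0=rec.t0 + i0 / rec.fs)
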