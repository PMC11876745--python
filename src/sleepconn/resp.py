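"""Respiratory signal conditioning and feature primitives.

Infant respiration recorded with a pressure pad is the single physiological
channel the sleep coder works from.  This module provides the four
primitives everything downstream is built on:

* zero-phase IIR band-pass filtering of the raw trace,
* breath-event detection (peak picking with a physiological refractory
  period),
* the coefficient of variation of the instantaneous breathing rate over a
  time window, and
* Welch power spectral density estimation.

Infant breathing rates span roughly 20-80 breaths per minute (bpm),
i.e. fundamental frequencies of about 0.3-1.3 Hz, which motivates the
default 0.05-5 Hz pass band: wide enough to keep breath morphology and its
first harmonics, tight enough to reject baseline drift and high-frequency
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientSignalError

__all__ = [
    "RespirationTrace",
    "BreathSeries",
    "PsdEstimate",
    "bandpass",
    "detect_breaths",
    "instantaneous_rate_cv",
    "welch_psd",
    "read_physio",
    "write_physio",
    "write_breaths",
    "write_psd",
    "read_two_column_tsv",
]


@dataclass(frozen=True)
class RespirationTrace:
    """Uniformly sampled pressure-pad signal.

    Parameters
    ----------
    samples
        Signal values in arbitrary pressure units.
    sampling_rate
        Sampling frequency in Hz (500 Hz for the acquisition setup this
        models).
    start_time
        Time of the first sample on the session clock, in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("respiration samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples within [t0, t1) on the session clock."""
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.sampling_rate - 1e-9)))
        i1 = min(self.samples.size, int(np.floor((t1 - self.start_time) * self.sampling_rate - 1e-9)) + 1)
        return self.samples[i0:i1]


@dataclass(frozen=True)
class BreathSeries:
    """Detected breath events and derived inter-breath intervals.

    ``inst_rate[i] = 60 / ibi[i]`` in breaths per minute; the invariant
    ``len(ibi) == len(breath_times) - 1`` always holds.
    """

    breath_times: np.ndarray
    ibi: np.ndarray = field(init=False)
    inst_rate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.breath_times, dtype=float)
        if times.size < 2:
            raise ValueError("need at least two breath events")
        if np.any(np.diff(times) <= 0):
            raise ValueError("breath_times must be strictly increasing")
        object.__setattr__(self, "breath_times", times)
        object.__setattr__(self, "ibi", np.diff(times))
        object.__setattr__(self, "inst_rate", 60.0 / np.diff(times))


@dataclass(frozen=True)
class PsdEstimate:
    """Welch power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    window_s: float
    overlap_fraction: float

    def band_power(self, low: float, high: float) -> float:
        """Integrated power (trapezoidal) within [low, high] Hz."""
        mask = (self.frequencies >= low) & (self.frequencies <= high)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.power[mask], self.frequencies[mask]))


def bandpass(trace: RespirationTrace, low: float = 0.05, high: float = 5.0,
             order: int = 4) -> RespirationTrace:
    """Zero-phase IIR band-pass filter.

    A Butterworth high-pass at `low` cascaded with a Butterworth low-pass at
    `high` (both of the given order), applied forward-backward
    (``sosfiltfilt``) so breath-peak times are not shifted.
    """
    nyq = trace.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos_hp = signal.butter(order, low, btype="highpass", fs=trace.sampling_rate, output="sos")
    sos_lp = signal.butter(order, high, btype="lowpass", fs=trace.sampling_rate, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return RespirationTrace(filtered, trace.sampling_rate, trace.start_time)


def detect_breaths(trace: RespirationTrace, min_separation_s: float = 0.45,
                   prominence_factor: float = 0.5,
                   rolling_window_s: float = 30.0) -> BreathSeries:
    """Detect one event per breath by local-maximum picking.

    Two constraints define a breath peak: a refractory period of
    `min_separation_s` between events (just above the ~80 bpm physiological
    ceiling), and a prominence of at least `prominence_factor` times the
    rolling standard deviation of the signal over `rolling_window_s`, which
    adapts the threshold to slow amplitude changes.

    The trace is expected to be band-passed first.

    Raises
    ------
    InsufficientSignalError
        If fewer than three peaks are found.
    """
    x = trace.samples
    fs = trace.sampling_rate
    win = max(3, int(round(rolling_window_s * fs)))
    m1 = uniform_filter1d(x, win, mode="reflect")
    m2 = uniform_filter1d(x * x, win, mode="reflect")
    rolling_sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    prominence = np.maximum(prominence_factor * rolling_sd, 1e-12)
    peaks, _ = signal.find_peaks(x, distance=max(1, int(round(min_separation_s * fs))),
                                 prominence=prominence)
    if peaks.size < 3:
        raise InsufficientSignalError(
            f"only {peaks.size} breath events detected; need at least 3"
        )
    return BreathSeries(trace.start_time + peaks / fs)


def instantaneous_rate_cv(breaths: BreathSeries, window: tuple[float, float]) -> float:
    """Coefficient of variation of inter-breath intervals within a window.

    Only intervals with both endpoints inside [t0, t1) count.  Uses the
    sample (n-1) standard deviation.  Returns NaN when fewer than three
    breaths fall in the window, which downstream coding treats as an
    indeterminate epoch.
    """
    t0, t1 = window
    inside = (breaths.breath_times >= t0) & (breaths.breath_times < t1)
    if inside.sum() < 3:
        return float("nan")
    idx = np.flatnonzero(inside)
    ibis = breaths.ibi[idx[0]: idx[-1]]
    return float(np.std(ibis, ddof=1) / np.mean(ibis))


def welch_psd(samples: np.ndarray, sampling_rate: float, window_s: float = 10.0,
              overlap: float = 0.5) -> PsdEstimate:
    """Welch PSD: mean of Hann-windowed periodograms over overlapping windows.

    The frequency resolution is 1/window_s (0.1 Hz for the default 10-s
    window) regardless of segment length.
    """
    samples = np.asarray(samples, dtype=float)
    nperseg = int(round(window_s * sampling_rate))
    if samples.size < nperseg:
        raise ValueError(
            f"segment of {samples.size / sampling_rate:.1f} s is shorter than one "
            f"{window_s:.1f} s Welch window"
        )
    freqs, power = signal.welch(
        samples, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend="constant", average="mean",
    )
    return PsdEstimate(freqs, power, window_s, overlap)


# ---------------------------------------------------------------------------
# I/O: BIDS-style physiological recordings and plain two-column TSV
# ---------------------------------------------------------------------------

def write_physio(trace: RespirationTrace, prefix: str | Path) -> tuple[Path, Path]:
    """Write a trace as `<prefix>_physio.tsv.gz` + `<prefix>_physio.json`.

    The sidecar follows the BIDS physiological-recording convention
    (SamplingFrequency, StartTime, Columns).
    """
    import pandas as pd

    prefix = Path(prefix)
    tsv_path = prefix.with_name(prefix.name + "_physio.tsv.gz")
    json_path = prefix.with_name(prefix.name + "_physio.json")
    pd.DataFrame({"respiratory": trace.samples}).to_csv(
        tsv_path, sep="\t", header=False, index=False, float_format="%.6f",
        compression={"method": "gzip", "compresslevel": 1})
    sidecar = {
        "SamplingFrequency": trace.sampling_rate,
        "StartTime": trace.start_time,
        "Columns": ["respiratory"],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return tsv_path, json_path


def read_physio(tsv_path: str | Path) -> RespirationTrace:
    """Read a BIDS-style physio TSV(.gz) with its JSON sidecar."""
    tsv_path = Path(tsv_path)
    name = tsv_path.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            json_path = tsv_path.with_name(name[: -len(suffix)] + ".json")
            break
    else:
        raise ValueError(f"expected a .tsv or .tsv.gz file, got {tsv_path}")
    import pandas as pd

    sidecar = json.loads(json_path.read_text())
    data = pd.read_csv(tsv_path, sep="\t", header=None).to_numpy(float)
    col = sidecar.get("Columns", ["respiratory"]).index("respiratory")
    return RespirationTrace(
        data[:, col], float(sidecar["SamplingFrequency"]), float(sidecar.get("StartTime", 0.0))
    )


def write_breaths(breaths: BreathSeries, path: str | Path) -> None:
    """Write breath events as TSV (breath_time_s, ibi_s, inst_rate_bpm).

    The interval columns describe the interval ending at each breath; the
    first row has no preceding interval and stores NaN.
    """
    import pandas as pd

    pd.DataFrame({
        "breath_time_s": breaths.breath_times,
        "ibi_s": np.concatenate([[np.nan], breaths.ibi]),
        "inst_rate_bpm": np.concatenate([[np.nan], breaths.inst_rate]),
    }).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_psd(psd: PsdEstimate, path: str | Path) -> None:
    """Write a PSD estimate as TSV (frequency_hz, power)."""
    import pandas as pd

    pd.DataFrame({"frequency_hz": psd.frequencies, "power": psd.power}).to_csv(
        path, sep="\t", index=False, float_format="%.8g")


def read_two_column_tsv(path: str | Path) -> RespirationTrace:
    """Read a plain (time_s, value) TSV; the time column must be uniform."""
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("expected two columns: time_s, value")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time column is not uniformly sampled")
    return RespirationTrace(v, 1.0 / dt[0], float(t[0]))
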