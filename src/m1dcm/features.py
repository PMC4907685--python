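"""Empirical spectral features of a virtual-electrode recording.

A recording is a single source-space time series (default 600 Hz) with
visual-cue onset times.  Around each cue the task structure defines three
one-second analysis windows: rest [-1, 0] s, grip [1, 2] s and post-grip
[4, 5] s.  Windows are cut per trial, concatenated within condition, and
summarised as auto-spectra on the shared 5-45 Hz grid; a percent-change
Morlet spectrogram over the whole peri-cue interval serves as visual QC
(movement-related beta desynchronisation during grip, rebound after).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.signal

from .config import default_frequency_grid
from .errors import ParameterError, ShapeError
from .spectral import SpectralPrediction

__all__ = [
    "CONDITION_WINDOWS",
    "VirtualElectrodeRecording",
    "EpochSet",
    "Spectrogram",
    "epoch_and_concatenate",
    "estimate_psd",
    "morlet_spectrogram",
]

#: Analysis windows in seconds relative to cue onset.
CONDITION_WINDOWS: dict[str, tuple[float, float]] = {
    "rest": (-1.0, 0.0),
    "grip": (1.0, 2.0),
    "post_grip": (4.0, 5.0),
}


@dataclass
class VirtualElectrodeRecording:
    """Single-channel source time series with cue events."""

    samples: np.ndarray
    fs: float = 600.0
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        self.events = np.atleast_1d(np.asarray(self.events, dtype=float))
        if self.fs <= 2 * 45.0:
            raise ParameterError(
                "sampling rate must exceed twice the highest analysis frequency"
            )
        span = self.samples.size / self.fs
        if np.any((self.events < 0) | (self.events > span)):
            raise ParameterError("events must lie within the recording span")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    # -- CSV round trip -------------------------------------------------
    def to_csv(self, path) -> None:
        t = np.arange(self.samples.size) / self.fs
        df = pd.DataFrame({"time_s": t, "signal": self.samples})
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={self.fs}\n")
            fh.write(f"# subject={self.subject_id}\n")
            fh.write("# events_s=" + ",".join(f"{e:.6f}" for e in self.events) + "\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "VirtualElectrodeRecording":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
        df = pd.read_csv(path, comment="#")
        events = (
            np.array([float(x) for x in meta.get("events_s", "").split(",") if x])
            if meta.get("events_s") else np.empty(0)
        )
        return cls(
            samples=df["signal"].to_numpy(),
            fs=float(meta.get("fs_hz", 600.0)),
            events=events,
            subject_id=meta.get("subject", ""),
        )


@dataclass
class EpochSet:
    """Per-condition concatenated segments plus bookkeeping."""

    segments: dict[str, np.ndarray]
    fs: float
    windows: dict[str, tuple[float, float]]
    n_trials: int
    n_dropped: int

    def duration(self, condition: str) -> float:
        return self.segments[condition].size / self.fs


def epoch_and_concatenate(rec: VirtualElectrodeRecording) -> EpochSet:
    """Cut the three condition windows around every cue and concatenate
    within condition (trial order preserved).  Trials whose windows run
    past either end of the recording are dropped with a warning."""
    windows = dict(CONDITION_WINDOWS)
    pre = min(w[0] for w in windows.values())
    post = max(w[1] for w in windows.values())
    kept, dropped = [], 0
    for ev in rec.events:
        if ev + pre < 0 or ev + post > rec.duration + 1e-9:
            dropped += 1
        else:
            kept.append(ev)
    if dropped:
        warnings.warn(
            f"dropped {dropped} trial(s) too close to the recording edge",
            stacklevel=2,
        )
    segments: dict[str, list[np.ndarray]] = {c: [] for c in windows}
    n_win = int(round(rec.fs))  # one-second windows
    for ev in kept:
        for cond, (a, b) in windows.items():
            i0 = int(round((ev + a) * rec.fs))
            segments[cond].append(rec.samples[i0:i0 + n_win])
    return EpochSet(
        segments={
            c: (np.concatenate(v) if v else np.empty(0))
            for c, v in segments.items()
        },
        fs=rec.fs,
        windows=windows,
        n_trials=len(kept),
        n_dropped=dropped,
    )


def estimate_psd(
    segments: np.ndarray,
    fs: float,
    band: tuple[float, float] = (5.0, 45.0),
    grid: np.ndarray | None = None,
    window_s: float = 1.0,
    overlap: float = 0.5,
    method: str = "welch",
    ar_order: int = 30,
    condition: str = "rest",
) -> SpectralPrediction:
    """Auto-spectral density of a (concatenated) signal on the shared grid.

    The default estimator is an averaged cosine-tapered periodogram
    (Welch, one-second windows, 50% overlap) interpolated onto the 0.5 Hz
    grid and truncated to the 5-45 Hz band; ``method="ar"`` substitutes a
    Yule-Walker autoregressive spectrum.  Output is strictly positive.
    """
    x = np.asarray(segments, dtype=float).ravel()
    if x.size < int(fs * window_s):
        raise ParameterError("input must contain at least one analysis window")
    grid = default_frequency_grid() if grid is None else np.asarray(grid, float)
    grid = grid[(grid >= band[0] - 1e-9) & (grid <= band[1] + 1e-9)]

    if method == "welch":
        nperseg = int(round(fs * window_s))
        f, pxx = scipy.signal.welch(
            x, fs=fs, window="hann", nperseg=nperseg,
            noverlap=int(round(nperseg * overlap)),
        )
    elif method == "ar":
        from statsmodels.regression.linear_model import yule_walker

        rho, sigma = yule_walker(x - x.mean(), order=ar_order, method="mle")
        f = np.linspace(0.0, fs / 2.0, 2048)
        z = np.exp(-2j * np.pi * np.outer(f / fs, np.arange(1, ar_order + 1)))
        denom = np.abs(1.0 - z @ rho) ** 2
        pxx = 2.0 * sigma**2 / fs / denom
    else:
        raise ParameterError(f"unknown spectral estimator {method!r}")

    interp = scipy.interpolate.interp1d(f, pxx, kind="linear", bounds_error=True)
    psd = np.maximum(interp(grid), np.finfo(float).tiny)
    return SpectralPrediction(freqs=grid, psd=psd, condition=condition)


@dataclass
class Spectrogram:
    """Trial-averaged time-frequency power, optionally rescaled to percent
    change from the pre-cue baseline."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray          # (n_freqs, n_times)
    percent_change: bool = False
    baseline: tuple[float, float] = (-1.0, 0.0)


def morlet_spectrogram(
    rec: VirtualElectrodeRecording,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
    tmin: float = -1.0,
    tmax: float = 5.0,
    baseline: tuple[float, float] = (-1.0, 0.0),
) -> Spectrogram:
    """Trial-averaged Morlet-wavelet spectrogram over the peri-cue window,
    expressed as percent change from the per-frequency baseline mean."""
    from mne.time_frequency import tfr_array_morlet

    freqs = np.arange(5.0, 45.5, 0.5) if freqs is None else np.asarray(freqs, float)
    n_pre = int(round(-tmin * rec.fs))
    n_post = int(round(tmax * rec.fs))
    trials = []
    for ev in rec.events:
        i = int(round(ev * rec.fs))
        if i - n_pre < 0 or i + n_post > rec.samples.size:
            continue
        trials.append(rec.samples[i - n_pre:i + n_post])
    if not trials:
        raise ParameterError("no complete trials in the recording")
    data = np.asarray(trials)[:, None, :]  # (n_trials, 1 channel, n_times)

    power = tfr_array_morlet(
        data, sfreq=rec.fs, freqs=freqs, n_cycles=n_cycles, output="power",
        zero_mean=True,
    )[:, 0, :, :]  # (n_trials, n_freqs, n_times)
    times = (np.arange(n_pre + n_post) - n_pre) / rec.fs

    # average across trials before the baseline ratio: dividing by a noisy
    # per-trial baseline would bias the percent change upward (Jensen)
    avg = power.mean(axis=0)
    base_sel = (times >= baseline[0]) & (times < baseline[1])
    base = avg[:, base_sel].mean(axis=1, keepdims=True)
    pct = 100.0 * (avg - base) / base
    return Spectrogram(
        times=times, freqs=freqs, power=pct,
        percent_change=True, baseline=baseline,
    )
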