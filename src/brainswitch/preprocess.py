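"""Band-pass filtering, large-Laplacian virtual Cz, epoching and windowing.

The detection path filters causally (single forward pass, as an online system
would); the morphology path filters forward-backward for zero phase lag.
The virtual Cz channel is ``Cz - mean(8 surrounding 10-20 sites)``, the large
surface Laplacian that rejects the common-mode background and sharpens the
focal sources over the foot motor area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import (
    BoundaryError,
    InvalidParameterError,
    MissingChannelError,
)
from .simulate import CENTER_LABEL, NEIGHBOR_LABELS, Recording

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "VirtualChannel",
    "EpochSet",
    "WindowSet",
    "bandpass_filter",
    "large_laplacian",
    "extract_epochs",
    "sliding_windows",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float  # Hz
    high: float  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise InvalidParameterError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low}, {self.high})")


#: The six analysis bands: MRCP (near-DC), theta, alpha, beta, lower gamma
#: and the full 0.05-40 Hz range.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "mrcp": BandDefinition("mrcp", 0.05, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 15.0),
    "beta": BandDefinition("beta", 16.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 40.0),
    "full": BandDefinition("full", 0.05, 40.0),
}


@dataclass
class VirtualChannel:
    """Single surface-Laplacian channel derived from a 9-channel montage."""

    samples: np.ndarray  # µV
    sampling_rate: float
    center_label: str = CENTER_LABEL
    neighbor_labels: tuple[str, ...] = NEIGHBOR_LABELS

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """Per-trial virtual-Cz segments on a common cue-relative time axis."""

    data: np.ndarray  # [trials x samples]
    times: np.ndarray  # s relative to the cue
    sampling_rate: float
    reference_interval: tuple[float, float] = (-3.0, -2.0)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def reference_mask(self) -> np.ndarray:
        lo, hi = self.reference_interval
        return (self.times >= lo) & (self.times < hi)


@dataclass
class WindowSet:
    """Causal sliding windows with signal/noise labels.

    ``end_times`` are the absolute trailing-edge times (the causal timestamp
    at which each window becomes fully observed).  A window is labelled
    ``"signal"`` when its trailing edge falls in ``(cue - 1 s, cue + 1 s]``
    for some cue, otherwise ``"noise"``.  ``"excluded"`` is reserved for
    windows a caller masks out (e.g. artifact rejection).
    """

    windows: np.ndarray  # [n x window_samples]
    end_times: np.ndarray  # s, absolute
    labels: np.ndarray  # str array: signal | noise | excluded
    sampling_rate: float
    length: float
    step: float

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def is_signal(self) -> np.ndarray:
        return self.labels == "signal"


def _design_bandpass(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    if band.high >= sampling_rate / 2:
        raise InvalidParameterError(
            f"band {band.name!r} high cutoff {band.high} Hz >= Nyquist "
            f"({sampling_rate / 2} Hz)")
    return sps.butter(2, [band.low, band.high], btype="bandpass",
                      fs=sampling_rate, output="sos")


def _apply_bandpass(x: np.ndarray, band: BandDefinition, sampling_rate: float,
                    mode: str) -> np.ndarray:
    sos = _design_bandpass(band, sampling_rate)
    if mode == "causal":
        return sps.sosfilt(sos, x, axis=-1)
    if mode == "zero_phase":
        return sps.sosfiltfilt(sos, x, axis=-1)
    raise InvalidParameterError(f"unknown filter mode {mode!r}")


def bandpass_filter(recording: Recording, band: BandDefinition,
                    mode: str = "causal") -> Recording:
    """2nd-order Butterworth band-pass, applied independently per channel.

    ``causal`` runs a single forward pass (the pseudo-online detection path);
    ``zero_phase`` runs forward-backward (the morphology path).
    """
    filtered = _apply_bandpass(recording.samples, band,
                               recording.sampling_rate, mode)
    return Recording(samples=filtered, channel_labels=recording.channel_labels,
                     sampling_rate=recording.sampling_rate,
                     events=list(recording.events))


def large_laplacian(recording: Recording, center: str = CENTER_LABEL,
                    neighbors: Sequence[str] = NEIGHBOR_LABELS) -> VirtualChannel:
    """Virtual Cz: ``center - mean(neighbors)``, computed exactly."""
    labels = list(recording.channel_labels)
    for lab in (center, *neighbors):
        if lab not in labels:
            raise MissingChannelError(f"channel {lab!r} missing from recording")
    c = recording.samples[labels.index(center)]
    nb = recording.samples[[labels.index(l) for l in neighbors]]
    return VirtualChannel(samples=c - nb.mean(axis=0),
                          sampling_rate=recording.sampling_rate,
                          center_label=center,
                          neighbor_labels=tuple(neighbors))


def extract_epochs(virtual: VirtualChannel, cues: Iterable[float],
                   tmin: float = -3.0, tmax: float = 6.0,
                   reference_interval: tuple[float, float] = (-3.0, -2.0)
                   ) -> EpochSet:
    """Cut one ``[tmin, tmax)`` segment of the virtual channel per cue.

    No baseline subtraction happens here; downstream statistics reference
    against the declared interval themselves.
    """
    if tmax <= tmin:
        raise InvalidParameterError("tmax must exceed tmin")
    fs = virtual.sampling_rate
    n = int(round((tmax - tmin) * fs))
    rows = []
    for cue in cues:
        start = int(round((cue + tmin) * fs))
        if start < 0 or start + n > virtual.n_samples:
            raise BoundaryError(
                f"cue at {cue:.3f} s needs data on [{cue + tmin:.3f}, "
                f"{cue + tmax:.3f}] s, outside the recording")
        rows.append(virtual.samples[start:start + n])
    data = np.array(rows) if rows else np.empty((0, n))
    times = tmin + np.arange(n) / fs
    return EpochSet(data=data, times=times, sampling_rate=fs,
                    reference_interval=reference_interval)


def sliding_windows(virtual: VirtualChannel, cues: Sequence[float],
                    length: float = 2.0, step: float = 0.1,
                    signal_halfwidth: float = 1.0) -> WindowSet:
    """Causal 2-s / 0.1-s sliding segmentation with signal/noise labels.

    Trailing edges run from ``length`` to the recording end in steps of
    ``step``; the label is ``signal`` iff the trailing edge lies in the
    half-open interval ``(cue - 1, cue + 1]`` s for some cue.  Comparisons
    are done on integer sample indices so the boundaries are exact.
    """
    fs = virtual.sampling_rate
    n_len = int(round(length * fs))
    n_step = int(round(step * fs))
    if n_len <= 0 or n_step <= 0:
        raise InvalidParameterError("length and step must be > 0")
    if virtual.n_samples < n_len:
        raise InvalidParameterError("recording shorter than one window")
    ends = np.arange(n_len, virtual.n_samples + 1, n_step)
    starts = ends - n_len
    windows = np.stack([virtual.samples[s:e] for s, e in zip(starts, ends)])
    half = int(round(signal_halfwidth * fs))
    cue_samples = np.round(np.asarray(cues, dtype=float) * fs).astype(int)
    labels = np.full(ends.size, "noise", dtype="<U8")
    for c in cue_samples:
        labels[(ends > c - half) & (ends <= c + half)] = "signal"
    return WindowSet(windows=windows, end_times=ends / fs, labels=labels,
                     sampling_rate=fs, length=length, step=step)
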