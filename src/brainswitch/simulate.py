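"""Seeded simulation of motor-imagery EEG sessions with known ground truth.

A session mimics a cue-paced imagery experiment: each trial walks through an
idle / focus / preparation / task phase sequence, with the cue (imagery onset)
at the start of the 4-s task phase.  Two sources are injected on top of
correlated 1/f + white background noise:

* a movement-related cortical potential (MRCP) — a slow negative deflection
  peaking at the cue, with a task-dependent rebound (ballistic: back to
  baseline within ~2 s; repetitive: sustained negativity through the task
  phase), and
* band-limited sensorimotor-rhythm (SMR) carriers whose amplitude is
  modulated around each cue (ERD dip followed by an ERS rebound; the ERS is
  delayed for repetitive imagery).

Sources are injected through a spatial profile peaking at Cz and normalised
so the large Laplacian (virtual Cz) recovers them with unit gain, which makes
ground truth exactly recoverable in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidParameterError

__all__ = [
    "CHANNEL_LABELS",
    "CENTER_LABEL",
    "NEIGHBOR_LABELS",
    "BandSpec",
    "NoiseParams",
    "PhaseDurations",
    "SimulationConfig",
    "Event",
    "Recording",
    "mrcp_template",
    "smr_modulation_profile",
    "background_noise",
    "generate_session",
]

#: Standard 10-20 montage used throughout: Cz plus its eight surrounding sites.
CHANNEL_LABELS = ("Cz", "Fz", "F3", "F4", "C3", "C4", "P3", "P4", "Pz")
CENTER_LABEL = "Cz"
NEIGHBOR_LABELS = tuple(l for l in CHANNEL_LABELS if l != CENTER_LABEL)

#: Extra delay (s) of the ERS rebound in repetitive relative to ballistic
#: imagery: with a 4-s repetitive task the beta rebound follows task end,
#: whereas a ballistic rebound follows the single imagined contraction.
REPETITIVE_ERS_DELAY = 2.7

#: Epoch span (s) relative to the cue used for templates and envelopes.
TEMPLATE_SPAN = (-3.0, 6.0)


class Event(NamedTuple):
    onset: float  # seconds from recording start
    label: str  # "cue" or "run_start"


@dataclass(frozen=True)
class BandSpec:
    """One SMR carrier band and its event-related modulation.

    ``erd_onset``/``ers_onset`` are in seconds relative to the cue and refer
    to the ballistic task; :func:`smr_modulation_profile` derives the
    repetitive timing (delayed ERS, ERD sustained over the 4-s task).
    """

    center: float  # Hz
    bandwidth: float  # Hz (full width)
    amplitude: float = 2.0  # µV RMS of the carrier at virtual Cz
    erd_depth: float = 0.5  # in [0, 1]; 0 disables the ERD dip
    ers_gain: float = 2.0  # >= 1; 1 disables the ERS bump
    erd_onset: float = -0.5
    erd_duration: float = 1.5
    ers_onset: float = 0.8
    ers_duration: float = 1.5

    def validate(self) -> None:
        if not (0.0 < self.center and 0.0 < self.bandwidth):
            raise InvalidParameterError("band center and bandwidth must be > 0")
        if self.amplitude < 0:
            raise InvalidParameterError("carrier amplitude must be >= 0")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise InvalidParameterError("ERD depth must lie in [0, 1]")
        if self.ers_gain < 1.0:
            raise InvalidParameterError("ERS gain must be >= 1")
        if self.erd_duration <= 0 or self.ers_duration <= 0:
            raise InvalidParameterError("modulation durations must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    pink_amplitude: float = 8.0  # µV RMS per channel, 1/f component
    white_amplitude: float = 2.0  # µV RMS per channel, white component
    mixing: float = 0.5  # fraction of noise variance shared across channels

    def validate(self) -> None:
        if self.pink_amplitude < 0 or self.white_amplitude < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")
        if not 0.0 <= self.mixing <= 1.0:
            raise InvalidParameterError("noise mixing must lie in [0, 1]")


@dataclass(frozen=True)
class PhaseDurations:
    """Per-trial phase lengths in seconds (idle, focus, preparation, task)."""

    idle: float = 5.0
    focus: float = 2.0
    preparation: float = 3.0
    task: float = 4.0

    @property
    def trial(self) -> float:
        return self.idle + self.focus + self.preparation + self.task

    @property
    def cue_offset(self) -> float:
        """Task-phase onset relative to trial start."""
        return self.idle + self.focus + self.preparation

    def validate(self) -> None:
        for name in ("idle", "focus", "preparation", "task"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"phase duration {name!r} must be > 0")


def _default_bands() -> tuple[BandSpec, ...]:
    # Alpha (mu) and beta carriers; beta shows the classic post-onset rebound.
    return (
        BandSpec(center=11.5, bandwidth=7.0, amplitude=2.0, erd_depth=0.4,
                 ers_gain=1.3, erd_onset=-0.5, erd_duration=2.0,
                 ers_onset=1.2, ers_duration=1.5),
        BandSpec(center=23.0, bandwidth=14.0, amplitude=2.0, erd_depth=0.5,
                 ers_gain=2.0, erd_onset=-0.5, erd_duration=1.5,
                 ers_onset=0.8, ers_duration=1.5),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated session (one task kind)."""

    sampling_rate: float = 1200.0  # Hz
    channel_labels: tuple[str, ...] = CHANNEL_LABELS
    n_runs: int = 3
    trials_per_run: int = 20
    task_kind: str = "ballistic"  # or "repetitive"
    phase_durations: PhaseDurations = field(default_factory=PhaseDurations)
    mrcp_amplitude: float = 8.0  # µV peak negativity at virtual Cz
    smr_bands: tuple[BandSpec, ...] = field(default_factory=_default_bands)
    noise: NoiseParams = field(default_factory=NoiseParams)
    spatial_profile: dict[str, float] | None = None  # None -> Cz 1.0, rest 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if len(self.channel_labels) != 9 or len(set(self.channel_labels)) != 9:
            raise InvalidParameterError("channel_labels must be 9 distinct names")
        if CENTER_LABEL not in self.channel_labels:
            raise InvalidParameterError("channel_labels must include 'Cz'")
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise InvalidParameterError("n_runs and trials_per_run must be >= 1")
        if self.task_kind not in ("ballistic", "repetitive"):
            raise InvalidParameterError(f"unknown task_kind {self.task_kind!r}")
        if self.mrcp_amplitude < 0:
            raise InvalidParameterError("mrcp_amplitude must be >= 0")
        self.phase_durations.validate()
        self.noise.validate()
        for band in self.smr_bands:
            band.validate()
            if band.center + band.bandwidth / 2 >= self.sampling_rate / 2:
                raise InvalidParameterError(
                    f"band at {band.center} Hz exceeds Nyquist")
        profile = self.resolve_profile()
        if not np.all(np.isfinite(profile)):
            raise InvalidParameterError("spatial profile must be finite")

    def resolve_profile(self) -> np.ndarray:
        """Per-channel source gain aligned with ``channel_labels``."""
        mapping = self.spatial_profile
        if mapping is None:
            mapping = {lab: (1.0 if lab == CENTER_LABEL else 0.3)
                       for lab in self.channel_labels}
        try:
            return np.array([float(mapping[lab]) for lab in self.channel_labels])
        except KeyError as exc:  # pragma: no cover - config error path
            raise InvalidParameterError(f"spatial profile misses {exc}") from exc

    @property
    def run_duration(self) -> float:
        """Run length in s: trials plus a trailing idle pad so that the last
        cue still has 6 s of post-cue data."""
        return self.trials_per_run * self.phase_durations.trial + self.phase_durations.idle


@dataclass
class Recording:
    """A multi-channel EEG recording with cue / run-boundary events."""

    samples: np.ndarray  # [channels x time], µV
    channel_labels: tuple[str, ...]
    sampling_rate: float
    events: list[Event]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidParameterError("samples must be 2-D [channels x time]")
        if self.samples.shape[0] != len(self.channel_labels):
            raise InvalidParameterError("channel count must match label count")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidParameterError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] > self.duration):
            raise InvalidParameterError("event onsets must lie inside the recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def cue_times(self) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.label == "cue"])

    def run_starts(self) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.label == "run_start"])


# ---------------------------------------------------------------------------
# Templates and envelopes
# ---------------------------------------------------------------------------

def _raised_cosine(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """Smooth 0->1 ramp over [start, start+duration], clamped outside."""
    x = np.clip((t - start) / duration, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _hann_bump(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """Unit-peak Hann bump supported on [start, start+duration]."""
    x = (t - start) / duration
    inside = (x >= 0.0) & (x <= 1.0)
    out = np.zeros_like(t)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    return out


def template_time_axis(sampling_rate: float) -> np.ndarray:
    n = int(round((TEMPLATE_SPAN[1] - TEMPLATE_SPAN[0]) * sampling_rate)) + 1
    return TEMPLATE_SPAN[0] + np.arange(n) / sampling_rate


def mrcp_template(task_kind: str, amplitude: float,
                  sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """MRCP waveform on t in [-3, 6] s relative to the cue.

    Both task kinds share the pre-onset limb: a smooth fall starting 2 s
    before the cue reaching the negative peak ``-amplitude`` exactly at t = 0.
    Ballistic: rebound crossing baseline within ~1 s, a small positive
    overshoot, and return to zero by t = 2 s.  Repetitive: rebound only to a
    sustained negative plateau covering the 4-s task phase, decaying to zero
    afterwards.

    Returns ``(t, waveform)`` in seconds / µV.
    """
    if amplitude < 0:
        raise InvalidParameterError("MRCP amplitude must be >= 0")
    if task_kind not in ("ballistic", "repetitive"):
        raise InvalidParameterError(f"unknown task_kind {task_kind!r}")
    t = template_time_axis(sampling_rate)
    w = np.zeros_like(t)
    # Shared pre-onset fall: starts 2 s before the cue but stays shallow
    # until ~1 s before onset (convex time warp of a raised cosine), so the
    # deflection becomes distinguishable from baseline only from about -1 s.
    x = np.clip((t + 2.0) / 2.0, 0.0, 1.0)
    w -= amplitude * 0.5 * (1.0 - np.cos(np.pi * x ** 2))
    if task_kind == "ballistic":
        overshoot = 0.05 * amplitude
        # Rebound: -A at 0 up to +overshoot at 1 s ...
        w += (amplitude + overshoot) * _raised_cosine(t, 0.0, 1.0)
        # ... then decay of the overshoot back to 0 by 2 s.
        w -= overshoot * _raised_cosine(t, 1.0, 1.0)
    else:
        plateau = 0.6 * amplitude
        # Partial rebound to a sustained plateau of -0.6 A by 0.5 s.
        w += (amplitude - plateau) * _raised_cosine(t, 0.0, 0.5)
        # Plateau decays to baseline only after the 4-s task phase.
        w += plateau * _raised_cosine(t, 4.0, 1.5)
    # Fall/rise segments are exactly zero outside [-2, support end].
    return t, w


def smr_modulation_profile(task_kind: str, band_spec: BandSpec,
                           sampling_rate: float = 100.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Time-varying amplitude gain for one SMR carrier on t in [-3, 6] s.

    Gain is 1 at baseline, dips to ``1 - erd_depth`` during the ERD window
    and rises to ``ers_gain`` during the ERS window.  For repetitive imagery
    the ERD is sustained across the full 4-s task phase and the ERS is
    delayed by :data:`REPETITIVE_ERS_DELAY` seconds.
    """
    band_spec.validate()
    if task_kind not in ("ballistic", "repetitive"):
        raise InvalidParameterError(f"unknown task_kind {task_kind!r}")
    t = template_time_axis(sampling_rate)
    return t, _gain_curve(task_kind, band_spec, t)


def _gain_curve(task_kind: str, spec: BandSpec, t: np.ndarray) -> np.ndarray:
    erd_on, erd_dur = spec.erd_onset, spec.erd_duration
    ers_on, ers_dur = spec.ers_onset, spec.ers_duration
    if task_kind == "repetitive":
        # ERD covers the whole task phase; beta rebound follows task end.
        erd_dur = max(erd_dur, 4.0 - erd_on)
        ers_on = ers_on + REPETITIVE_ERS_DELAY
    gain = np.ones_like(t)
    gain -= spec.erd_depth * _hann_bump(t, erd_on, erd_dur)
    gain += (spec.ers_gain - 1.0) * _hann_bump(t, ers_on, ers_dur)
    return gain


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def _unit_pink(n: int, sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-spectrum noise via spectral shaping of white noise.

    The PSD follows 1/f above a low-frequency shelf at 0.05 Hz (or the first
    FFT bin, whichever is larger) so the series has no unbounded drift.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    shelf = max(0.05, sampling_rate / n)
    scale = 1.0 / np.sqrt(np.maximum(f, shelf))
    scale[0] = 0.0  # remove DC
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _unit_white(n: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    return x / x.std()


def background_noise(duration: float, n_channels: int,
                     noise_params: NoiseParams,
                     seed: int | np.random.Generator = 0,
                     sampling_rate: float = 1200.0) -> np.ndarray:
    """Correlated pink + white EEG background, shape [channels x time] in µV.

    Each channel is ``sqrt(mixing) * common + sqrt(1 - mixing) * own`` for
    both components, so per-channel RMS equals the configured amplitudes
    while neighbouring channels share a common-mode part (which the surface
    Laplacian will reject).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    noise_params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    out = np.zeros((n_channels, n))
    m = noise_params.mixing
    for amplitude, maker in ((noise_params.pink_amplitude,
                              lambda: _unit_pink(n, sampling_rate, rng)),
                             (noise_params.white_amplitude,
                              lambda: _unit_white(n, rng))):
        common = maker()
        for ch in range(n_channels):
            own = maker()
            out[ch] += amplitude * (np.sqrt(m) * common + np.sqrt(1.0 - m) * own)
    return out


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def _unit_band_carrier(n: int, spec: BandSpec, sampling_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise carrier for one SMR band."""
    low = max(spec.center - spec.bandwidth / 2.0, 0.1)
    high = min(spec.center + spec.bandwidth / 2.0, 0.99 * sampling_rate / 2.0)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=sampling_rate,
                     output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_session(config: SimulationConfig) -> Recording:
    """Simulate one session: ``n_runs`` concatenated runs of cue-paced trials.

    Deterministic in ``(config, config.seed)``: a single generator seeded
    once drives every stochastic draw in a fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    phases = config.phase_durations
    run_dur = config.run_duration
    n_total = int(round(config.n_runs * run_dur * fs))

    events: list[Event] = []
    cue_samples: list[int] = []
    for run in range(config.n_runs):
        run_t0 = run * run_dur
        events.append(Event(run_t0, "run_start"))
        for trial in range(config.trials_per_run):
            cue_t = run_t0 + trial * phases.trial + phases.cue_offset
            events.append(Event(cue_t, "cue"))
            cue_samples.append(int(round(cue_t * fs)))
    events.sort(key=lambda e: e.onset)

    # 1) background noise (all channels), 2) SMR carriers, in fixed rng order
    samples = background_noise(config.n_runs * run_dur, len(config.channel_labels),
                               config.noise, rng, fs)

    source = np.zeros(n_total)
    _, template = mrcp_template(config.task_kind, config.mrcp_amplitude, fs)
    t0_offset = int(round(-TEMPLATE_SPAN[0] * fs))  # samples before the cue
    for c in cue_samples:
        lo = c - t0_offset
        hi = lo + template.size
        src_lo, src_hi = max(lo, 0), min(hi, n_total)
        source[src_lo:src_hi] += template[src_lo - lo:template.size - (hi - src_hi)]

    t_rel = template_time_axis(fs)
    for spec in config.smr_bands:
        carrier = spec.amplitude * _unit_band_carrier(n_total, spec, fs, rng)
        gain = np.ones(n_total)
        curve = _gain_curve(config.task_kind, spec, t_rel)
        for c in cue_samples:
            lo = c - t0_offset
            hi = lo + curve.size
            src_lo, src_hi = max(lo, 0), min(hi, n_total)
            gain[src_lo:src_hi] = curve[src_lo - lo:curve.size - (hi - src_hi)]
        source += carrier * gain

    profile = config.resolve_profile()
    labels = list(config.channel_labels)
    cz = labels.index(CENTER_LABEL)
    neighbor_idx = [i for i in range(len(labels)) if i != cz]
    laplacian_gain = profile[cz] - profile[neighbor_idx].mean()
    if abs(laplacian_gain) < 1e-12:
        raise InvalidParameterError(
            "spatial profile has zero gain at virtual Cz")
    samples += np.outer(profile / laplacian_gain, source)

    return Recording(samples=samples, channel_labels=tuple(labels),
                     sampling_rate=fs, events=events)
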