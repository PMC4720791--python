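"""MRCP and SMR morphology statistics.

Two complementary views of the cue-locked response on virtual Cz:

* the MRCP significance profile — for every 0.1-s segment outside the
  -3..-2 s reference interval, a paired t-test across trials between the
  segment mean amplitude and the reference mean, Holm-Bonferroni corrected;
* the SMR time-frequency map — trial-averaged Welch power on a 1 Hz x 0.5 s
  grid, the relative power (A - R) / R against the reference interval
  (positive = ERS, negative = ERD), and a trial-resampling bootstrap mask of
  the time-frequency points whose power differs from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateReferenceError,
    InsufficientDataError,
    InvalidParameterError,
)
from .preprocess import EpochSet

__all__ = [
    "SignificanceProfile",
    "TimeFrequencyMap",
    "mrcp_significance_profile",
    "welch_tf_map",
    "erd_ers_percent",
    "bootstrap_mask",
    "holm_bonferroni",
]


@dataclass
class SignificanceProfile:
    """Paired-t MRCP profile on the 0.1-s segment grid."""

    segment_centers: np.ndarray  # s relative to the cue
    p_values: np.ndarray
    rejected: np.ndarray  # Holm-adjusted decisions at `alpha`
    alpha: float
    mean_difference: np.ndarray  # segment mean - reference mean, µV


@dataclass
class TimeFrequencyMap:
    """Trial-averaged power grid plus per-trial PSDs for resampling."""

    freqs: np.ndarray  # Hz, 1-Hz grid
    times: np.ndarray  # s relative to the cue, 0.5-s grid (window centers)
    trial_power: np.ndarray  # [trials x freqs x times], µV²/Hz
    power: np.ndarray  # A_{f,t}: mean over trials
    reference: np.ndarray  # R_f: mean power over the reference interval
    reference_interval: tuple[float, float]
    smr: np.ndarray | None = None  # relative power (A - R) / R
    mask: np.ndarray | None = None  # bootstrap significance


def holm_bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm procedure; returns a boolean rejection array."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def mrcp_significance_profile(epochs: EpochSet, alpha: float = 0.05,
                              segment_length: float = 0.1
                              ) -> SignificanceProfile:
    """Segment-wise paired t-test of MRCP amplitude against the baseline.

    Each 0.1-s segment outside the reference interval is summarised per trial
    by its mean amplitude and compared (paired across trials) with the
    per-trial reference-interval mean; Holm-Bonferroni is applied jointly
    over all segments.
    """
    if epochs.n_trials < 2:
        raise InsufficientDataError("need at least 2 trials for a paired t-test")
    fs = epochs.sampling_rate
    n_seg = int(round(segment_length * fs))
    if n_seg < 1:
        raise InvalidParameterError("segment shorter than one sample")
    n_full = (epochs.times.size // n_seg) * n_seg
    seg_means = epochs.data[:, :n_full].reshape(epochs.n_trials, -1, n_seg).mean(axis=2)
    centers = epochs.times[:n_full].reshape(-1, n_seg).mean(axis=1)

    ref = epochs.data[:, epochs.reference_mask()].mean(axis=1)
    lo, hi = epochs.reference_interval
    keep = (centers < lo) | (centers >= hi)
    seg_means = seg_means[:, keep]
    centers = centers[keep]

    diff = seg_means - ref[:, None]
    n = epochs.n_trials
    sd = diff.std(axis=0, ddof=1)
    mean = diff.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    # Degenerate segments: identically-zero difference is a perfect null.
    p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
    return SignificanceProfile(segment_centers=centers, p_values=p,
                               rejected=holm_bonferroni(p, alpha), alpha=alpha,
                               mean_difference=mean)


def welch_tf_map(epochs: EpochSet, fmax: float = 40.0,
                 fmin: float = 1.0) -> TimeFrequencyMap:
    """Welch power on a 1 Hz x 0.5 s grid (1-s Hamming windows, 0.5-s overlap).

    Per trial, the epoch is scanned with 1-s Hamming windows advancing by
    0.5 s; each window contributes the periodogram at 1-Hz resolution at the
    window-center time.  ``power`` averages over trials; ``reference`` is the
    time-average of ``power`` over the reference interval.
    """
    fs = epochs.sampling_rate
    nperseg = int(round(fs))
    if epochs.times.size < nperseg:
        raise InvalidParameterError("epochs shorter than one 1-s PSD window")
    if epochs.n_trials < 1:
        raise InsufficientDataError("no trials")
    freqs, t_rel, spec = sps.spectrogram(
        epochs.data, fs=fs, window=sps.get_window("hamming", nperseg),
        nperseg=nperseg, noverlap=nperseg // 2, nfft=nperseg,
        detrend=False, scaling="density", mode="psd", axis=1)
    # spec: [trials x freqs x times]; times are window centers from epoch start
    times = epochs.times[0] + t_rel
    sel = (freqs >= fmin) & (freqs <= fmax)
    freqs, spec = freqs[sel], spec[:, sel, :]
    power = spec.mean(axis=0)
    lo, hi = epochs.reference_interval
    ref_cols = (times >= lo) & (times <= hi)
    if not ref_cols.any():
        raise InvalidParameterError("no PSD window centers inside the reference interval")
    reference = power[:, ref_cols].mean(axis=1)
    return TimeFrequencyMap(freqs=freqs, times=times, trial_power=spec,
                            power=power, reference=reference,
                            reference_interval=epochs.reference_interval)


def erd_ers_percent(tf_map: TimeFrequencyMap) -> TimeFrequencyMap:
    """Relative SMR power (A - R) / R; x100 gives percent.

    Positive values are ERS (power above baseline), negative values ERD.
    """
    bad = ~(tf_map.reference > 0)
    if bad.any():
        raise DegenerateReferenceError(
            f"non-positive reference power at {tf_map.freqs[bad]} Hz")
    smr = (tf_map.power - tf_map.reference[:, None]) / tf_map.reference[:, None]
    return replace(tf_map, smr=smr)


def bootstrap_mask(tf_map: TimeFrequencyMap, n_boot: int = 1000,
                   alpha: float = 0.05,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Trial-resampling bootstrap significance of each time-frequency point.

    Trials are resampled with replacement; for each resample the difference
    between mean power at (f, t) and the mean reference power at f is
    recorded.  A point is flagged when the two-sided percentile interval of
    that difference excludes zero at level ``alpha``.  Per-point (no
    multiplicity correction), matching how such maps are usually displayed;
    feed the implied p-values to :func:`holm_bonferroni` for a corrected
    variant.
    """
    if n_boot < 100:
        raise InvalidParameterError("n_boot must be >= 100")
    n_trials = tf_map.trial_power.shape[0]
    if n_trials < 2:
        raise InsufficientDataError("need at least 2 trials to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lo_t, hi_t = tf_map.reference_interval
    ref_cols = (tf_map.times >= lo_t) & (tf_map.times <= hi_t)
    flat = tf_map.trial_power.reshape(n_trials, -1)  # [trials x F*T]

    idx = rng.integers(0, n_trials, size=(n_boot, n_trials))
    counts = np.zeros((n_boot, n_trials))
    np.add.at(counts, (np.repeat(np.arange(n_boot), n_trials), idx.ravel()), 1.0)
    weights = counts / n_trials
    boot_mean = (weights @ flat).reshape(n_boot, *tf_map.power.shape)
    boot_ref = boot_mean[:, :, ref_cols].mean(axis=2)
    diff = boot_mean - boot_ref[:, :, None]
    lo = np.percentile(diff, 100 * alpha / 2, axis=0)
    hi = np.percentile(diff, 100 * (1 - alpha / 2), axis=0)
    return (lo > 0) | (hi < 0)
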