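"""The two detection branches and the pseudo-online brain switch.

Time-series branch: decimated samples of the band-filtered virtual Cz,
projected to a low-dimensional manifold by Locality Preserving Projection
(LPP), classified by linear discriminant analysis (LDA).  Subband branch:
Welch band-power vectors (1-Hz resolution) fed straight to LDA.

The brain switch scans the per-window signal/noise labels causally and emits
a detection when WN consecutive windows are labelled signal; a detection is
a true positive when its latency relative to the nearest cue lies in
(-1, 1] s and that cue has not already been detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps
from scipy.spatial import cKDTree

from .exceptions import DegenerateDataError, InvalidParameterError
from .preprocess import BandDefinition, WindowSet

__all__ = [
    "FeatureMatrix",
    "LPPModel",
    "LDAModel",
    "DetectorConfig",
    "DetectionEvent",
    "make_timeseries_features",
    "make_subband_features",
    "fit_lpp",
    "project_lpp",
    "fit_lda",
    "lda_scores",
    "score_windows",
    "run_online_detector",
    "classify_detections",
]


@dataclass
class FeatureMatrix:
    vectors: np.ndarray  # [n_windows x d]
    labels: np.ndarray  # str array from preprocessing (signal/noise)
    end_times: np.ndarray  # s, window trailing edges

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def is_signal(self) -> np.ndarray:
        return self.labels == "signal"


@dataclass
class LPPModel:
    """Linear LPP map, optionally through a variance-preserving pre-projection."""

    projection: np.ndarray  # [d_eff x m]
    pre_projection: np.ndarray | None  # [d x d_eff] or None (identity)
    combined: np.ndarray  # [d x m]
    n_neighbors: int
    kernel_width: float
    eigenvalues: np.ndarray

    @property
    def output_dim(self) -> int:
        return self.projection.shape[1]


@dataclass
class LDAModel:
    """Two-class Gaussian equal-covariance discriminant (signal vs noise)."""

    weights: np.ndarray
    bias: float
    mean_signal: np.ndarray
    mean_noise: np.ndarray
    pooled_covariance: np.ndarray
    priors: tuple[float, float]  # (noise, signal)


@dataclass(frozen=True)
class DetectorConfig:
    wn: int  # consecutive signal windows required
    refractory: float = 2.0  # s of dead time after each detection
    window_length: float = 2.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.wn < 1:
            raise InvalidParameterError("WN must be >= 1")
        if self.refractory < 0:
            raise InvalidParameterError("refractory must be >= 0")


@dataclass(frozen=True)
class DetectionEvent:
    time: float  # trailing edge of the WN-th window, s
    latency: float | None = None  # DL: time - nearest cue, s
    label: str | None = None  # "TP" or "FP"


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def make_timeseries_features(windows: WindowSet,
                             decimation_factor: int) -> FeatureMatrix:
    """Anti-aliased decimation of each window's raw samples (no scaling)."""
    if decimation_factor < 1 or int(decimation_factor) != decimation_factor:
        raise InvalidParameterError("decimation_factor must be a positive integer")
    q = int(decimation_factor)
    if q == 1:
        vectors = windows.windows.copy()
    else:
        vectors = sps.resample_poly(windows.windows, up=1, down=q, axis=1)
    if vectors.shape[1] < 4:
        raise InvalidParameterError(
            f"decimation by {q} leaves {vectors.shape[1]} samples (< 4)")
    return FeatureMatrix(vectors=vectors, labels=windows.labels.copy(),
                         end_times=windows.end_times.copy())


def make_subband_features(windows: WindowSet,
                          band: BandDefinition) -> FeatureMatrix:
    """Welch band-power vector per window at 1-Hz resolution.

    The feature is the PSD evaluated at the integer frequencies inside
    ``[band.low, band.high]`` (e.g. 15 values for beta, 16-30 Hz).
    """
    fs = windows.sampling_rate
    if band.high >= fs / 2:
        raise InvalidParameterError(
            f"band {band.name!r} exceeds Nyquist ({fs / 2} Hz)")
    nperseg = min(int(round(fs)), windows.windows.shape[1])
    freqs, psd = sps.welch(windows.windows, fs=fs,
                           window=sps.get_window("hamming", nperseg),
                           nperseg=nperseg, noverlap=nperseg // 2,
                           nfft=int(round(fs)), axis=1)
    sel = (freqs >= band.low) & (freqs <= band.high)
    if not sel.any():
        raise InvalidParameterError(
            f"no 1-Hz bins inside band {band.name!r}")
    return FeatureMatrix(vectors=psd[:, sel], labels=windows.labels.copy(),
                         end_times=windows.end_times.copy())


# ---------------------------------------------------------------------------
# Locality Preserving Projection
# ---------------------------------------------------------------------------

def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.vectors
    return np.asarray(features, dtype=float)


def _mean_squared_pairwise_distance(y: np.ndarray) -> float:
    # E_{i!=j} ||y_i - y_j||^2 = 2 n/(n-1) * mean squared deviation
    n = y.shape[0]
    dev = y - y.mean(axis=0)
    return 2.0 * (n / (n - 1)) * float(np.mean(np.sum(dev ** 2, axis=1)))


def fit_lpp(features, m: int = 10, k: int = 5,
            kernel_width: float | None = None) -> LPPModel:
    """Fit a Locality Preserving Projection.

    Builds a symmetrised k-nearest-neighbour graph with heat-kernel weights
    ``exp(-||x_i - x_j||^2 / width)`` (width defaulting to the mean squared
    pairwise distance), forms the graph Laplacian ``L = D - W`` and solves
    the generalized eigenproblem ``X' L X a = lambda X' D X a``; the
    projection keeps the eigenvectors of the ``m`` smallest eigenvalues.
    When the data matrix is rank-deficient (e.g. d > n), a PCA
    pre-projection retaining 99% of the variance is applied first.
    """
    x = _as_matrix(features)
    n, d = x.shape
    if n <= k:
        raise InvalidParameterError(f"need n > k, got n={n}, k={k}")
    if m > d or m < 1:
        raise InvalidParameterError(f"need 1 <= m <= d, got m={m}, d={d}")

    centered = x - x.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    tol = svals[0] * max(n, d) * np.finfo(float).eps if svals.size else 0.0
    rank = int(np.sum(svals > tol))
    if rank == 0:
        raise DegenerateDataError("features have zero variance")

    pre: np.ndarray | None = None
    y = x
    if rank < d:
        # variance-preserving pre-projection (99% of total variance)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        var = s ** 2
        r = int(np.searchsorted(np.cumsum(var) / var.sum(), 0.99) + 1)
        r = min(max(r, m), rank)
        if m > r:
            raise DegenerateDataError(
                f"effective rank {r} < requested output dimension {m}")
        pre = vt[:r].T
        y = x @ pre

    width = kernel_width if kernel_width is not None else _mean_squared_pairwise_distance(y)
    if not np.isfinite(width) or width <= 0:
        raise DegenerateDataError("degenerate kernel width")

    tree = cKDTree(y)
    dist, idx = tree.query(y, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    w_vals = np.exp(-dist[:, 1:].ravel() ** 2 / width)
    w = np.zeros((n, n))
    w[rows, cols] = w_vals
    w = np.maximum(w, w.T)  # symmetrise: edge if either point claims it

    deg = w.sum(axis=1)
    # X' L X = X' D X - X' W X, all via the (possibly pre-projected) data
    ydw = y * deg[:, None]
    b = y.T @ ydw
    a = b - y.T @ (w @ y)
    a = 0.5 * (a + a.T)
    b = 0.5 * (b + b.T)
    d_eff = y.shape[1]
    reg = 1e-8 * np.trace(b) / d_eff
    if not np.isfinite(reg) or reg <= 0:
        raise DegenerateDataError("degenerate graph degree matrix")
    try:
        evals, evecs = sla.eigh(a, b + reg * np.eye(d_eff))
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("generalized eigenproblem is singular") from exc
    projection = evecs[:, :m]
    combined = projection if pre is None else pre @ projection
    return LPPModel(projection=projection, pre_projection=pre,
                    combined=combined, n_neighbors=k, kernel_width=width,
                    eigenvalues=evals[:m])


def project_lpp(model: LPPModel, x: np.ndarray) -> np.ndarray:
    """Linear map into the LPP space; accepts a vector or a [n x d] matrix."""
    x = np.asarray(x, dtype=float)
    d = model.combined.shape[0]
    if x.shape[-1] != d:
        raise InvalidParameterError(
            f"expected feature dimension {d}, got {x.shape[-1]}")
    return x @ model.combined


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

def fit_lda(features, labels, shrinkage: float = 0.0,
            priors: str = "empirical") -> LDAModel:
    """Fisher / Gaussian equal-covariance LDA for signal-vs-noise.

    ``weights = S_pooled^-1 (mu_signal - mu_noise)``; the bias places the
    boundary at equal posterior under the class priors (empirical by
    default, ``priors="equal"`` for a balanced boundary).  ``shrinkage``
    blends the pooled covariance toward a scaled identity.
    """
    x = _as_matrix(features)
    y = np.asarray(labels)
    is_signal = (y == "signal") if y.dtype.kind in "US" else y.astype(bool)
    n1, n0 = int(is_signal.sum()), int((~is_signal).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidParameterError("both classes must be present")
    if not 0.0 <= shrinkage <= 1.0:
        raise InvalidParameterError("shrinkage must lie in [0, 1]")
    xs, xn = x[is_signal], x[~is_signal]
    mu1, mu0 = xs.mean(axis=0), xn.mean(axis=0)
    dev = np.vstack([xs - mu1, xn - mu0])
    denom = max(n1 + n0 - 2, 1)
    cov = dev.T @ dev / denom
    if shrinkage > 0:
        target = np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        cov = (1 - shrinkage) * cov + shrinkage * target
    if not np.all(np.isfinite(cov)):
        raise DegenerateDataError("non-finite covariance")
    try:
        weights = sla.solve(cov, mu1 - mu0, assume_a="pos")
    except (np.linalg.LinAlgError, sla.LinAlgError):
        raise DegenerateDataError("pooled covariance is singular; "
                                  "use shrinkage > 0") from None
    if priors == "empirical":
        p1, p0 = n1 / (n1 + n0), n0 / (n1 + n0)
    elif priors == "equal":
        p1 = p0 = 0.5
    else:
        raise InvalidParameterError(f"unknown priors mode {priors!r}")
    bias = -0.5 * float(weights @ (mu1 + mu0)) + float(np.log(p1 / p0))
    return LDAModel(weights=weights, bias=bias, mean_signal=mu1,
                    mean_noise=mu0, pooled_covariance=cov, priors=(p0, p1))


def lda_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Signed discriminant scores; > 0 classifies as signal."""
    return np.asarray(x, dtype=float) @ model.weights + model.bias


def score_windows(lpp: LPPModel | None, lda: LDAModel,
                  features) -> np.ndarray:
    """Per-window boolean signal decisions, causally in stream order."""
    x = _as_matrix(features)
    if lpp is not None:
        x = project_lpp(lpp, x)
    scores = lda_scores(lda, x)
    if not np.all(np.isfinite(scores)):
        raise DegenerateDataError("non-finite classifier scores")
    return scores > 0


# ---------------------------------------------------------------------------
# Pseudo-online brain switch
# ---------------------------------------------------------------------------

def run_online_detector(labels, times, config: DetectorConfig) -> list[DetectionEvent]:
    """Scan a causal label stream and emit WN-consecutive-signal detections.

    A detection is stamped at the trailing edge of the WN-th consecutive
    signal window; the consecutive counter then resets and every window
    whose trailing edge falls inside the refractory period is ignored
    (it neither extends nor resets a run).
    """
    labels = np.asarray(labels)
    is_signal = (labels == "signal") if labels.dtype.kind in "US" else labels.astype(bool)
    times = np.asarray(times, dtype=float)
    detections: list[DetectionEvent] = []
    run = 0
    blocked_until = -np.inf
    for flag, t in zip(is_signal, times):
        if t < blocked_until:
            continue
        if flag:
            run += 1
            if run >= config.wn:
                detections.append(DetectionEvent(time=float(t)))
                run = 0
                blocked_until = t + config.refractory
        else:
            run = 0
    return detections


def classify_detections(events, cues, window: tuple[float, float] = (-1.0, 1.0)
                        ) -> list[DetectionEvent]:
    """Fill latency (DL) and TP/FP labels.

    DL = detection time minus the nearest cue time.  A detection is a TP iff
    DL lies in the half-open interval ``(window[0], window[1]]`` and that cue
    has no earlier TP; every other detection is an FP.
    """
    cues = np.sort(np.asarray(cues, dtype=float))
    lo, hi = window
    claimed: set[int] = set()
    out: list[DetectionEvent] = []
    for ev in sorted(events, key=lambda e: e.time):
        t = ev.time
        if cues.size == 0:
            out.append(DetectionEvent(time=t, latency=None, label="FP"))
            continue
        pos = int(np.searchsorted(cues, t))
        candidates = [i for i in (pos - 1, pos) if 0 <= i < cues.size]
        nearest = min(candidates, key=lambda i: (abs(t - cues[i]), cues[i]))
        dl = t - cues[nearest]
        is_tp = (lo < dl <= hi) and nearest not in claimed
        if is_tp:
            claimed.add(nearest)
        out.append(DetectionEvent(time=t, latency=float(dl),
                                  label="TP" if is_tp else "FP"))
    return out
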