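"""MEA spike/burst detection and spatial activity-propagation analysis.

Spikes are threshold crossings on a band-passed copy of each channel; bursts
are spike runs whose Poisson surprise ``S = −log10 P(N ≥ n)`` (for a
homogeneous Poisson process at the channel's mean rate) exceeds a minimum,
with at least 10 spikes in at least 0.1 s. Activity spread is quantified by
the size of the largest spatially adjacent (8-connected) group of channels
whose preprocessed field potential exceeds ±2 per-channel standard
deviations, evaluated on a 21-point lag grid around each dentate-gyrus
trigger spike (5 ms spacing, 100 ms span) and normalized to the first four
post-trigger bins.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, signal, special

from .io_formats import Recording

__all__ = [
    "SpikeTrain",
    "MeaBurst",
    "ClusterTimecourse",
    "detect_spikes",
    "poisson_surprise",
    "detect_bursts",
    "preprocess_for_clusters",
    "channel_sds",
    "activity_clusters_at",
    "cluster_timecourse",
]

logger = logging.getLogger(__name__)

N_LAG_BINS = 21
LAG_STEP_MS = 5.0
NORM_BINS = 4                  # first 4 bins (20 ms) define the normalization
EARLY_WINDOW_MS = 20.0         # "first 20 ms" summary
LATE_WINDOW_MS = (30.0, 70.0)  # "30–70 ms" summary


@dataclasses.dataclass
class SpikeTrain:
    channel_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")


@dataclasses.dataclass
class MeaBurst:
    channel_id: str
    start_s: float
    end_s: float
    n_spikes: int
    surprise: float


@dataclasses.dataclass
class ClusterTimecourse:
    """Max-cluster sizes around one trigger spike.

    ``raw`` holds the largest spatially adjacent supra-threshold channel
    group per lag bin (max over positive/negative polarity); ``normalized``
    divides by the mean of the first four bins (NaN when that mean is 0).
    """

    trigger_t_s: float
    lags_ms: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    polarity_used: list[str]


# ---------------------------------------------------------------------------
# spikes and bursts


def _robust_sd(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def detect_spikes(
    rec: Recording,
    band_hz: tuple[float, float] = (300.0, 3000.0),
    threshold_sd: float = 4.0,
    refractory_ms: float = 1.0,
) -> list[SpikeTrain]:
    """Per-channel spike detection on a band-passed copy.

    Threshold is ``threshold_sd`` robust (MAD-based) standard deviations of
    the filtered signal; one spike per refractory window, timestamped at the
    absolute-peak sample.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if rec.rate_hz < 10_000:
        warnings.warn(
            f"sampling rate {rec.rate_hz} Hz < 10 kHz; spike band edge clipped",
            stacklevel=2,
        )
    hi = min(band_hz[1], 0.45 * rec.rate_hz)
    sos = signal.butter(4, [band_hz[0], hi], btype="band", fs=rec.rate_hz, output="sos")
    dist = max(int(round(refractory_ms / 1000.0 * rec.rate_hz)), 1)
    trains = []
    for ci, cid in enumerate(rec.channel_ids):
        bp = signal.sosfiltfilt(sos, rec.samples[ci])
        thr = threshold_sd * _robust_sd(bp)
        if thr == 0:
            trains.append(SpikeTrain(cid, np.empty(0)))
            continue
        peaks, _ = signal.find_peaks(np.abs(bp), height=thr, distance=dist)
        trains.append(SpikeTrain(cid, peaks / rec.rate_hz))
    return trains


def poisson_surprise(n: int, t: float, lam: float) -> float:
    """Poisson surprise ``S = −log10 P(N ≥ n)`` for ``N ~ Poisson(λt)``.

    Uses the incomplete-gamma identity ``P(N ≥ n) = P(n, λt)`` with a
    log-space summation fallback when the tail underflows. ``λ = 0`` with
    ``n > 0`` returns +inf by convention.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if lam < 0 or n < 0:
        raise ValueError("lam and n must be non-negative")
    if n == 0:
        return 0.0
    if lam == 0:
        warnings.warn("surprise with lam=0 and n>0 is +inf by convention", stacklevel=2)
        return float("inf")
    mu = lam * t
    tail = special.gammainc(n, mu)  # == P(N >= n) for Poisson(mu)
    if tail > 0:
        return float(-np.log10(tail))
    # log-space tail sum, k = n .. n + 2000
    k = np.arange(n, n + 2001, dtype=float)
    log_pmf = k * np.log(mu) - mu - special.gammaln(k + 1)
    return float(-special.logsumexp(log_pmf) / np.log(10.0))


def detect_bursts(
    train: SpikeTrain,
    duration_s: float,
    s_min: float = 10.0,
    min_spikes: int = 10,
    min_dur_s: float = 0.1,
    isi_factor: float = 0.5,
    lookahead: int = 10,
) -> list[MeaBurst]:
    """Poisson-surprise burst detection (Legéndy–Salcman style).

    Candidate cores are maximal runs of inter-spike intervals shorter than
    ``isi_factor``× the mean ISI; each core is grown forward and trimmed at
    the start to maximize the surprise, then accepted iff S ≥ ``s_min``,
    spike count ≥ ``min_spikes`` and span ≥ ``min_dur_s``. Accepted bursts
    never overlap.
    """
    times = train.times
    if times.size < 2:
        return []
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    lam = times.size / duration_s
    mean_isi = 1.0 / lam
    isi = np.diff(times)

    def surprise_of(a: int, b: int) -> float:
        span = times[b] - times[a]
        if span <= 0:
            span = 1.0 / 1e6
        return poisson_surprise(b - a + 1, span, lam)

    bursts: list[MeaBurst] = []
    i = 0
    n = times.size
    while i < n - 1:
        if isi[i] >= isi_factor * mean_isi:
            i += 1
            continue
        # core: run of short ISIs
        a, b = i, i + 1
        while b < n - 1 and isi[b] < isi_factor * mean_isi:
            b += 1
        # grow the end with lookahead
        best_s, best_b = surprise_of(a, b), b
        j = b
        while j < n - 1 and j < best_b + lookahead:
            j += 1
            s = surprise_of(a, j)
            if s > best_s:
                best_s, best_b = s, j
        b = best_b
        # trim the start
        best_a = a
        for j in range(a + 1, b - 1):
            s = surprise_of(j, b)
            if s > best_s:
                best_s, best_a = s, j
        a = best_a
        span = times[b] - times[a]
        n_sp = b - a + 1
        if best_s >= s_min and n_sp >= min_spikes and span >= min_dur_s:
            bursts.append(MeaBurst(train.channel_id, float(times[a]), float(times[b]), n_sp, best_s))
        i = b + 1
    return bursts


# ---------------------------------------------------------------------------
# activity clusters


def preprocess_for_clusters(
    rec: Recording,
    target_hz: float = 5000.0,
    demean_win_s: float = 1.0,
    overlap: float = 0.5,
) -> Recording:
    """Anti-aliased resampling to 5 kHz plus windowed demeaning.

    Channel means are computed in 1 s windows with 50% overlap and linearly
    interpolated between window centers before subtraction, so slow drift is
    removed while fast transients survive. Recordings shorter than one
    window fall back to whole-trace demeaning with a warning.
    """
    if rec.rate_hz < target_hz:
        raise ValueError("recording rate below the 5 kHz target")
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    data = signal.resample_poly(
        rec.samples, frac.numerator, frac.denominator, axis=1, padtype="line"
    )
    n = data.shape[1]

    win = int(round(demean_win_s * target_hz))
    step = max(int(round(win * (1.0 - overlap))), 1)
    if n < win:
        warnings.warn("recording shorter than the demeaning window; using one window",
                      stacklevel=2)
        data = data - data.mean(axis=1, keepdims=True)
    else:
        starts = np.arange(0, n - win + 1, step)
        centers = starts + win / 2.0
        idx = np.arange(n, dtype=float)
        for ci in range(data.shape[0]):
            means = np.array([data[ci, s : s + win].mean() for s in starts])
            data[ci] -= np.interp(idx, centers, means)
    return Recording(
        samples=data,
        rate_hz=target_hz,
        channel_ids=list(rec.channel_ids),
        geometry=rec.geometry,
        units=rec.units,
    )


def channel_sds(rec: Recording, mode: str = "per_channel") -> np.ndarray:
    """Per-channel (default) or global standard deviation of the whole signal."""
    if mode == "per_channel":
        return rec.samples.std(axis=1)
    if mode == "global":
        return np.full(rec.n_channels, rec.samples.std())
    raise ValueError(f"unknown SD mode {mode!r}")


def _grid_masks(
    rec: Recording, idx: int, sds: np.ndarray, thresh_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    if rec.geometry is None:
        raise ValueError("recording has no grid geometry")
    rows = max(r for r, _ in rec.geometry) + 1
    cols = max(c for _, c in rec.geometry) + 1
    pos = np.zeros((rows, cols), dtype=bool)
    neg = np.zeros((rows, cols), dtype=bool)
    v = rec.samples[:, idx]
    for ci, (r, c) in enumerate(rec.geometry):
        pos[r, c] = v[ci] > thresh_sd * sds[ci]
        neg[r, c] = v[ci] < -thresh_sd * sds[ci]
    return pos, neg


def max_component_size(mask: np.ndarray, connectivity: int = 8) -> int:
    """Size of the largest connected component of a boolean grid."""
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def activity_clusters_at(
    rec5k: Recording,
    t_s: float,
    sds: np.ndarray,
    thresh_sd: float = 2.0,
    connectivity: int = 8,
) -> tuple[int, int]:
    """Largest positive and negative supra-threshold cluster sizes at time t.

    Channels above ``+thresh_sd`` (below ``−thresh_sd``) per-channel SDs form
    binary grid masks whose connected components (8-connectivity by default)
    are measured; only the largest component per polarity is returned.
    """
    idx = int(round(t_s * rec5k.rate_hz))
    if not 0 <= idx < rec5k.n_samples:
        raise ValueError(f"time {t_s} s outside the recording")
    pos, neg = _grid_masks(rec5k, idx, sds, thresh_sd)
    return max_component_size(pos, connectivity), max_component_size(neg, connectivity)


def cluster_timecourse(
    rec5k: Recording,
    dg_spike_times: np.ndarray,
    thresh_sd: float = 2.0,
    lag_start_ms: float = 0.0,
    lag_step_ms: float = LAG_STEP_MS,
    n_bins: int = N_LAG_BINS,
    sd_mode: str = "per_channel",
    connectivity: int = 8,
) -> tuple[list[ClusterTimecourse], dict]:
    """Max-cluster timecourse on the 21-point lag grid around DG triggers.

    By default the grid runs 0–100 ms after each trigger (``lag_start_ms=-50``
    restores a window centered on the spike). Per-bin value is the larger of
    the positive and negative maximal cluster sizes. Returns the per-trigger
    curves plus aggregate statistics: the mean raw and normalized curves, the
    per-trigger maximum over the first 20 ms, and the mean normalized value
    over the 30–70 ms lags.
    """
    sds = channel_sds(rec5k, sd_mode)
    lags_ms = lag_start_ms + lag_step_ms * np.arange(n_bins)
    curves: list[ClusterTimecourse] = []
    for trig in np.asarray(dg_spike_times, dtype=float):
        t_bins = trig + lags_ms / 1000.0
        if t_bins[0] < 0 or t_bins[-1] >= rec5k.duration_s:
            logger.info("trigger at %.3f s too close to the recording edge; skipped", trig)
            continue
        raw = np.empty(n_bins)
        pols: list[str] = []
        for j, tb in enumerate(t_bins):
            p, q = activity_clusters_at(rec5k, tb, sds, thresh_sd, connectivity)
            raw[j] = max(p, q)
            pols.append("positive" if p >= q else "negative")
        base = raw[:NORM_BINS].mean()
        normalized = raw / base if base > 0 else np.full(n_bins, np.nan)
        curves.append(ClusterTimecourse(float(trig), lags_ms, raw, normalized, pols))

    agg: dict = {"n_triggers": len(curves), "lags_ms": lags_ms}
    if curves:
        raw_stack = np.vstack([c.raw for c in curves])
        norm_stack = np.vstack([c.normalized for c in curves])
        early = lags_ms <= EARLY_WINDOW_MS
        late = (lags_ms >= LATE_WINDOW_MS[0]) & (lags_ms <= LATE_WINDOW_MS[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            agg["mean_raw_curve"] = raw_stack.mean(axis=0)
            agg["mean_normalized_curve"] = np.nanmean(norm_stack, axis=0)
            agg["max_first_20ms"] = raw_stack[:, early].max(axis=1)
            agg["mean_norm_30_70ms"] = np.nanmean(norm_stack[:, late], axis=1)
        agg["normalization_defined"] = ~np.isnan(norm_stack[:, 0])
    else:
        agg["mean_raw_curve"] = np.full(n_bins, np.nan)
        agg["mean_normalized_curve"] = np.full(n_bins, np.nan)
        agg["max_first_20ms"] = np.empty(0)
        agg["mean_norm_30_70ms"] = np.empty(0)
        agg["normalization_defined"] = np.empty(0, dtype=bool)
    return curves, agg
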