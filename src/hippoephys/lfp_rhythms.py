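"""Awake-LFP preprocessing, band power, theta–gamma coupling and ripples.

The pipeline mirrors a standard awake-recording analysis: 350 Hz zero-phase
low-pass and demeaning; tiling of behavioral intervals into non-overlapping
3 s idle/running segments; complex Morlet wavelet power in theta (3–12 Hz)
and gamma (20–90 Hz); a theta-phase (7 Hz) → gamma-power profile over eight
equal phase bins with a nested quadratic-fit F test between groups; and a
Kay-style ripple detector (150–200 Hz band, summed squared cross-channel
envelope, z-scored within idle epochs, candidates above a z threshold
extended to the zero crossing).

Morlet convolution uses the canonical MNE wavelets directly; segments are
reflection-padded so low frequencies remain computable on 3 s epochs, and an
explicit validity mask excludes samples without full wavelet support (capped
so the central part of a segment always remains usable).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from mne.time_frequency import morlet
from scipy import ndimage, signal, stats

from .io_formats import Recording, validate_epochs

__all__ = [
    "BANDS",
    "Segment",
    "PhaseGammaProfile",
    "QuadFitComparison",
    "preprocess_lfp",
    "epoch_signal",
    "morlet_band_power",
    "phase_gamma_profile",
    "compare_quadratic_fits",
    "detect_ripples_kay",
    "ripple_stats",
]

BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 12.0),
    "low_theta": (3.0, 6.0),
    "high_theta": (7.0, 13.0),
    "gamma": (20.0, 90.0),
}
THETA_PHASE_HZ = 7.0
N_PHASE_BINS = 8


@dataclasses.dataclass
class Segment:
    """A fixed-length behavioral-state segment cut from a recording."""

    data: np.ndarray          # (n_channels, n_samples)
    rate_hz: float
    state: str
    t0_s: float


@dataclasses.dataclass
class PhaseGammaProfile:
    """Mean gamma power in 8 equal theta-phase bins over [−π, π)."""

    bin_centers_rad: np.ndarray
    mean_gamma_power: np.ndarray
    n_samples_per_bin: np.ndarray
    n_epochs: int
    empty_bins: list[int]


@dataclasses.dataclass
class QuadFitComparison:
    """Extra-sum-of-squares F test: one shared quadratic vs per-group fits."""

    ss_shared: float
    ss_separate: float
    df_shared: int
    df_separate: int
    f_stat: float
    p_value: float
    coef_shared: np.ndarray
    coef_a: np.ndarray
    coef_b: np.ndarray


# ---------------------------------------------------------------------------
# preprocessing and epoching


def preprocess_lfp(rec: Recording, lowpass_hz: float = 350.0) -> Recording:
    """Zero-phase 350 Hz low-pass and per-channel mean subtraction."""
    cutoff = min(lowpass_hz, 0.45 * rec.rate_hz)
    sos = signal.butter(4, cutoff, btype="low", fs=rec.rate_hz, output="sos")
    data = signal.sosfiltfilt(sos, rec.samples, axis=1)
    data = data - data.mean(axis=1, keepdims=True)
    return Recording(
        samples=data,
        rate_hz=rec.rate_hz,
        channel_ids=list(rec.channel_ids),
        geometry=rec.geometry,
        units=rec.units,
    )


def epoch_signal(
    rec: Recording, epochs: pd.DataFrame, len_s: float = 3.0
) -> list[Segment]:
    """Tile each behavioral interval with non-overlapping ``len_s`` segments.

    Remainders shorter than ``len_s`` are discarded; segments never straddle
    a state boundary.
    """
    epochs = validate_epochs(epochs)
    n_seg = int(round(len_s * rec.rate_hz))
    segments: list[Segment] = []
    for row in epochs.itertuples():
        start = float(row.start_s)
        end = min(float(row.end_s), rec.duration_s)
        k = 0
        while start + (k + 1) * len_s <= end + 1e-9:
            i0 = int(round((start + k * len_s) * rec.rate_hz))
            if i0 + n_seg > rec.n_samples:
                break
            segments.append(
                Segment(rec.samples[:, i0 : i0 + n_seg], rec.rate_hz,
                        str(row.state), start + k * len_s)
            )
            k += 1
    return segments


# ---------------------------------------------------------------------------
# Morlet power


def _morlet_transform(
    x: np.ndarray, rate_hz: float, freqs: np.ndarray, n_cycles: float = 7.0
) -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet coefficients W (n_freqs × n) and a validity mask.

    The signal is reflection-padded to accommodate wavelets longer than the
    segment; samples within half a wavelet of either edge are marked invalid
    per frequency, capped at 45% of the segment from each side so a central
    band always stays valid.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    wavelets = morlet(rate_hz, freqs, n_cycles=n_cycles)
    w_out = np.empty((len(freqs), n), dtype=complex)
    valid = np.zeros((len(freqs), n), dtype=bool)
    cap = int(0.45 * n)
    for i, w in enumerate(wavelets):
        half = len(w) // 2
        pad = min(half, n - 1)
        xp = np.pad(x, pad, mode="reflect")
        conv = signal.fftconvolve(xp, w, mode="same")
        w_out[i] = conv[pad : pad + n]
        margin = min(half, cap)
        valid[i, margin : n - margin] = True
    return w_out, valid


def morlet_band_power(
    segment: Segment | np.ndarray,
    band: tuple[float, float] | str,
    rate_hz: float | None = None,
    n_cycles: float = 7.0,
    freq_step_hz: float = 1.0,
) -> float:
    """Mean Morlet power over a frequency band (1 Hz grid) and a segment.

    ``|W(f, t)|²`` averaged over valid times per frequency, then across the
    band's frequency grid. Raises if the band's low edge cannot be resolved
    on the segment length.
    """
    if isinstance(segment, Segment):
        x, rate_hz = segment.data, segment.rate_hz
    else:
        x = np.asarray(segment, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required when passing a bare array")
    x = np.atleast_2d(x)
    if isinstance(band, str):
        band = BANDS[band]
    lo, hi = band
    seg_len_s = x.shape[1] / rate_hz
    if lo < 1.0 / seg_len_s:
        raise ValueError(f"band low edge {lo} Hz below 1/segment-length")
    freqs = np.arange(lo, hi + freq_step_hz / 2, freq_step_hz)
    powers = []
    for ch in x:
        w, valid = _morlet_transform(ch, rate_hz, freqs, n_cycles)
        p = np.abs(w) ** 2
        per_freq = np.array([p[i, valid[i]].mean() for i in range(len(freqs))])
        powers.append(per_freq.mean())
    return float(np.mean(powers))


def band_power_table(
    segments: list[Segment],
    bands: dict[str, tuple[float, float]] | None = None,
    n_cycles: float = 7.0,
) -> pd.DataFrame:
    """Per-epoch, per-band mean power table (epoch, state, band, power)."""
    bands = bands or BANDS
    rows = []
    for i, seg in enumerate(segments):
        for name, edges in bands.items():
            rows.append((i, seg.state, name, morlet_band_power(seg, edges, n_cycles=n_cycles)))
    return pd.DataFrame(rows, columns=["epoch", "state", "band", "power"])


# ---------------------------------------------------------------------------
# theta-phase → gamma-power profile


def phase_gamma_profile(
    segments: list[Segment],
    theta_hz: float = THETA_PHASE_HZ,
    gamma_band: tuple[float, float] = BANDS["gamma"],
    n_bins: int = N_PHASE_BINS,
    n_cycles: float = 7.0,
    gamma_step_hz: float = 1.0,
    channel: int = 0,
) -> PhaseGammaProfile:
    """Mean gamma power per theta-phase bin, pooled over segments.

    Per sample, θ is the angle of the 7 Hz complex Morlet coefficient and
    gamma power the mean ``|W|²`` over 20–90 Hz; samples are assigned to one
    of eight equal bins partitioning [−π, π). Empty bins are flagged but the
    profile is still returned.
    """
    if not segments:
        raise ValueError("need at least one segment")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    gfreqs = np.arange(gamma_band[0], gamma_band[1] + gamma_step_hz / 2, gamma_step_hz)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for seg in segments:
        x = seg.data[channel]
        w_t, v_t = _morlet_transform(x, seg.rate_hz, np.array([theta_hz]), n_cycles)
        w_g, v_g = _morlet_transform(x, seg.rate_hz, gfreqs, n_cycles)
        valid = v_t[0] & v_g.all(axis=0)
        phase = np.angle(w_t[0, valid])
        gpow = (np.abs(w_g[:, valid]) ** 2).mean(axis=0)
        which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
        np.add.at(sums, which, gpow)
        np.add.at(counts, which, 1)
    mean_power = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    return PhaseGammaProfile(
        bin_centers_rad=centers,
        mean_gamma_power=mean_power,
        n_samples_per_bin=counts,
        n_epochs=len(segments),
        empty_bins=[int(i) for i in np.flatnonzero(counts == 0)],
    )


def _as_xy(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, PhaseGammaProfile):
        ok = ~np.isnan(profile.mean_gamma_power)
        return profile.bin_centers_rad[ok], profile.mean_gamma_power[ok]
    x, y = profile
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def compare_quadratic_fits(profile_a, profile_b) -> QuadFitComparison:
    """Nested quadratic-regression F test between two phase–power datasets.

    Fits ``power = a·θ² + b·θ + c`` separately per group and once over the
    pooled data; ``F = [(SS_shared − SS_sep)/(df_shared − df_sep)] /
    (SS_sep/df_sep)`` with p from the F distribution. Inputs are
    :class:`PhaseGammaProfile` objects or ``(theta, power)`` pairs
    (replicates allowed).
    """
    xa, ya = _as_xy(profile_a)
    xb, yb = _as_xy(profile_b)
    for x in (xa, xb):
        if len(np.unique(x)) < 4:
            raise ValueError("need at least 4 distinct theta values per group")

    def rss(x, y):
        coef = np.polyfit(x, y, 2)
        return float(np.sum((y - np.polyval(coef, x)) ** 2)), coef

    ss_a, coef_a = rss(xa, ya)
    ss_b, coef_b = rss(xb, yb)
    x_all, y_all = np.concatenate([xa, xb]), np.concatenate([ya, yb])
    ss_shared, coef_shared = rss(x_all, y_all)
    n = len(x_all)
    df_shared = n - 3
    df_sep = n - 6
    if df_sep <= 0:
        raise ValueError("not enough points for separate quadratic fits")
    ss_sep = ss_a + ss_b
    num = max(ss_shared - ss_sep, 0.0) / (df_shared - df_sep)
    den = ss_sep / df_sep
    if den == 0:
        f_stat = 0.0 if num == 0 else float("inf")
        p = 1.0 if num == 0 else 0.0
    else:
        f_stat = num / den
        p = float(stats.f.sf(f_stat, df_shared - df_sep, df_sep))
    return QuadFitComparison(
        ss_shared=ss_shared,
        ss_separate=ss_sep,
        df_shared=df_shared,
        df_separate=df_sep,
        f_stat=float(f_stat),
        p_value=p,
        coef_shared=coef_shared,
        coef_a=coef_a,
        coef_b=coef_b,
    )


def _stack_epochs(
    epoch_xy: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([x for x, _ in epoch_xy])
    ys = np.concatenate([y for _, y in epoch_xy])
    return xs, ys


def compare_quadratic_fits_permutation(
    epochs_a: list[tuple[np.ndarray, np.ndarray]],
    epochs_b: list[tuple[np.ndarray, np.ndarray]],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[QuadFitComparison, float]:
    """Quadratic-fit comparison with a permutation-calibrated p value.

    The pooled extra-sum-of-squares F test assumes independent residuals,
    but the 8 bins of one epoch's phase–power profile share that epoch's
    gamma-power level and smooth wavelet-induced wobble, so the parametric p
    is anticonservative. Here whole epoch profiles (the exchangeable unit
    under the null) are permuted between groups and the observed F is ranked
    against the permutation distribution. Returns the parametric comparison
    plus the permutation p value.
    """
    obs = compare_quadratic_fits(_stack_epochs(epochs_a), _stack_epochs(epochs_b))
    pool = list(epochs_a) + list(epochs_b)
    n_a = len(epochs_a)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        order = rng.permutation(len(pool))
        pa = [pool[i] for i in order[:n_a]]
        pb = [pool[i] for i in order[n_a:]]
        f = compare_quadratic_fits(_stack_epochs(pa), _stack_epochs(pb)).f_stat
        if f >= obs.f_stat:
            n_ge += 1
    p_perm = (1.0 + n_ge) / (n_perm + 1.0)
    return obs, p_perm


def per_epoch_phase_profiles(
    segments: list[Segment],
    normalize: bool = True,
    **profile_kwargs,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (theta, power) pair per segment, optionally unit-mean normalized.

    The per-epoch form feeds the permutation comparison; normalization
    removes epoch-level gamma-power scale so the comparison is about the
    shape of the phase modulation.
    """
    out = []
    for seg in segments:
        prof = phase_gamma_profile([seg], **profile_kwargs)
        ok = ~np.isnan(prof.mean_gamma_power)
        y = prof.mean_gamma_power[ok]
        if normalize and y.size and y.mean() > 0:
            y = y / y.mean()
        out.append((prof.bin_centers_rad[ok], y))
    return out


# ---------------------------------------------------------------------------
# ripples


def _idle_sample_mask(epochs: pd.DataFrame, n: int, rate_hz: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for row in epochs[epochs["state"] == "idle"].itertuples():
        i0 = max(int(round(row.start_s * rate_hz)), 0)
        i1 = min(int(round(row.end_s * rate_hz)), n)
        mask[i0:i1] = True
    return mask


def detect_ripples_kay(
    rec: Recording,
    channel_ids: list[str] | None,
    epochs: pd.DataFrame,
    band_hz: tuple[float, float] = (150.0, 200.0),
    smooth_sigma_s: float = 0.004,
    z_thresh: float = 2.0,
    min_dur_s: float = 0.015,
    min_gap_s: float = 0.0,
) -> pd.DataFrame:
    """Kay-style ripple detection confined to idle epochs.

    Each selected channel is band-passed 150–200 Hz and squared; the squared
    signals are summed across channels, Gaussian-smoothed (σ = 4 ms),
    square-rooted, and z-scored against the idle-epoch distribution.
    Candidate intervals where z ≥ ``z_thresh`` are extended to the
    surrounding zero crossings of z, merged when closer than ``min_gap_s``,
    and dropped when shorter than ``min_dur_s``. Returns columns
    ``start_s, end_s, duration_ms, peak_z``.
    """
    epochs = validate_epochs(epochs)
    if not (epochs["state"] == "idle").any():
        raise ValueError("no idle epochs available for ripple detection")
    chans = channel_ids if channel_ids is not None else rec.channel_ids
    idx = [rec.channel_index(c) for c in chans]
    sos = signal.butter(4, band_hz, btype="band", fs=rec.rate_hz, output="sos")
    power = np.zeros(rec.n_samples)
    for ci in idx:
        bp = signal.sosfiltfilt(sos, rec.samples[ci])
        power += bp**2
    env = np.sqrt(ndimage.gaussian_filter1d(power, smooth_sigma_s * rec.rate_hz))

    idle = _idle_sample_mask(epochs, rec.n_samples, rec.rate_hz)
    mu, sd = env[idle].mean(), env[idle].std()
    if sd == 0:
        return pd.DataFrame(columns=["start_s", "end_s", "duration_ms", "peak_z"])
    z = (env - mu) / sd

    rows: list[tuple[float, float, float, float]] = []
    for row in epochs[epochs["state"] == "idle"].itertuples():
        i0 = max(int(round(row.start_s * rec.rate_hz)), 0)
        i1 = min(int(round(row.end_s * rec.rate_hz)), rec.n_samples)
        zz = z[i0:i1]
        above = zz >= z_thresh
        if not above.any():
            continue
        d = np.diff(above.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(zz))
        nonpos = zz <= 0
        intervals: list[list[int]] = []
        for s, e in zip(starts, ends):
            # the above-threshold core must last min_dur_s; boundaries are
            # then extended to where z returns to 0
            if (e - s) / rec.rate_hz < min_dur_s:
                continue
            left = np.flatnonzero(nonpos[:s])
            s_ext = int(left[-1]) + 1 if left.size else 0
            right = np.flatnonzero(nonpos[e:])
            e_ext = e + int(right[0]) if right.size else len(zz)
            if intervals and s_ext - intervals[-1][1] <= min_gap_s * rec.rate_hz:
                intervals[-1][1] = max(intervals[-1][1], e_ext)
            else:
                intervals.append([s_ext, e_ext])
        for s, e in intervals:
            dur = (e - s) / rec.rate_hz
            rows.append(
                (
                    (i0 + s) / rec.rate_hz,
                    (i0 + e) / rec.rate_hz,
                    dur * 1000.0,
                    float(zz[s:e].max()),
                )
            )
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_ms", "peak_z"])


def ripple_stats(
    events: pd.DataFrame, idle_epochs: pd.DataFrame
) -> tuple[float, float, float]:
    """Ripple occurrence rate, mean duration and % of ripples > 100 ms.

    Rate is events per second of total idle time; the percentage counts
    ripples strictly longer than 100 ms. With zero events the duration
    statistics are NaN.
    """
    idle = idle_epochs[idle_epochs["state"] == "idle"] if "state" in idle_epochs else idle_epochs
    total_idle = float((idle["end_s"] - idle["start_s"]).sum())
    if total_idle <= 0:
        raise ValueError("total idle duration must be positive")
    n = len(events)
    rate = n / total_idle
    if n == 0:
        return rate, float("nan"), float("nan")
    dur = events["duration_ms"].to_numpy(dtype=float)
    return rate, float(dur.mean()), float(100.0 * np.mean(dur > 100.0))
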