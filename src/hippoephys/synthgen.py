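"""Synthetic recordings with known ground truth.

Three generators emulate the statistical structure of the three data classes
the pipeline analyzes:

* :func:`gen_patch_trace` — a single-channel voltage-clamp current trace with
  Poisson trains of bi-exponential synaptic events (outward sIPSC-like,
  inward sEPSC-like, the sign convention of a low-chloride internal solution
  at −50 mV), optional slow outward network-burst envelopes with nested
  events, and additive Gaussian noise.
* :func:`gen_mea_recording` — an 8×8 multi-electrode-array grid with
  per-channel background spiking, per-channel burst episodes, and a
  dentate-gyrus-triggered activity wave that recruits a contiguous set of
  channels at a configurable conduction speed and spatial extent.
* :func:`gen_lfp` — an awake-like LFP with a theta carrier, theta-phase
  modulated gamma (envelope ``base·(1 + m·cos(θ − φ0))``), Hann-windowed
  ripple bursts confined to idle epochs, an alternating idle/running epoch
  schedule, and 1/f + white noise.

Every generator returns its embedded features as explicit ground truth so
downstream detectors can be validated without hidden state. A single
``numpy.random.default_rng(seed)`` stream drives each simulation; identical
parameters and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Recording

__all__ = [
    "PatchSimParams",
    "MeaSimParams",
    "LfpSimParams",
    "GroundTruth",
    "psc_kernel",
    "gen_patch_trace",
    "gen_mea_recording",
    "gen_lfp",
]


@dataclass
class GroundTruth:
    """Everything a simulation embedded, echoed back for validation.

    Only the fields relevant to the producing generator are populated.
    ``params`` echoes the full parameter set (including the seed).
    """

    params: dict
    events: pd.DataFrame | None = None      # t_s, polarity, amplitude_pa
    bursts: pd.DataFrame | None = None      # onset_s, duration_s, peak_amplitude_pa
    spikes: dict[str, np.ndarray] | None = None   # channel_id -> times (s)
    dg_spike_times: np.ndarray | None = None
    wave: pd.DataFrame | None = None        # channel_id, rank, activation_lag_s
    mea_bursts: pd.DataFrame | None = None  # channel_id, start_s, end_s, n_spikes
    ripples: pd.DataFrame | None = None     # start_s, end_s, duration_ms, center_hz
    epochs: pd.DataFrame | None = None      # start_s, end_s, state


# ---------------------------------------------------------------------------
# patch-clamp traces


@dataclass
class PatchSimParams:
    """Conditions for a synthetic whole-cell voltage-clamp trace.

    Default event rates and the burst envelope mimic a neonatal CA3
    pyramidal-cell recording: frequent outward sIPSCs, sparse inward sEPSCs,
    and occasional slow outward network bursts of ≥10 pA lasting hundreds of
    milliseconds.
    """

    rate_ipsc_hz: float = 4.0
    rate_epsc_hz: float = 0.25
    amp_mean_pa: float = 20.0        # outward (IPSC) mean amplitude
    amp_sd_pa: float = 5.0
    amp_mean_epsc_pa: float = 15.0   # inward (EPSC) mean amplitude
    amp_sd_epsc_pa: float = 4.0
    rise_ms: float = 1.5
    decay_ms: float = 15.0
    burst_rate_hz: float = 0.02
    burst_amp_pa: float = 25.0
    burst_dur_ms: float = 400.0
    noise_rms_pa: float = 2.0
    duration_s: float = 60.0
    rate_hz: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_ipsc_hz", "rate_epsc_hz", "burst_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decay_ms <= self.rise_ms:
            raise ValueError("decay_ms must exceed rise_ms")
        if self.noise_rms_pa < 0:
            raise ValueError("noise_rms_pa must be >= 0")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")


def psc_kernel(
    rate_hz: float, rise_ms: float, decay_ms: float, support_factor: float = 8.0
) -> np.ndarray:
    """Difference-of-exponentials PSC kernel normalized to unit peak.

    ``k(t) = (exp(-t/τd) - exp(-t/τr)) / k(t_peak)`` with analytic peak time
    ``t_peak = τr τd / (τd − τr) · ln(τd/τr)``; support truncated at
    ``support_factor · τd``.
    """
    tau_r = rise_ms / 1000.0
    tau_d = decay_ms / 1000.0
    n = max(int(round(support_factor * tau_d * rate_hz)), 2)
    t = np.arange(n) / rate_hz
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    return k / peak


def psc_peak_time_s(rise_ms: float, decay_ms: float) -> float:
    """Time from event onset to kernel peak (seconds)."""
    tau_r = rise_ms / 1000.0
    tau_d = decay_ms / 1000.0
    return tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)


def _add_kernel(trace: np.ndarray, start_idx: int, kernel: np.ndarray) -> None:
    stop = min(start_idx + len(kernel), len(trace))
    if stop > start_idx >= 0:
        trace[start_idx:stop] += kernel[: stop - start_idx]


def gen_patch_trace(p: PatchSimParams) -> tuple[Recording, GroundTruth]:
    """Simulate a 1-channel current trace with known synaptic events.

    Outward events are positive (sIPSC), inward negative (sEPSC). Network
    bursts are slow outward Hann envelopes with nested outward events.
    Returns the trace (pA) and the embedded truth.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.rate_hz))
    trace = np.zeros(n)
    kernel = psc_kernel(p.rate_hz, p.rise_ms, p.decay_ms)

    ev_t: list[float] = []
    ev_pol: list[str] = []
    ev_amp: list[float] = []

    for polarity, rate, mean, sd in (
        ("outward", p.rate_ipsc_hz, p.amp_mean_pa, p.amp_sd_pa),
        ("inward", p.rate_epsc_hz, p.amp_mean_epsc_pa, p.amp_sd_epsc_pa),
    ):
        n_ev = rng.poisson(rate * p.duration_s)
        times = np.sort(rng.uniform(0, p.duration_s, n_ev))
        amps = np.clip(rng.normal(mean, sd, n_ev), 0.2 * mean, None)
        sign = 1.0 if polarity == "outward" else -1.0
        for t0, amp in zip(times, amps):
            _add_kernel(trace, int(round(t0 * p.rate_hz)), sign * amp * kernel)
            ev_t.append(float(t0))
            ev_pol.append(polarity)
            ev_amp.append(float(amp))

    bursts: list[tuple[float, float, float]] = []
    n_b = rng.poisson(p.burst_rate_hz * p.duration_s)
    dur_s = p.burst_dur_ms / 1000.0
    for t0 in np.sort(rng.uniform(0, max(p.duration_s - dur_s, 0.0), n_b)):
        m = int(round(dur_s * p.rate_hz))
        envelope = p.burst_amp_pa * np.hanning(m)
        _add_kernel(trace, int(round(t0 * p.rate_hz)), envelope)
        # nested fast outward events riding the envelope
        for tn in np.sort(rng.uniform(t0, t0 + dur_s, rng.poisson(20 * dur_s))):
            amp = float(np.clip(rng.normal(p.amp_mean_pa, p.amp_sd_pa), 1.0, None))
            _add_kernel(trace, int(round(tn * p.rate_hz)), amp * kernel)
        bursts.append((float(t0), dur_s, float(p.burst_amp_pa)))

    if p.noise_rms_pa > 0:
        trace += rng.normal(0.0, p.noise_rms_pa, n)

    events = pd.DataFrame({"t_s": ev_t, "polarity": ev_pol, "amplitude_pa": ev_amp})
    events = events.sort_values("t_s", ignore_index=True)
    truth = GroundTruth(
        params=dataclasses.asdict(p),
        events=events,
        bursts=pd.DataFrame(
            bursts, columns=["onset_s", "duration_s", "peak_amplitude_pa"]
        ),
    )
    rec = Recording(
        samples=trace[None, :], rate_hz=p.rate_hz, channel_ids=["patch0"], units="pA"
    )
    return rec, truth


# ---------------------------------------------------------------------------
# MEA grids


@dataclass
class MeaSimParams:
    """Conditions for a synthetic 8×8 MEA recording of an organotypic slice.

    Each dentate-gyrus (DG) trigger spike is followed, after
    ``wave_onset_lag_ms``, by a slow negative field deflection recruiting
    ``wave_extent_channels`` spatially contiguous channels outward from the
    DG electrode at ``wave_speed_ch_per_ms``; the deflection amplitude is
    ``wave_amp_sd`` noise standard deviations and persists until
    ``wave_dur_ms`` after the trigger.
    """

    n_rows: int = 8
    n_cols: int = 8
    baseline_rate_hz: float = 0.2         # background spikes per channel
    spike_amp_sd: float = 8.0             # spike peak in noise-SD units
    burst_rate_hz: float = 0.0            # burst episodes per channel
    burst_n_spikes: int = 12
    burst_dur_s: float = 0.15
    dg_channel: str = "e33"               # trigger electrode (row 3, col 3)
    dg_spike_times: tuple[float, ...] | None = None
    dg_spike_rate_hz: float = 0.5
    wave_onset_lag_ms: float = 5.0
    wave_speed_ch_per_ms: float = 0.3
    wave_extent_channels: int = 12
    wave_amp_sd: float = 8.0
    wave_dur_ms: float = 120.0
    noise_rms: float = 10.0               # µV
    duration_s: float = 10.0
    rate_hz: float = 20_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wave_extent_channels < 0 or self.wave_extent_channels > self.n_rows * self.n_cols:
            raise ValueError("wave extent must be within the grid size")
        if self.wave_onset_lag_ms < 0:
            raise ValueError("wave onset lag must be >= 0")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")


def _mea_channel_ids(n_rows: int, n_cols: int) -> tuple[list[str], list[tuple[int, int]]]:
    ids, geom = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"e{r}{c}")
            geom.append((r, c))
    return ids, geom


def _wave_recruitment_order(
    origin: tuple[int, int], n_rows: int, n_cols: int
) -> list[tuple[int, int]]:
    """Grid cells sorted by distance from the origin (8-neighbourhood rings).

    Sorting by (Chebyshev ring, Euclidean distance, row, col) yields a
    deterministic recruitment order in which every prefix is 8-connected.
    """
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]

    def key(cell: tuple[int, int]):
        dr, dc = cell[0] - origin[0], cell[1] - origin[1]
        return (max(abs(dr), abs(dc)), dr * dr + dc * dc, cell[0], cell[1])

    return sorted(cells, key=key)


def _spike_waveform(rate_hz: float) -> np.ndarray:
    """Biphasic ~1.2 ms extracellular spike, unit negative peak."""
    t = np.arange(int(round(1.2e-3 * rate_hz))) / rate_hz
    w = -np.exp(-(((t - 3e-4) / 1.2e-4) ** 2)) + 0.45 * np.exp(
        -(((t - 6.5e-4) / 2.2e-4) ** 2)
    )
    return w / np.max(np.abs(w))


def gen_mea_recording(p: MeaSimParams) -> tuple[Recording, GroundTruth]:
    """Simulate a 64-channel MEA grid with a DG-triggered propagating wave."""
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.rate_hz))
    ids, geom = _mea_channel_ids(p.n_rows, p.n_cols)
    n_ch = len(ids)
    data = np.zeros((n_ch, n))
    spike_w = _spike_waveform(p.rate_hz) * p.spike_amp_sd * p.noise_rms

    spikes: dict[str, np.ndarray] = {}
    mea_bursts: list[tuple[str, float, float, int]] = []
    for ci, cid in enumerate(ids):
        times = np.sort(
            rng.uniform(0, p.duration_s, rng.poisson(p.baseline_rate_hz * p.duration_s))
        )
        burst_times = []
        for b0 in rng.uniform(
            0, max(p.duration_s - p.burst_dur_s, 0),
            rng.poisson(p.burst_rate_hz * p.duration_s),
        ):
            bt = np.sort(rng.uniform(b0, b0 + p.burst_dur_s, p.burst_n_spikes))
            burst_times.append(bt)
            mea_bursts.append((cid, float(b0), float(b0 + p.burst_dur_s), len(bt)))
        if burst_times:
            times = np.sort(np.concatenate([times] + burst_times))
        for t0 in times:
            _add_kernel(data[ci], int(round(t0 * p.rate_hz)), spike_w)
        spikes[cid] = times

    # DG trigger spikes
    if p.dg_spike_times is not None:
        dg_times = np.sort(np.asarray(p.dg_spike_times, dtype=float))
    else:
        n_dg = rng.poisson(p.dg_spike_rate_hz * p.duration_s)
        dg_times = np.sort(rng.uniform(0.2, max(p.duration_s - 0.2, 0.2), n_dg))
    dg_idx = ids.index(p.dg_channel)
    dg_w = _spike_waveform(p.rate_hz) * 2.0 * p.spike_amp_sd * p.noise_rms
    for t0 in dg_times:
        _add_kernel(data[dg_idx], int(round(t0 * p.rate_hz)), dg_w)
    spikes[p.dg_channel] = np.sort(np.concatenate([spikes[p.dg_channel], dg_times]))

    # propagating activity wave: contiguous recruitment outward from DG
    order = _wave_recruitment_order(geom[dg_idx], p.n_rows, p.n_cols)
    recruited = order[: p.wave_extent_channels]
    wave_rows: list[tuple[str, int, float]] = []
    rise_s = 0.004
    for rank, cell in enumerate(recruited):
        ci = geom.index(cell)
        lag_s = p.wave_onset_lag_ms / 1000.0 + (
            rank / p.wave_speed_ch_per_ms / 1000.0 if p.wave_speed_ch_per_ms > 0 else 0.0
        )
        wave_rows.append((ids[ci], rank, float(lag_s)))
        end_s = p.wave_dur_ms / 1000.0
        if lag_s >= end_s:
            continue
        m = int(round((end_s - lag_s) * p.rate_hz))
        pulse = -p.wave_amp_sd * p.noise_rms * np.ones(m)
        n_rise = min(int(rise_s * p.rate_hz), m)
        pulse[:n_rise] *= 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / max(n_rise, 1)))
        n_fall = min(int(2 * rise_s * p.rate_hz), m)
        pulse[m - n_fall:] *= 0.5 * (
            1 + np.cos(np.pi * np.arange(n_fall) / max(n_fall, 1))
        )
        for t0 in dg_times:
            _add_kernel(data[ci], int(round((t0 + lag_s) * p.rate_hz)), pulse)

    if p.noise_rms > 0:
        data += rng.normal(0.0, p.noise_rms, data.shape)

    rec = Recording(
        samples=data, rate_hz=p.rate_hz, channel_ids=ids, geometry=geom, units="uV"
    )
    truth = GroundTruth(
        params=dataclasses.asdict(p),
        spikes=spikes,
        dg_spike_times=dg_times,
        wave=pd.DataFrame(wave_rows, columns=["channel_id", "rank", "activation_lag_s"]),
        mea_bursts=pd.DataFrame(
            mea_bursts, columns=["channel_id", "start_s", "end_s", "n_spikes"]
        ),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# awake LFP


@dataclass
class LfpSimParams:
    """Conditions for a synthetic awake hippocampal LFP.

    The gamma envelope is ``gamma_amp_base · (1 + m·cos(θ_theta − φ0))``
    where ``θ_theta`` is the theta carrier phase; ripples are Hann-windowed
    sinusoid bursts placed only inside idle epochs. Epochs alternate
    idle/running blocks starting with idle.
    """

    theta_hz: float = 7.0
    theta_amp: float = 100.0              # µV
    gamma_hz: float = 55.0
    gamma_bw_hz: float = 30.0             # carrier bandwidth around gamma_hz
    gamma_amp_base: float = 20.0
    modulation_depth: float = 0.5         # m in [0, 1]
    preferred_phase_rad: float = 0.0      # φ0
    ripple_rate_hz: float = 0.2           # during idle
    ripple_center_hz: float = 180.0       # within [150, 200]
    ripple_dur_range_ms: tuple[float, float] = (40.0, 140.0)
    ripple_min_gap_s: float = 0.25        # refractory gap between ripples
    ripple_amp: float = 60.0
    idle_block_s: float = 12.0
    run_block_s: float = 12.0
    noise_white: float = 10.0
    noise_pink: float = 15.0
    n_channels: int = 3
    duration_s: float = 48.0
    rate_hz: float = 1250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")
        if not 150.0 <= self.ripple_center_hz <= 200.0:
            raise ValueError("ripple_center_hz must lie within [150, 200]")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")


def _epoch_schedule(p: LfpSimParams) -> pd.DataFrame:
    rows = []
    t, state = 0.0, "idle"
    while t < p.duration_s - 1e-9:
        block = p.idle_block_s if state == "idle" else p.run_block_s
        end = min(t + block, p.duration_s)
        rows.append((t, end, state))
        t = end
        state = "running" if state == "idle" else "idle"
    return pd.DataFrame(rows, columns=["start_s", "end_s", "state"])


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def gen_lfp(p: LfpSimParams) -> tuple[Recording, GroundTruth, pd.DataFrame]:
    """Simulate a multichannel awake LFP with theta, coupled gamma and ripples."""
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.rate_hz))
    t = np.arange(n) / p.rate_hz
    epochs = _epoch_schedule(p)

    theta_phase = 2 * np.pi * p.theta_hz * t
    theta = p.theta_amp * np.cos(theta_phase)
    envelope = p.gamma_amp_base * (
        1.0 + p.modulation_depth * np.cos(theta_phase - p.preferred_phase_rad)
    )
    # stochastic narrowband gamma carrier (unit RMS): real gamma is broadband
    # activity, not a tone phase-locked to theta
    from scipy import signal as _signal

    lo = max(p.gamma_hz - p.gamma_bw_hz / 2, 1.0)
    hi = min(p.gamma_hz + p.gamma_bw_hz / 2, 0.45 * p.rate_hz)
    sos = _signal.butter(4, [lo, hi], btype="band", fs=p.rate_hz, output="sos")
    carrier = _signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    carrier /= max(carrier.std(), 1e-12)
    gamma = envelope * carrier
    base = theta + gamma

    # ripples: sequential Poisson placement inside idle epochs, no overlap
    ripple_rows: list[tuple[float, float, float, float]] = []
    ripple_sig = np.zeros(n)
    dur_lo, dur_hi = p.ripple_dur_range_ms
    for _, ep in epochs[epochs.state == "idle"].iterrows():
        t_cur = ep.start_s + 0.2
        while p.ripple_rate_hz > 0:
            t_cur += rng.exponential(1.0 / p.ripple_rate_hz)
            dur_s = rng.uniform(dur_lo, dur_hi) / 1000.0
            if t_cur + dur_s > ep.end_s - 0.05:
                break
            m = int(round(dur_s * p.rate_hz))
            tt = np.arange(m) / p.rate_hz
            burst = (
                p.ripple_amp
                * np.hanning(m)
                * np.cos(2 * np.pi * p.ripple_center_hz * (tt - dur_s / 2))
            )
            _add_kernel(ripple_sig, int(round(t_cur * p.rate_hz)), burst)
            ripple_rows.append(
                (float(t_cur), float(t_cur + dur_s), dur_s * 1000.0, p.ripple_center_hz)
            )
            t_cur += dur_s + p.ripple_min_gap_s

    data = np.zeros((p.n_channels, n))
    for ci in range(p.n_channels):
        noise = p.noise_white * rng.normal(0.0, 1.0, n) + p.noise_pink * _pink_noise(
            rng, n
        )
        data[ci] = base + ripple_sig + noise

    rec = Recording(
        samples=data,
        rate_hz=p.rate_hz,
        channel_ids=[f"lfp{ci}" for ci in range(p.n_channels)],
        units="uV",
    )
    truth = GroundTruth(
        params=dataclasses.asdict(p),
        ripples=pd.DataFrame(
            ripple_rows, columns=["start_s", "end_s", "duration_ms", "center_hz"]
        ),
        epochs=epochs,
    )
    return rec, truth, epochs
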