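import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from hippoephys import mea_spread, synthgen
from hippoephys.io_formats import Recording
from hippoephys.mea_spread import (
    SpikeTrain,
    activity_clusters_at,
    channel_sds,
    cluster_timecourse,
    detect_bursts,
    detect_spikes,
    max_component_size,
    poisson_surprise,
    preprocess_for_clusters,
)


def flood_fill_max(mask):
    """Brute-force largest 8-connected component (independent oracle)."""
    mask = mask.copy()
    best = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0]:
                continue
            stack, size = [(r0, c0)], 0
            mask[r0, c0] = False
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                            mask[rr, cc] = False
                            stack.append((rr, cc))
            best = max(best, size)
    return best


class TestSpikes:
    def test_empty_recording_rejected(self):
        rec = Recording(np.empty((1, 0)), 20000.0, ["a"])
        with pytest.raises(ValueError):
            detect_spikes(rec)

    def test_injected_spike_recovered(self):
        """One 10x-SD spike waveform gives exactly 1 spike within 0.5 ms."""
        rng = np.random.default_rng(0)
        n = int(2 * 20000)
        data = rng.normal(0, 5.0, (1, n))
        w = synthgen._spike_waveform(20000.0) * 50.0
        i0 = n // 2
        data[0, i0 : i0 + len(w)] += w
        rec = Recording(data, 20000.0, ["a"])
        trains = detect_spikes(rec)
        big = trains[0].times[np.abs(trains[0].times - 1.0) < 0.01]
        assert len(big) == 1
        assert big[0] == pytest.approx(1.0, abs=0.0005)

    def test_noise_false_positive_rate_bounded(self):
        """At 4 robust-SD the FP rate stays below the Gaussian upcrossing bound."""
        rng = np.random.default_rng(1)
        dur, rate = 30.0, 20000.0
        rec = Recording(rng.normal(0, 3.0, (1, int(dur * rate)))[None, 0][None, :][0],
                        rate, ["a"])
        trains = detect_spikes(rec)
        # Rice upcrossing bound for band-limited Gaussian noise at k sigma:
        # rate <= f_max * exp(-k^2 / 2)
        bound = 3000.0 * np.exp(-(4.0**2) / 2)
        assert len(trains[0].times) / dur <= bound

    def test_low_rate_warns(self):
        rec = Recording(np.zeros((1, 5000)), 5000.0, ["a"])
        with pytest.warns(UserWarning):
            detect_spikes(rec)


class TestPoissonSurprise:
    def test_zero_count_is_zero(self):
        assert poisson_surprise(0, 1.0, 5.0) == 0.0

    def test_matches_brute_force_tail(self):
        """S equals -log10 of the direct pmf tail sum to 1e-10 relative."""
        for n, t, lam in [(10, 0.1, 1.0), (3, 2.0, 0.5), (50, 1.0, 5.0), (1, 1.0, 1.0)]:
            mu = lam * t
            k = np.arange(n, n + 400)
            tail = np.sum(np.exp(k * np.log(mu) - mu - special.gammaln(k + 1)))
            assert poisson_surprise(n, t, lam) == pytest.approx(
                -np.log10(tail), rel=1e-10
            )

    @given(n=st.integers(1, 60))
    @settings(deadline=None, max_examples=30)
    def test_monotone_in_count(self, n):
        assert poisson_surprise(n + 1, 0.5, 2.0) > poisson_surprise(n, 0.5, 2.0)

    def test_zero_rate_convention(self):
        with pytest.warns(UserWarning):
            assert poisson_surprise(3, 1.0, 0.0) == np.inf


class TestBursts:
    def test_scripted_burst_detected(self):
        """20 spikes in 0.15 s on a 0.5 Hz background give exactly one burst."""
        rng = np.random.default_rng(5)
        bg = np.sort(rng.uniform(0, 600, 300))
        burst = 100.0 + np.sort(rng.uniform(0, 0.15, 20))
        train = SpikeTrain("e00", np.unique(np.concatenate([bg, burst])))
        bursts = detect_bursts(train, 600.0)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.start_s >= 99.9 and b.end_s <= 100.3
        assert b.n_spikes >= 20

    def test_small_burst_rejected_by_count_rule(self):
        rng = np.random.default_rng(6)
        bg = np.sort(rng.uniform(0, 600, 300))
        burst = 100.0 + np.sort(rng.uniform(0, 0.12, 8))
        train = SpikeTrain("e00", np.unique(np.concatenate([bg, burst])))
        assert detect_bursts(train, 600.0) == []

    def test_outputs_satisfy_rules(self):
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, 300, 600))
        for b in detect_bursts(SpikeTrain("x", np.unique(times)), 300.0):
            assert b.n_spikes >= 10
            assert b.end_s - b.start_s >= 0.1
            assert b.surprise >= 10.0

    def test_too_few_spikes_empty(self):
        assert detect_bursts(SpikeTrain("x", np.array([1.0])), 10.0) == []


class TestPreprocess:
    def test_constant_becomes_zero(self):
        rec = Recording(np.full((2, 40000), 7.0), 20000.0, ["a", "b"])
        out = preprocess_for_clusters(rec)
        assert out.rate_hz == 5000.0
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_drift_removed_transient_kept(self):
        """Slow linear drift is suppressed; a fast transient survives."""
        rate = 20000.0
        n = int(6 * rate)
        t = np.arange(n) / rate
        drift = 50.0 * t / 6.0
        x = drift.copy()
        i0 = n // 2
        x[i0 : i0 + int(0.004 * rate)] += 40.0
        rec = Recording(x[None, :], rate, ["a"])
        out = preprocess_for_clusters(rec)
        mid = out.samples[0][int(1.0 * 5000) : int(5.0 * 5000)]
        transient_peak = out.samples[0][
            int(2.9 * 5000) : int(3.1 * 5000)
        ].max()
        assert transient_peak == pytest.approx(40.0, rel=0.10)
        baseline = np.delete(mid, slice(int(1.8 * 5000), int(2.2 * 5000)))
        assert np.percentile(np.abs(baseline), 95) < 0.05 * 50.0

    def test_output_rate_exact(self, mea_sim):
        _, rec, _ = mea_sim
        assert preprocess_for_clusters(rec).rate_hz == 5000.0


class TestClusters:
    @staticmethod
    def _grid_recording(values):
        geom = [(r, c) for r in range(8) for c in range(8)]
        ids = [f"e{r}{c}" for r, c in geom]
        return Recording(np.asarray(values, float).reshape(64, 1), 5000.0, ids,
                         geometry=geom)

    def test_all_above_threshold(self):
        rec = self._grid_recording(np.full(64, 10.0))
        pos, neg = activity_clusters_at(rec, 0.0, np.ones(64), thresh_sd=2.0)
        assert pos == 64 and neg == 0

    def test_single_channel(self):
        v = np.zeros(64)
        v[27] = 10.0
        rec = self._grid_recording(v)
        assert activity_clusters_at(rec, 0.0, np.ones(64)) == (1, 0)

    def test_checkerboard_is_single_component(self):
        """An 8-connected checkerboard forms one 32-cell component."""
        v = np.array([10.0 if (r + c) % 2 == 0 else 0.0
                      for r in range(8) for c in range(8)])
        rec = self._grid_recording(v)
        pos, _ = activity_clusters_at(rec, 0.0, np.ones(64))
        assert pos == 32 == flood_fill_max(v.reshape(8, 8) > 2)

    def test_time_outside_rejected(self):
        rec = self._grid_recording(np.zeros(64))
        with pytest.raises(ValueError):
            activity_clusters_at(rec, 5.0, np.ones(64))

    @given(st.integers(0, 2**63 - 1))
    @settings(deadline=None, max_examples=60)
    def test_matches_flood_fill_oracle(self, seed):
        """Largest component equals a brute-force flood fill on random masks."""
        mask = np.random.default_rng(seed).random((8, 8)) < 0.4
        assert max_component_size(mask) == flood_fill_max(mask)


class TestClusterTimecourse:
    def test_wave_recovered_at_50ms(self, mea_sim):
        """The generator wave of 12 channels is read back at the 50 ms lag."""
        p, rec, truth = mea_sim
        rec5k = preprocess_for_clusters(rec)
        _, agg = cluster_timecourse(rec5k, truth.dg_spike_times)
        i50 = int(np.flatnonzero(agg["lags_ms"] == 50.0)[0])
        assert agg["mean_raw_curve"][i50] == pytest.approx(12.0, abs=2.0)

    def test_normalization_mean_of_first_bins_is_one(self, mea_sim):
        _, rec, truth = mea_sim
        rec5k = preprocess_for_clusters(rec)
        curves, _ = cluster_timecourse(rec5k, truth.dg_spike_times)
        for c in curves:
            if not np.isnan(c.normalized[0]):
                assert np.mean(c.normalized[:4]) == pytest.approx(1.0)

    def test_no_activity_flags_undefined_normalization(self):
        geom = [(r, c) for r in range(8) for c in range(8)]
        ids = [f"e{r}{c}" for r, c in geom]
        rec = Recording(np.zeros((64, 5000)), 5000.0, ids, geometry=geom)
        curves, agg = cluster_timecourse(rec, np.array([0.4]))
        assert np.all(curves[0].raw == 0)
        assert np.all(np.isnan(curves[0].normalized))
        assert not agg["normalization_defined"][0]

    def test_trigger_near_edge_skipped(self, mea_sim):
        _, rec, truth = mea_sim
        rec5k = preprocess_for_clusters(rec)
        curves, _ = cluster_timecourse(rec5k, np.array([rec5k.duration_s - 0.01]))
        assert curves == []

    def test_time_shift_equivariance(self):
        """Circularly shifting recording and triggers leaves curves unchanged."""
        rng = np.random.default_rng(9)
        geom = [(r, c) for r in range(8) for c in range(8)]
        ids = [f"e{r}{c}" for r, c in geom]
        data = rng.normal(0, 1, (64, 10000))
        shift = 2500
        rec_a = Recording(data, 5000.0, ids, geometry=geom)
        rec_b = Recording(np.roll(data, shift, axis=1), 5000.0, ids, geometry=geom)
        ca, _ = cluster_timecourse(rec_a, np.array([0.5]))
        cb, _ = cluster_timecourse(rec_b, np.array([0.5 + shift / 5000.0]))
        assert np.array_equal(ca[0].raw, cb[0].raw)

    def test_sd_modes(self, mea_sim):
        _, rec, _ = mea_sim
        rec5k = preprocess_for_clusters(rec)
        per = channel_sds(rec5k, "per_channel")
        glob = channel_sds(rec5k, "global")
        assert per.shape == (64,) and len(np.unique(glob)) == 1
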