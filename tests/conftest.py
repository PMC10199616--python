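import numpy as np
import pytest

from hippoephys import synthgen


@pytest.fixture(scope="session")
def patch_sim():
    """A 60 s neonatal-like voltage-clamp simulation with known truth."""
    p = synthgen.PatchSimParams(
        rate_ipsc_hz=4.0, rate_epsc_hz=0.25, burst_rate_hz=0.0,
        noise_rms_pa=2.0, duration_s=60.0, seed=11,
    )
    rec, truth = synthgen.gen_patch_trace(p)
    return p, rec, truth


@pytest.fixture(scope="session")
def mea_sim():
    """A 10 s MEA simulation with a 12-channel DG-triggered wave."""
    p = synthgen.MeaSimParams(
        seed=5, duration_s=10.0, dg_spike_times=tuple(np.arange(0.5, 9.5, 1.0))
    )
    rec, truth = synthgen.gen_mea_recording(p)
    return p, rec, truth


@pytest.fixture(scope="session")
def lfp_sim():
    """A 24 s awake-LFP simulation with theta-coupled gamma, no ripples."""
    p = synthgen.LfpSimParams(
        seed=7, modulation_depth=1.0, preferred_phase_rad=0.0,
        ripple_rate_hz=0.0, duration_s=24.0,
    )
    rec, truth, epochs = synthgen.gen_lfp(p)
    return p, rec, truth, epochs
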