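import numpy as np
import pytest

from erpdecode.simgen import (ComponentSpec, GroupProfile, SimulationConfig,
                              simulate_participant)


def quiet_component(name="P3", cluster="central", latency=340.0,
                    amplitude=5.0, width=40.0, polarity=1):
    """Deterministic component: no between- or within-trial variability."""
    return ComponentSpec(name=name, cluster=cluster, polarity=polarity,
                         mean_latency=latency, latency_sd_between=0.0,
                         latency_jitter_within=0.0, mean_amplitude=amplitude,
                         amplitude_sd=0.0, width=width)


def quiet_profile(components, group="young", white=0.0, pink=0.0):
    comps = tuple(components)
    return GroupProfile(group=group, components_frequent=comps,
                        components_rare=comps, noise_white_sd=white,
                        noise_pink_sd=pink)


@pytest.fixture
def p3_only_profile():
    """Noise-free single-P3 profile (rare and frequent identical)."""
    return quiet_profile([quiet_component()])


@pytest.fixture
def small_config():
    return SimulationConfig(n_young=1, n_older=1, trials_per_participant=40,
                            n_rare=8, fs=256.0, epoch_len_samples=256, seed=0)


@pytest.fixture
def noisy_epochs():
    """One realistic participant at reduced sampling rate."""
    from erpdecode.simgen import default_profiles
    young, _ = default_profiles()
    cfg = SimulationConfig(n_young=1, n_older=0, fs=96.0,
                           epoch_len_samples=96, seed=42)
    return simulate_participant(young, cfg, participant_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
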