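"""Synthetic visual-oddball EEG epoch generation.

Simulates per-participant epoch sets with the statistical structure the
downstream decoding analysis assumes: Gaussian-bump ERP components (P1,
N170, P2 over the occipital cluster; P3 over the central cluster) whose
amplitudes and latencies differ by stimulus type (frequent square vs. rare
face) and by age group (older adults: delayed latencies, reduced posterior
amplitudes), riding on pink + white noise, with optional high-amplitude
artifact epochs.

The generator works directly at the electrode-cluster level (one trace per
cluster, fixed order occipital/parietal/central/frontal), because the
analysis only ever consumes cluster averages.  An optional
``channels_per_cluster=3`` mode emits three noisy copies per cluster under
standard 10-20 channel names to exercise cluster averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CLUSTERS: tuple[str, ...] = ("occipital", "parietal", "central", "frontal")

#: default 10-20 channel triplets per cluster, used by the 3-channel mode
CLUSTER_CHANNELS: dict[str, tuple[str, ...]] = {
    "occipital": ("O1", "Oz", "O2"),
    "parietal": ("P3", "Pz", "P4"),
    "central": ("C3", "Cz", "C4"),
    "frontal": ("F3", "Fz", "F4"),
}

LABEL_FREQUENT = 0
LABEL_RARE = 1


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component as a Gaussian bump on a single cluster.

    ``mean_amplitude`` is signed (negative for N170); ``polarity`` must
    agree with its sign and exists so downstream window definitions can be
    derived from the spec without inspecting amplitudes.
    """

    name: str
    cluster: str
    polarity: int
    mean_latency: float  # ms
    latency_sd_between: float  # ms, participant-level offset
    latency_jitter_within: float  # ms, trial-level jitter
    mean_amplitude: float  # µV, signed
    amplitude_sd: float  # µV
    width: float  # ms, Gaussian sigma

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r}; valid: {CLUSTERS}")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.latency_sd_between < 0:
            raise ValueError("latency_sd_between must be >= 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.mean_amplitude != 0 and np.sign(self.mean_amplitude) != self.polarity:
            raise ValueError(
                f"{self.name}: polarity {self.polarity} inconsistent with "
                f"signed mean_amplitude {self.mean_amplitude}"
            )
        if self.name == "N170" and self.polarity != -1:
            raise ValueError("N170 must have polarity -1")
        if self.name in ("P1", "P2", "P3") and self.polarity != 1:
            raise ValueError(f"{self.name} must have polarity +1")


@dataclass(frozen=True)
class GroupProfile:
    """Per-age-group generative profile: component sets per stimulus type
    plus noise levels."""

    group: str
    components_frequent: tuple[ComponentSpec, ...]
    components_rare: tuple[ComponentSpec, ...]
    noise_white_sd: float  # µV
    noise_pink_sd: float  # µV

    def __post_init__(self) -> None:
        freq = {c.name: c for c in self.components_frequent}
        rare = {c.name: c for c in self.components_rare}
        # oddball contrast: rare components must not be weaker than
        # frequent ones (equality allowed for degenerate test profiles)
        if "P3" in freq and "P3" in rare:
            if rare["P3"].mean_amplitude < freq["P3"].mean_amplitude:
                raise ValueError("rare P3 amplitude must exceed frequent P3 amplitude")
        if "N170" in freq and "N170" in rare:
            if abs(rare["N170"].mean_amplitude) < abs(freq["N170"].mean_amplitude):
                raise ValueError("rare N170 magnitude must exceed frequent N170 magnitude")

    def component(self, name: str, rare: bool) -> ComponentSpec:
        pool = self.components_rare if rare else self.components_frequent
        for c in pool:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class SimulationConfig:
    n_young: int = 10
    n_older: int = 10
    trials_per_participant: int = 147
    n_rare: int = 23
    fs: float = 256.0
    epoch_start: float = -200.0  # ms
    epoch_len_samples: int = 256
    artifact_rate: float = 0.0
    artifact_amplitude: float = 150.0  # µV
    seed: int = 0
    channels_per_cluster: int = 1  # 1 = cluster traces; 3 = named channels

    def __post_init__(self) -> None:
        if not self.n_rare < self.trials_per_participant:
            raise ValueError("n_rare must be < trials_per_participant")
        if self.epoch_len_samples < 64:
            raise ValueError("epoch_len_samples must be >= 64")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 100:
            raise ValueError("artifact_amplitude must exceed 100 µV")
        if self.channels_per_cluster not in (1, 3):
            raise ValueError("channels_per_cluster must be 1 or 3")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        step = 1000.0 / self.fs
        return self.epoch_start + step * np.arange(self.epoch_len_samples)


@dataclass
class EpochSet:
    """Trials × samples × clusters voltage array with trial labels.

    ``voltages`` is in µV; the third axis follows the fixed cluster order
    (occipital, parietal, central, frontal) unless ``channel_names`` is set,
    in which case the axis holds the named channels and the set must pass
    through ``preprocess.cluster_average`` before feature extraction.
    """

    voltages: np.ndarray  # (n_trials, n_samples, n_clusters_or_channels)
    labels: np.ndarray  # (n_trials,), 0=frequent 1=rare
    times: np.ndarray  # (n_samples,) ms
    participant_id: str
    group: str
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.labels.shape[0] != self.voltages.shape[0]:
            raise ValueError("labels length must equal number of trials")
        if self.times.shape[0] != self.voltages.shape[1]:
            raise ValueError("times length must equal number of samples")
        d = np.diff(self.times)
        if len(d) and not np.all(d > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def fs(self) -> float:
        return 1000.0 / (self.times[1] - self.times[0])

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.voltages.copy(), self.labels.copy(), self.times.copy(),
            self.participant_id, self.group, self.channel_names,
        )


# ---------------------------------------------------------------------------
# default group profiles

def _spec(name, cluster, pol, lat, amp, *, lat_sd=10.0, jitter=15.0,
          amp_sd=0.8, width=None):
    default_widths = {"P1": 20.0, "N170": 22.0, "P2": 30.0, "P3": 45.0}
    return ComponentSpec(
        name=name, cluster=cluster, polarity=pol, mean_latency=lat,
        latency_sd_between=lat_sd, latency_jitter_within=jitter,
        mean_amplitude=amp, amplitude_sd=amp_sd,
        width=width if width is not None else default_widths[name],
    )


def default_profiles() -> tuple[GroupProfile, GroupProfile]:
    """Default young/older generative profiles.

    Encodes the structure the analysis probes: rare (face) trials carry a
    larger N170 and P3 than frequent (square) trials; older adults show
    delayed P2/P3 latencies (P3 340 ms young vs. 400 ms older, P2 235 vs.
    300 ms) and reduced posterior (occipital) amplitudes, while the P2
    rare-vs-frequent contrast is the same in both groups — an age-invariant
    discriminative feature.
    """
    young_frequent = (
        _spec("P1", "occipital", 1, 100.0, 3.0),
        _spec("N170", "occipital", -1, 170.0, -1.5, jitter=12.0),
        _spec("P2", "occipital", 1, 235.0, 2.0),
        _spec("P3", "central", 1, 340.0, 1.5),
    )
    young_rare = (
        _spec("P1", "occipital", 1, 100.0, 3.0),
        _spec("N170", "occipital", -1, 170.0, -5.5, jitter=12.0),
        _spec("P2", "occipital", 1, 235.0, 5.0),
        _spec("P3", "central", 1, 340.0, 4.0),
    )
    older_frequent = (
        _spec("P1", "occipital", 1, 110.0, 2.1),
        _spec("N170", "occipital", -1, 180.0, -1.0, jitter=12.0),
        _spec("P2", "occipital", 1, 300.0, 2.0),
        _spec("P3", "central", 1, 400.0, 1.5),
    )
    older_rare = (
        _spec("P1", "occipital", 1, 110.0, 2.1),
        _spec("N170", "occipital", -1, 180.0, -3.0, jitter=12.0),
        _spec("P2", "occipital", 1, 300.0, 5.0),
        _spec("P3", "central", 1, 400.0, 3.5),
    )
    young = GroupProfile("young", young_frequent, young_rare,
                         noise_white_sd=2.0, noise_pink_sd=3.0)
    older = GroupProfile("older", older_frequent, older_rare,
                         noise_white_sd=2.0, noise_pink_sd=3.0)
    return young, older


# ---------------------------------------------------------------------------
# noise

def pink_noise(rng: np.random.Generator, n_samples: int, size: tuple[int, ...],
               sd: float) -> np.ndarray:
    """1/f-power noise: spectrally shape white noise with a 1/sqrt(f) gain,
    then rescale to the requested standard deviation."""
    if sd == 0:
        return np.zeros(size + (n_samples,))
    white = rng.standard_normal(size + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    s = shaped.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return shaped / s * sd


# ---------------------------------------------------------------------------
# simulation

def _validate_latencies(profile: GroupProfile, config: SimulationConfig) -> None:
    t0, t1 = config.times[0], config.times[-1]
    for comp in profile.components_frequent + profile.components_rare:
        if not t0 <= comp.mean_latency <= t1:
            raise ValueError(
                f"component {comp.name} latency {comp.mean_latency} ms lies "
                f"outside the epoch window [{t0:.1f}, {t1:.1f}] ms"
            )


def simulate_participant(profile: GroupProfile, config: SimulationConfig,
                         participant_seed: int,
                         participant_id: str | None = None) -> EpochSet:
    """Simulate one participant's oddball session.

    Exactly ``config.n_rare`` trials are labeled rare, at positions drawn
    uniformly without replacement.  Per-participant latency offsets are
    drawn once per component name; trial-level jitter and amplitudes are
    independent across trials.  Deterministic for a fixed seed.
    """
    _validate_latencies(profile, config)
    rng = np.random.default_rng(participant_seed)
    n_trials = config.trials_per_participant
    times = config.times
    n_samples = config.epoch_len_samples

    labels = np.zeros(n_trials, dtype=int)
    rare_pos = rng.choice(n_trials, size=config.n_rare, replace=False)
    labels[rare_pos] = LABEL_RARE

    # one latency offset per component name, shared across stimulus types
    names = []
    for c in profile.components_frequent + profile.components_rare:
        if c.name not in names:
            names.append(c.name)
    sd_by_name = {}
    for c in profile.components_frequent + profile.components_rare:
        sd_by_name.setdefault(c.name, c.latency_sd_between)
    lat_offset = {name: rng.normal(0.0, sd_by_name[name]) for name in names}

    signal = np.zeros((n_trials, n_samples, len(CLUSTERS)))
    for rare_flag, mask in ((False, labels == LABEL_FREQUENT),
                            (True, labels == LABEL_RARE)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        pool = profile.components_rare if rare_flag else profile.components_frequent
        for comp in pool:
            ci = CLUSTERS.index(comp.cluster)
            amps = rng.normal(comp.mean_amplitude, comp.amplitude_sd, size=idx.size)
            lats = (comp.mean_latency + lat_offset[comp.name]
                    + rng.normal(0.0, comp.latency_jitter_within, size=idx.size))
            bump = amps[:, None] * np.exp(
                -((times[None, :] - lats[:, None]) ** 2) / (2.0 * comp.width ** 2))
            signal[idx, :, ci] += bump

    n_tracks = len(CLUSTERS) * config.channels_per_cluster
    noise = pink_noise(rng, n_samples, (n_trials, n_tracks), profile.noise_pink_sd)
    noise = np.swapaxes(noise, 1, 2)  # (trials, samples, tracks)
    noise += rng.normal(0.0, profile.noise_white_sd,
                        size=(n_trials, n_samples, n_tracks))

    if config.channels_per_cluster == 1:
        voltages = signal + noise
        channel_names = None
    else:
        # replicate each cluster trace into its named channels, each with
        # its own independent noise track
        voltages = np.repeat(signal, 3, axis=2) + noise
        channel_names = tuple(
            ch for cl in CLUSTERS for ch in CLUSTER_CHANNELS[cl])

    pid = participant_id or f"{profile.group}_{participant_seed}"
    epochs = EpochSet(voltages, labels, times, pid, profile.group, channel_names)
    if config.artifact_rate > 0:
        art_seed = int(rng.integers(0, 2 ** 31))
        epochs = inject_artifacts(epochs, config.artifact_rate,
                                  config.artifact_amplitude, art_seed)
    return epochs


def participant_seed(master_seed: int, index: int) -> int:
    """Stable per-participant seed: a function of (master seed, global
    participant index) only, so the order of generation cannot matter."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def simulate_dataset(young_profile: GroupProfile, older_profile: GroupProfile,
                     config: SimulationConfig) -> list[EpochSet]:
    """Simulate the full cohort: ``n_young`` young then ``n_older`` older
    participants, with per-participant seeds derived from ``config.seed``."""
    if config.n_young + config.n_older < 1:
        raise ValueError("need at least 1 participant")
    out: list[EpochSet] = []
    idx = 0
    for profile, n in ((young_profile, config.n_young),
                       (older_profile, config.n_older)):
        for j in range(n):
            out.append(simulate_participant(
                profile, config, participant_seed(config.seed, idx),
                participant_id=f"{profile.group}_{j:02d}"))
            idx += 1
    return out


def inject_artifacts(epochs: EpochSet, rate: float, amplitude: float,
                     seed: int) -> EpochSet:
    """Add a one-sample high-amplitude spike to each epoch independently
    selected with probability ``rate``.  The spike's sign follows the sign
    of the underlying sample so the epoch's absolute peak is guaranteed to
    reach ``amplitude``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if amplitude <= 100:
        raise ValueError("artifact amplitude must exceed 100 µV")
    out = epochs.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    hit = rng.random(out.n_trials) < rate
    n_samples = out.voltages.shape[1]
    n_tracks = out.voltages.shape[2]
    for i in np.flatnonzero(hit):
        s = rng.integers(n_samples)
        c = rng.integers(n_tracks)
        v = out.voltages[i, s, c]
        out.voltages[i, s, c] = v + np.copysign(amplitude, v if v != 0 else 1.0)
    return out


# ---------------------------------------------------------------------------
# serialization: long-format delimited text + JSON sidecar

def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write one participant's epochs as CSV (trial, track, time_ms,
    voltage_uv, label) plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    names = epochs.channel_names or CLUSTERS
    n_trials, n_samples, n_tracks = epochs.voltages.shape
    track_cycle = np.tile(np.arange(n_tracks), n_trials * n_samples)
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(n_trials), n_samples * n_tracks),
        "track": [names[k] for k in track_cycle],
        "time_ms": np.tile(np.repeat(epochs.times, n_tracks), n_trials),
        "voltage_uv": epochs.voltages.reshape(-1),
        "label": np.repeat(epochs.labels, n_samples * n_tracks),
    })
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "participant_id": epochs.participant_id,
        "group": epochs.group,
        "fs": epochs.fs,
        "n_trials": int(n_trials),
        "n_samples": int(n_samples),
        "tracks": list(names),
        "channel_level": epochs.channel_names is not None,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path)
    n_trials, n_samples = meta["n_trials"], meta["n_samples"]
    tracks = meta["tracks"]
    order = {name: k for k, name in enumerate(tracks)}
    df["track_i"] = df["track"].map(order)
    df = df.sort_values(["trial", "time_ms", "track_i"], kind="stable")
    voltages = df["voltage_uv"].to_numpy().reshape(n_trials, n_samples, len(tracks))
    labels = (df.groupby("trial", sort=True)["label"].first()
              .to_numpy().astype(int))
    times = np.sort(df["time_ms"].unique())
    channel_names = tuple(tracks) if meta["channel_level"] else None
    return EpochSet(voltages, labels, times, meta["participant_id"],
                    meta["group"], channel_names)
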