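"""Time-resolved feature extraction: 40 features per trial and time point.

Four features are the raw voltages of the four electrode clusters; the
remaining 36 are spectral power in dB at 9 linearly spaced frequencies
(4–36 Hz) per cluster, from a sliding 32-sample Hann-tapered DFT.  Windows
are centered (16 samples each side), so 16 samples are trimmed from each
end of the epoch; each window is zero-padded to 64 samples so that at
256 Hz the DFT bin grid (4 Hz) lines up exactly with the requested
frequencies.  Power features are absolute dB, 10·log10(power + ε) with
ε = 1e-12 µV²; no per-trial baseline correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simgen import CLUSTERS, EpochSet

POWER_EPS = 1e-12  # µV², floors the log


def frequency_grid(f_min: float = 4.0, f_max: float = 36.0, n: int = 9
                   ) -> np.ndarray:
    """Arithmetic progression of ``n`` frequencies inclusive of both ends."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not f_max > f_min:
        raise ValueError("f_max must exceed f_min")
    return np.linspace(f_min, f_max, n)


def stft_power(trace: np.ndarray, fs: float, window_len: int = 32,
               freqs: np.ndarray | None = None, *, n_fft: int | None = None,
               eps: float = POWER_EPS) -> np.ndarray:
    """Sliding-window spectral power in dB.

    For each sample with a full centered window (``window_len/2`` samples
    each side), the window is Hann-tapered, zero-padded to ``n_fft``
    (default ``2*window_len``), and the squared DFT magnitude is read at
    the DFT bin nearest each requested frequency.

    Returns an array of shape ``(n_samples - window_len, n_freqs)``
    corresponding to input samples ``window_len//2 .. n_samples -
    window_len//2 - 1``.
    """
    trace = np.asarray(trace, dtype=float)
    if window_len % 2 != 0:
        raise ValueError("window_len must be even")
    n = trace.shape[-1]
    if window_len > n:
        raise ValueError("window_len exceeds trace length")
    freqs = frequency_grid() if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs > fs / 2):
        raise ValueError(
            f"requested frequency above Nyquist ({fs / 2:g} Hz): "
            f"{freqs[freqs > fs / 2]}")
    n_fft = n_fft or 2 * window_len
    # windows centered on samples window_len//2 .. n - window_len//2 - 1
    starts = np.arange(n - window_len)
    windows = np.lib.stride_tricks.sliding_window_view(trace, window_len,
                                                       axis=-1)[..., starts, :]
    # remove each window's mean so a DC offset cannot leak through the
    # taper into the low-frequency bins
    windows = windows - windows.mean(axis=-1, keepdims=True)
    taper = np.hanning(window_len)
    spec = np.fft.rfft(windows * taper, n=n_fft, axis=-1)
    bin_width = fs / n_fft
    bins = np.rint(freqs / bin_width).astype(int)
    power = np.abs(spec[..., bins]) ** 2
    return 10.0 * np.log10(power + eps)


@dataclass
class TemporalFeatureTensor:
    """Trials × trimmed-samples × 40 feature values.

    Feature order: ``amp_<cluster>`` for the four clusters, then
    ``pow_<f>Hz_<cluster>`` cluster-major (all 9 frequencies of the
    occipital cluster, then parietal, central, frontal).
    """

    values: np.ndarray  # (n_trials, n_times, n_features)
    feature_names: tuple[str, ...]
    times: np.ndarray  # ms, trimmed
    labels: np.ndarray
    participant_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError("feature axis does not match feature_names")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("trial axis does not match labels")


def temporal_feature_names(freqs: np.ndarray | None = None) -> tuple[str, ...]:
    freqs = frequency_grid() if freqs is None else freqs
    names = [f"amp_{cl}" for cl in CLUSTERS]
    names += [f"pow_{f:g}Hz_{cl}" for cl in CLUSTERS for f in freqs]
    return tuple(names)


def build_temporal_features(epochs: EpochSet, window_len: int = 32,
                            freqs: np.ndarray | None = None
                            ) -> TemporalFeatureTensor:
    """Assemble the 4 amplitude + 36 power features for every trial.

    Amplitude features are the raw cluster voltages at the trimmed
    samples; power features come from :func:`stft_power` per cluster.
    """
    if epochs.channel_names is not None:
        raise ValueError("cluster-level EpochSet required (run cluster_average)")
    if epochs.voltages.shape[2] != len(CLUSTERS):
        raise ValueError("EpochSet must have exactly the 4 standard clusters")
    freqs = frequency_grid() if freqs is None else np.asarray(freqs, dtype=float)
    half = window_len // 2
    n_samples = epochs.voltages.shape[1]
    keep = slice(half, n_samples - half)
    amp = epochs.voltages[:, keep, :]  # (trials, trimmed, 4)
    pw = []
    for ci in range(len(CLUSTERS)):
        # (trials, trimmed, n_freqs)
        pw.append(stft_power(epochs.voltages[:, :, ci], epochs.fs,
                             window_len, freqs))
    values = np.concatenate([amp] + pw, axis=2)
    return TemporalFeatureTensor(
        values=values,
        feature_names=temporal_feature_names(freqs),
        times=epochs.times[keep],
        labels=epochs.labels.copy(),
        participant_id=epochs.participant_id,
        group=epochs.group,
    )


# ---------------------------------------------------------------------------
# serialization

def save_temporal(tensor: TemporalFeatureTensor, path: str | Path) -> None:
    """Long-format CSV (trial, time_ms, feature, value) + JSON schema."""
    path = Path(path)
    n_trials, n_times, n_feat = tensor.values.shape
    df = pd.DataFrame({
        "trial": np.repeat(np.arange(n_trials), n_times * n_feat),
        "time_ms": np.tile(np.repeat(tensor.times, n_feat), n_trials),
        "feature": list(tensor.feature_names) * (n_trials * n_times),
        "value": tensor.values.reshape(-1),
    })
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "participant_id": tensor.participant_id,
        "group": tensor.group,
        "feature_names": list(tensor.feature_names),
        "labels": tensor.labels.tolist(),
        "times": tensor.times.tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def load_temporal(path: str | Path) -> TemporalFeatureTensor:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path)
    names = meta["feature_names"]
    times = np.asarray(meta["times"], dtype=float)
    n_trials = df["trial"].nunique()
    values = df["value"].to_numpy().reshape(n_trials, len(times), len(names))
    return TemporalFeatureTensor(values, tuple(names), times,
                                 np.asarray(meta["labels"], dtype=int),
                                 meta["participant_id"], meta["group"])
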