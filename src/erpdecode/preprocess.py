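"""Epoch-level quality control and electrode-cluster averaging.

The pipeline consumes cluster-averaged traces, so averaging runs first and
the absolute-amplitude rejection criterion is applied to the cluster-level
signal the classifiers will actually see.  Both thresholds are strict
inequalities: an epoch is dropped when its absolute peak exceeds 100 µV,
and a recording is excluded when more than 25% of its epochs were dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simgen import CLUSTERS, CLUSTER_CHANNELS, EpochSet


@dataclass(frozen=True)
class RejectionReport:
    kept_indices: tuple[int, ...]
    removed_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        kept, removed = set(self.kept_indices), set(self.removed_indices)
        if kept & removed:
            raise ValueError("kept and removed indices overlap")

    @property
    def retained_fraction(self) -> float:
        total = len(self.kept_indices) + len(self.removed_indices)
        return len(self.kept_indices) / total

    def summary(self) -> str:
        return (f"kept={len(self.kept_indices)} removed={len(self.removed_indices)} "
                f"retained_fraction={self.retained_fraction:.4f} "
                f"excluded={check_exclusion(self)}")


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0
                  ) -> tuple[EpochSet, RejectionReport]:
    """Drop epochs whose absolute peak amplitude exceeds ``threshold_uv``
    (strictly) on any cluster at any sample; keep order otherwise."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be > 0")
    if epochs.n_trials == 0:
        raise ValueError("empty EpochSet")
    peak = np.abs(epochs.voltages).max(axis=(1, 2))
    removed = np.flatnonzero(peak > threshold_uv)
    kept = np.flatnonzero(peak <= threshold_uv)
    out = EpochSet(
        epochs.voltages[kept], epochs.labels[kept], epochs.times,
        epochs.participant_id, epochs.group, epochs.channel_names,
    )
    return out, RejectionReport(tuple(int(i) for i in kept),
                                tuple(int(i) for i in removed))


def check_exclusion(report: RejectionReport,
                    max_removed_fraction: float = 0.25) -> bool:
    """True iff the recording loses strictly more than
    ``max_removed_fraction`` of its epochs."""
    return (1.0 - report.retained_fraction) > max_removed_fraction


def cluster_average(channel_epochs: EpochSet,
                    cluster_map: dict[str, tuple[str, ...]] | None = None
                    ) -> EpochSet:
    """Average channel-level traces into the four cluster traces.

    ``cluster_map`` maps each cluster name to the channel names to average;
    defaults to the standard triplets (occipital = O1/Oz/O2, parietal =
    P3/Pz/P4, central = C3/Cz/C4, frontal = F3/Fz/F4).
    """
    if channel_epochs.channel_names is None:
        raise ValueError("input EpochSet is already cluster-level")
    cluster_map = cluster_map or CLUSTER_CHANNELS
    names = list(channel_epochs.channel_names)
    out = np.empty(channel_epochs.voltages.shape[:2] + (len(CLUSTERS),))
    for ci, cluster in enumerate(CLUSTERS):
        channels = cluster_map.get(cluster, ())
        if not channels:
            raise ValueError(f"cluster {cluster!r} has no channels in the map")
        try:
            cols = [names.index(ch) for ch in channels]
        except ValueError as exc:
            missing = [ch for ch in channels if ch not in names]
            raise ValueError(
                f"unknown channel(s) {missing}; valid names: {names}") from exc
        out[:, :, ci] = channel_epochs.voltages[:, :, cols].mean(axis=2)
    return EpochSet(out, channel_epochs.labels, channel_epochs.times,
                    channel_epochs.participant_id, channel_epochs.group, None)
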