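"""Mutual-information feature ranking and the top-8 selection rules.

MI between each continuous feature and the binary stimulus label is
estimated with a nearest-neighbour continuous–discrete estimator
(Kozachenko–Leonenko style, k = 3 neighbours), pooled over trials of all
participants.  For the temporal tensor the per-feature score is the mean
MI across time points and the best eight features are kept.  For the ERP
table the two amplitude measures are ranked against each other and the
two latency measures against each other by MI summed across components;
the winning measure of each kind is kept for all four components,
yielding eight features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import mutual_info_classif

from .features_erp import COMPONENT_ORDER, ERPFeatureTable
from .features_temporal import TemporalFeatureTensor

MI_NEIGHBORS = 3


@dataclass
class FeatureRanking:
    feature_names: tuple[str, ...]
    mi_scores: np.ndarray  # nats, >= 0
    selected: np.ndarray  # boolean mask

    def __post_init__(self) -> None:
        if np.any(self.mi_scores < 0):
            raise ValueError("MI scores must be non-negative")

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(n for n, s in zip(self.feature_names, self.selected) if s)

    def to_rows(self) -> list[tuple[str, float, bool]]:
        return [(n, float(s), bool(m)) for n, s, m in
                zip(self.feature_names, self.mi_scores, self.selected)]


def mutual_information(feature_values: np.ndarray, labels: np.ndarray,
                       n_neighbors: int = MI_NEIGHBORS,
                       random_state: int = 0) -> float:
    """MI (nats) between one continuous feature and the binary label,
    clipped at zero.  A constant feature carries no information."""
    x = np.asarray(feature_values, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    if min(np.bincount(y.astype(int), minlength=2)) < 2:
        raise ValueError("need at least 2 trials per class")
    if np.all(x == x[0]):
        return 0.0
    mi = mutual_info_classif(x, y, discrete_features=False,
                             n_neighbors=n_neighbors,
                             random_state=random_state)[0]
    return float(max(mi, 0.0))


def select_temporal(tensor: TemporalFeatureTensor, k: int = 8,
                    n_neighbors: int = MI_NEIGHBORS,
                    random_state: int = 0) -> FeatureRanking:
    """Top-``k`` temporal features by mean-over-time MI with the label.

    Ties are broken by the fixed feature order (amplitudes first, then
    powers cluster-major).
    """
    n_feat = tensor.values.shape[2]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds the {n_feat} available features")
    labels = tensor.labels
    scores = np.zeros(n_feat)
    for f in range(n_feat):
        per_time = [mutual_information(tensor.values[:, t, f], labels,
                                       n_neighbors, random_state)
                    for t in range(tensor.values.shape[1])]
        scores[f] = float(np.mean(per_time))
    order = np.argsort(-scores, kind="stable")  # stable: ties keep order
    selected = np.zeros(n_feat, dtype=bool)
    selected[order[:k]] = True
    return FeatureRanking(tensor.feature_names, scores, selected)


def select_erp(table: ERPFeatureTable, n_neighbors: int = MI_NEIGHBORS,
               random_state: int = 0) -> FeatureRanking:
    """Keep the better amplitude measure and the better latency measure.

    The two amplitude measures (peak vs. mean) and the two latency
    measures (peak vs. fractional 50%) are each compared by MI summed
    across the four components; the winners are retained for all
    components (8 features).  Ties prefer peak_amplitude and the
    fractional 50% latency.
    """
    if len(table.columns) != 16:
        raise ValueError("expected the 16-column component-measure table")
    labels = table.labels
    col = {name: i for i, name in enumerate(table.columns)}
    scores = np.array([
        mutual_information(table.values[:, i], labels, n_neighbors, random_state)
        for i in range(16)])

    def family_score(measure: str) -> float:
        return sum(scores[col[f"{c}_{measure}"]] for c in COMPONENT_ORDER)

    amp_winner = ("peak_amplitude"
                  if family_score("peak_amplitude") >= family_score("mean_amplitude")
                  else "mean_amplitude")
    lat_winner = ("fractional_peak_latency_50"
                  if family_score("fractional_peak_latency_50") >= family_score("peak_latency")
                  else "peak_latency")
    selected = np.zeros(16, dtype=bool)
    for c in COMPONENT_ORDER:
        selected[col[f"{c}_{amp_winner}"]] = True
        selected[col[f"{c}_{lat_winner}"]] = True
    return FeatureRanking(table.columns, scores, selected)


def save_ranking(ranking: FeatureRanking, path) -> None:
    lines = ["feature,mi_nats,selected"]
    lines += [f"{n},{s:.9g},{int(m)}" for n, s, m in ranking.to_rows()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
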