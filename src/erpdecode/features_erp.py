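"""Time-independent statistical ERP features.

Each of four components (P1, N170, P2 on the occipital cluster; P3 on the
central cluster) is parameterized per trial by four measures inside a
fixed window: peak amplitude, mean amplitude, peak latency, and the
fractional 50% peak latency — the leading-edge time at which the waveform
first reaches half its peak, found by searching backward from the peak
with linear interpolation between the straddling samples.

Measures for the negative N170 are computed on the negated trace
(polarity alignment) with the sign restored for amplitude reporting;
latencies are unaffected.  Window endpoints are inclusive: the samples
nearest each endpoint bound the scanned range.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simgen import CLUSTERS, EpochSet

COMPONENT_ORDER = ("P1", "N170", "P2", "P3")
MEASURES = ("peak_amplitude", "mean_amplitude", "peak_latency",
            "fractional_peak_latency_50")


@dataclass(frozen=True)
class ComponentWindow:
    component: str
    cluster: str
    t_start: float  # ms
    t_end: float  # ms
    polarity: int

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


def default_windows() -> tuple[ComponentWindow, ...]:
    """The fixed measurement windows: P1 50–150 ms, N170 100–200 ms,
    P2 200–325 ms (occipital); P3 250–500 ms (central)."""
    return (
        ComponentWindow("P1", "occipital", 50.0, 150.0, 1),
        ComponentWindow("N170", "occipital", 100.0, 200.0, -1),
        ComponentWindow("P2", "occipital", 200.0, 325.0, 1),
        ComponentWindow("P3", "central", 250.0, 500.0, 1),
    )


def _window_indices(times: np.ndarray, window: ComponentWindow) -> np.ndarray:
    if window.t_end < times[0] or window.t_start > times[-1]:
        raise ValueError(
            f"window [{window.t_start}, {window.t_end}] ms lies entirely "
            f"outside the trace ({times[0]:.1f}..{times[-1]:.1f} ms)")
    i0 = int(np.argmin(np.abs(times - window.t_start)))
    i1 = int(np.argmin(np.abs(times - window.t_end)))
    return np.arange(i0, i1 + 1)


def peak_amplitude(trace: np.ndarray, times: np.ndarray,
                   window: ComponentWindow) -> float:
    """Signed extremum in the window: maximum for positive polarity,
    minimum for negative."""
    idx = _window_indices(times, window)
    seg = np.asarray(trace)[idx] * window.polarity
    return float(seg.max() * window.polarity)


def mean_amplitude(trace: np.ndarray, times: np.ndarray,
                   window: ComponentWindow) -> float:
    idx = _window_indices(times, window)
    return float(np.asarray(trace)[idx].mean())


def peak_latency(trace: np.ndarray, times: np.ndarray,
                 window: ComponentWindow) -> float:
    """Time of the polarity-aligned extremum; ties go to the earliest
    sample."""
    idx = _window_indices(times, window)
    seg = np.asarray(trace)[idx] * window.polarity
    return float(times[idx[int(np.argmax(seg))]])


def fractional_peak_latency(trace: np.ndarray, times: np.ndarray,
                            window: ComponentWindow,
                            fraction: float = 0.5) -> float:
    """Leading-edge fractional latency.

    Searching backward from the peak toward the window start, find the
    first sample whose polarity-aligned value falls below ``fraction``
    times the aligned peak, and linearly interpolate the crossing time.
    If the trace never falls below the threshold inside the window, the
    window start time is returned.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    idx = _window_indices(times, window)
    seg = np.asarray(trace)[idx] * window.polarity
    t = times[idx]
    p = int(np.argmax(seg))
    thresh = fraction * seg[p]
    if seg[p] < thresh:
        # aligned peak is negative: the trace never rises to the
        # threshold, so the peak time is the best-defined onset
        return float(t[p])
    below = np.flatnonzero(seg[:p] < thresh)
    if below.size == 0:
        return float(window.t_start)
    j = int(below[-1])  # last sample below threshold before the peak
    # crossing between samples j and j+1
    v0, v1 = seg[j], seg[j + 1]
    frac = (thresh - v0) / (v1 - v0)
    return float(t[j] + frac * (t[j + 1] - t[j]))


def collapsed_localizer_windows(grand_average: np.ndarray, times: np.ndarray
                                ) -> tuple[ComponentWindow, ...]:
    """Diagnostic windows from the collapsed (all trials, all groups,
    both stimulus types) grand average.

    For each component, candidate intervals are bounded by consecutive
    zero-crossings of its cluster's grand-average trace; the interval
    containing the absolute-maximum sample within the default window's
    ±50 ms neighborhood is intersected with that neighborhood.  If a
    relevant cluster trace never crosses zero, the fixed default windows
    are returned with a warning.  The pipeline default remains the fixed
    windows; these are diagnostics.
    """
    grand_average = np.asarray(grand_average, dtype=float)
    defaults = default_windows()
    out = []
    for win in defaults:
        trace = grand_average[:, CLUSTERS.index(win.cluster)]
        cross = np.flatnonzero(np.signbit(trace[:-1]) != np.signbit(trace[1:]))
        if cross.size == 0:
            warnings.warn("grand-average trace has no zero-crossings; "
                          "falling back to the default windows")
            return defaults
        cross_t = times[cross]  # crossing between sample i and i+1
        lo, hi = win.t_start - 50.0, win.t_end + 50.0
        # locate the component by the absolute extremum inside its default
        # window (sign-agnostic, so boundaries are sign-flip invariant)
        inwin = (times >= win.t_start) & (times <= win.t_end)
        peak_t = times[inwin][int(np.argmax(np.abs(trace[inwin])))]
        left = cross_t[cross_t < peak_t]
        right = cross_t[cross_t >= peak_t]
        a = float(left[-1]) if left.size else float(times[0])
        b = float(right[0]) if right.size else float(times[-1])
        out.append(ComponentWindow(win.component, win.cluster,
                                   max(a, lo), min(b, hi), win.polarity))
    return tuple(out)


@dataclass
class ERPFeatureTable:
    """Trials × 16 component-measure matrix.

    Column order: for each component in (P1, N170, P2, P3), the four
    measures (peak_amplitude, mean_amplitude, peak_latency,
    fractional_peak_latency_50).
    """

    values: np.ndarray  # (n_trials, 16)
    columns: tuple[str, ...]
    labels: np.ndarray
    participant_id: str = ""
    group: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df["label"] = self.labels
        return df


def erp_feature_columns() -> tuple[str, ...]:
    return tuple(f"{c}_{m}" for c in COMPONENT_ORDER for m in MEASURES)


def build_erp_features(epochs: EpochSet,
                       windows: tuple[ComponentWindow, ...] | None = None
                       ) -> ERPFeatureTable:
    """Parameterize every single trial with the 4 components × 4 measures."""
    if epochs.channel_names is not None:
        raise ValueError("cluster-level EpochSet required (run cluster_average)")
    windows = windows or default_windows()
    by_name = {w.component: w for w in windows}
    values = np.empty((epochs.n_trials, 4 * len(MEASURES)))
    for k, comp in enumerate(COMPONENT_ORDER):
        win = by_name[comp]
        ci = CLUSTERS.index(win.cluster)
        for i in range(epochs.n_trials):
            trace = epochs.voltages[i, :, ci]
            values[i, 4 * k + 0] = peak_amplitude(trace, epochs.times, win)
            values[i, 4 * k + 1] = mean_amplitude(trace, epochs.times, win)
            values[i, 4 * k + 2] = peak_latency(trace, epochs.times, win)
            values[i, 4 * k + 3] = fractional_peak_latency(trace, epochs.times, win)
    return ERPFeatureTable(values, erp_feature_columns(), epochs.labels.copy(),
                           epochs.participant_id, epochs.group)


def save_erp(table: ERPFeatureTable, path: str | Path) -> None:
    """Delimited text with header, one row per trial, label column last."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.9g")
    meta = {"participant_id": table.participant_id, "group": table.group}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def load_erp(path: str | Path) -> ERPFeatureTable:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    labels = df.pop("label").to_numpy().astype(int)
    return ERPFeatureTable(df.to_numpy(dtype=float), tuple(df.columns), labels,
                           meta["participant_id"], meta["group"])
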