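"""Classifier-comparison and age-group statistics.

Classifiers are compared on per-participant AUROC scores with the
Friedman rank test; post-hoc pairwise Wilcoxon signed-rank tests are
Holm-corrected.  The Nemenyi critical distance — the minimum mean-rank
gap deemed significant — comes from the studentized-range quantile:

    CD = q_alpha(k) / sqrt(2) * sqrt(k (k + 1) / (6 N))

The critical-difference diagram groups classifiers whose pairwise
differences are non-significant; its two-dimensional time-resolved
extension repeats the Friedman + post-hoc machinery at every time point,
clustering classifiers with a set of representatives (no marker at a
time point = the Friedman test itself was non-significant there).

Age-group comparisons use one-way ANOVA across group×dataset cells
followed by pairwise equal-variance two-sided t-tests, with no
across-time correction for the per-time-point group tests (matching the
analysis being reproduced, not endorsed as optimal practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TABULATED_ALPHAS = (0.01, 0.05, 0.10)


# ---------------------------------------------------------------------------
# Friedman test

def friedman(scores: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test on an N (participants) × k (classifiers)
    score matrix, with average ranks for ties and the standard tie
    correction.  Returns (statistic, p).  A matrix of fully tied rows
    yields (0, 1)."""
    M = np.asarray(scores, dtype=float)
    n, k = M.shape
    if n < 2 or k < 3:
        raise ValueError("need N >= 2 participants and k >= 3 classifiers")
    ranks = np.apply_along_axis(sps.rankdata, 1, M)
    rsum = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rsum ** 2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in M:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - tie_term / (n * k * (k ** 2 - 1))
    if denom <= 0:
        return 0.0, 1.0
    stat /= denom
    p = float(sps.chi2.sf(stat, k - 1))
    return float(stat), p


def pairwise_wilcoxon_holm(scores: pd.DataFrame, alpha: float = 0.05
                           ) -> dict[tuple[str, str], float]:
    """Wilcoxon signed-rank test per classifier pair, Holm-adjusted over
    all k(k−1)/2 pairs.  A pair with all-zero differences records p = 1."""
    cols = list(scores.columns)
    pairs, raw = [], []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = scores[cols[i]].to_numpy(dtype=float)
            b = scores[cols[j]].to_numpy(dtype=float)
            if np.all(a == b):
                p = 1.0
            else:
                p = float(sps.wilcoxon(a, b, zero_method="wilcox").pvalue)
            pairs.append((cols[i], cols[j]))
            raw.append(p)
    adj = multipletests(raw, alpha=alpha, method="holm")[1]
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical distance for k methods over n subjects.

    ``q_alpha`` is the studentized-range quantile (infinite d.o.f.)
    divided by sqrt(2).  Only the conventional tabulated alphas are
    supported.
    """
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 and n >= 1")
    if not any(np.isclose(alpha, a) for a in TABULATED_ALPHAS):
        raise ValueError(f"alpha {alpha} not tabulated; "
                         f"supported: {TABULATED_ALPHAS}")
    q = sps.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


# ---------------------------------------------------------------------------
# critical-difference diagram

@dataclass
class ComparisonResult:
    classifiers: tuple[str, ...]
    mean_ranks: np.ndarray  # rank 1 = best (highest score)
    friedman_stat: float
    friedman_p: float
    pairwise_p: dict[tuple[str, str], float]  # Holm-adjusted
    cd_value: float
    alpha: float

    def pair_p(self, a: str, b: str) -> float:
        return self.pairwise_p.get((a, b), self.pairwise_p.get((b, a), 1.0))


def compare_classifiers(scores: pd.DataFrame, alpha: float = 0.05
                        ) -> ComparisonResult:
    """Full static comparison on a participants × classifiers score frame.
    Higher scores rank better (mean rank 1 = best)."""
    M = scores.to_numpy(dtype=float)
    n, k = M.shape
    stat, p = friedman(M)
    ranks = np.apply_along_axis(sps.rankdata, 1, -M)  # rank 1 = highest score
    pw = pairwise_wilcoxon_holm(scores, alpha=alpha)
    return ComparisonResult(
        classifiers=tuple(scores.columns),
        mean_ranks=ranks.mean(axis=0),
        friedman_stat=stat, friedman_p=p, pairwise_p=pw,
        cd_value=nemenyi_cd(k, n, alpha), alpha=alpha,
    )


def cd_diagram(comparison: ComparisonResult) -> dict:
    """Plot-ready structure: classifiers sorted by mean rank and the
    maximal groups of mutually non-different classifiers (bars)."""
    order = np.argsort(comparison.mean_ranks, kind="stable")
    names = [comparison.classifiers[i] for i in order]
    ranks = [float(comparison.mean_ranks[i]) for i in order]
    k = len(names)

    def clique_ok(i: int, j: int) -> bool:
        return all(comparison.pair_p(names[a], names[b]) > comparison.alpha
                   for a in range(i, j + 1) for b in range(a + 1, j + 1))

    groups: list[tuple[str, ...]] = []
    for i in range(k):
        j = i
        while j + 1 < k and clique_ok(i, j + 1):
            j += 1
        g = tuple(names[i:j + 1])
        if not any(set(g) <= set(prev) for prev in groups):
            groups.append(g)
    return {"order": names, "mean_ranks": ranks,
            "cd_value": comparison.cd_value, "groups": groups}


@dataclass
class TimeResolvedComparison:
    """Per-time-point comparison (the 2D CD-diagram extension)."""

    times: np.ndarray
    classifiers: tuple[str, ...]
    mean_ranks: pd.DataFrame  # time × classifier
    friedman_p: np.ndarray  # per time point
    #: representative -> (time × classifier) boolean membership; all False
    #: at times where the Friedman test is non-significant
    clusters: dict[str, pd.DataFrame]


DEFAULT_REPRESENTATIVES = ("lda", "rf", "xgb", "knn")


def cd_over_time(score_matrices: list[pd.DataFrame], times: np.ndarray,
                 representatives: tuple[str, ...] = DEFAULT_REPRESENTATIVES,
                 alpha: float = 0.05) -> TimeResolvedComparison:
    """Friedman + Holm-corrected post-hoc Wilcoxon at every time point.

    A classifier joins a representative's cluster at time t iff the
    Friedman test at t is significant AND the pair's adjusted p exceeds
    alpha (statistically indistinguishable).  No marker at t means the
    Friedman test was non-significant there.
    """
    cols = tuple(score_matrices[0].columns)
    for m in score_matrices:
        if tuple(m.columns) != cols:
            raise ValueError("all time points must share the same classifiers")
    missing = [r for r in representatives if r not in cols]
    if missing:
        raise ValueError(f"representatives not in score matrix: {missing}")
    T = len(score_matrices)
    ranks = np.zeros((T, len(cols)))
    fried_p = np.ones(T)
    member = {r: np.zeros((T, len(cols)), dtype=bool) for r in representatives}
    for t, M in enumerate(score_matrices):
        arr = M.to_numpy(dtype=float)
        _, fried_p[t] = friedman(arr)
        ranks[t] = np.apply_along_axis(sps.rankdata, 1, -arr).mean(axis=0)
        if fried_p[t] <= alpha:
            pw = pairwise_wilcoxon_holm(M, alpha=alpha)

            def pair_p(a: str, b: str) -> float:
                return pw.get((a, b), pw.get((b, a), 1.0))

            for r in representatives:
                for j, c in enumerate(cols):
                    if c == r:
                        member[r][t, j] = True
                    else:
                        member[r][t, j] = pair_p(c, r) > alpha
    return TimeResolvedComparison(
        times=np.asarray(times, dtype=float), classifiers=cols,
        mean_ranks=pd.DataFrame(ranks, columns=list(cols)),
        friedman_p=fried_p,
        clusters={r: pd.DataFrame(member[r], columns=list(cols))
                  for r in representatives},
    )


# ---------------------------------------------------------------------------
# age-group comparisons

@dataclass
class AgeComparison:
    anova_p: float
    cell_stats: pd.DataFrame  # cell, n, mean, sd (3 decimals)
    pairwise_p: dict[tuple[str, str], float]
    pairwise_t: dict[tuple[str, str], float]


def age_compare(scores: pd.DataFrame, equal_var: bool = True) -> AgeComparison:
    """One-way ANOVA across group×dataset cells followed by pairwise
    independent two-sample t-tests (two-sided).

    ``scores`` needs columns ``value`` and ``group``; an optional
    ``dataset`` column splits cells further (otherwise a single dataset
    is assumed).  Cell means and SDs are reported to 3 decimals.
    """
    df = scores.copy()
    if "dataset" not in df.columns:
        df["dataset"] = "all"
    df["cell"] = df["dataset"].astype(str) + "/" + df["group"].astype(str)
    cells = list(dict.fromkeys(df["cell"]))
    groups = [df.loc[df["cell"] == c, "value"].to_numpy(dtype=float)
              for c in cells]
    for c, g in zip(cells, groups):
        if len(g) < 2:
            raise ValueError(f"cell {c!r} has fewer than 2 participants")
    anova_p = float(sps.f_oneway(*groups).pvalue) if len(cells) > 1 else 1.0
    stats_rows = [{"cell": c, "n": len(g),
                   "mean": round(float(np.mean(g)), 3),
                   "sd": round(float(np.std(g, ddof=1)), 3)}
                  for c, g in zip(cells, groups)]
    pw_p, pw_t = {}, {}
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            t, p = sps.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            pw_p[(cells[i], cells[j])] = float(p)
            pw_t[(cells[i], cells[j])] = float(t)
    return AgeComparison(anova_p=anova_p, cell_stats=pd.DataFrame(stats_rows),
                         pairwise_p=pw_p, pairwise_t=pw_t)


def max_auroc_per_participant(timecourse: pd.DataFrame,
                              post_stimulus_only: bool = False) -> pd.DataFrame:
    """Per participant (and classifier), the maximum over time of the
    fold-mean AUROC.  ``timecourse`` is the long record frame from
    ``decode_timecourse`` (columns participant, group, classifier,
    time_ms, fold, auroc)."""
    df = timecourse
    if post_stimulus_only:
        df = df[df["time_ms"] >= 0]
    per_time = (df.groupby(["participant", "group", "classifier", "time_ms"],
                           sort=False)["auroc"].mean().reset_index())
    return (per_time.groupby(["participant", "group", "classifier"],
                             sort=False)["auroc"].max().reset_index()
            .rename(columns={"auroc": "max_auroc"}))


def significant_intervals(times: np.ndarray, pvalues: np.ndarray,
                          alpha: float = 0.01) -> list[tuple[float, float]]:
    """Maximal contiguous runs of p < alpha, as (t_start, t_end) in ms."""
    times = np.asarray(times, dtype=float)
    sig = np.asarray(pvalues, dtype=float) < alpha
    out = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            out.append((float(times[start]), float(times[i - 1])))
            start = None
    if start is not None:
        out.append((float(times[start]), float(times[-1])))
    return out
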