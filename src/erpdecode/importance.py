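"""Permutation-based feature importance.

For a fitted model and a (scaled, imbalanced) test split, each feature
column is shuffled ``n_repeats`` times while the others stay fixed; the
importance is the baseline AUROC minus the mean permuted AUROC.
Negative values are possible and mean the shuffle helped by chance.

Profiles aggregate per-feature importances over CV folds within a
participant and then average participants unweighted within each age
group — per time point for the temporal dataset, once for the
statistical dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoding import (ClassifierSpec, _scores_from, auroc, derive_seed,
                       evaluate_fold, minmax_scale_apply, stratified_kfold)


def permutation_importance(model, test_features: np.ndarray,
                           test_labels: np.ndarray, n_repeats: int = 10,
                           seed: int = 0) -> tuple[float, np.ndarray]:
    """(baseline AUROC, per-feature mean AUROC drop) on a test split."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(test_features, dtype=float)
    y = np.asarray(test_labels).astype(int)
    rng = np.random.default_rng(seed)
    baseline = auroc(_scores_from(model, X), y)
    n_feat = X.shape[1]
    drops = np.zeros(n_feat)
    for f in range(n_feat):
        perm_scores = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            perm_scores.append(auroc(_scores_from(model, Xp), y))
        drops[f] = baseline - float(np.mean(perm_scores))
    return baseline, drops


def _fold_importances(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                      seed: int, k: int, n_repeats: int) -> np.ndarray:
    """Per-feature importance averaged over CV folds for one participant
    and one (static or single-time-point) feature matrix."""
    plan = stratified_kfold(y, k=k, seed=derive_seed(seed, 1000))
    per_fold = []
    for fold_i, (tr, te) in enumerate(plan.folds):
        fold_seed = derive_seed(seed, fold_i)
        res = evaluate_fold(spec, X[tr], y[tr], X[te], y[te], seed=fold_seed,
                            fold=fold_i, return_model=True)
        if res is None:
            continue
        _, model, scaler = res
        Xt = minmax_scale_apply(scaler, X[te])
        _, drops = permutation_importance(model, Xt, y[te], n_repeats,
                                          seed=derive_seed(fold_seed, 2))
        per_fold.append(drops)
    return np.mean(per_fold, axis=0)


def importance_profile(participants: list[dict],
                       specs: tuple[ClassifierSpec, ...],
                       seed: int, k: int = 10, n_repeats: int = 10
                       ) -> pd.DataFrame:
    """Group-averaged permutation importances.

    ``participants`` is a list of dicts with keys ``values`` (either
    (trials, features) for the statistical dataset or (trials, time,
    features) for the temporal one), ``labels``, ``feature_names``,
    ``group``, and ``index`` (global participant index used for seed
    derivation).  Returns a long frame (classifier, group, feature,
    time_ms, importance) where time_ms is NaN for static input;
    participant-level importances are averaged unweighted within group.
    """
    rows = []
    for part in participants:
        X = np.asarray(part["values"], dtype=float)
        y = np.asarray(part["labels"]).astype(int)
        names = list(part["feature_names"])
        pseed = derive_seed(seed, part["index"])
        for spec in specs:
            if X.ndim == 2:
                imp = _fold_importances(X, y, spec, pseed, k, n_repeats)
                for f, name in enumerate(names):
                    rows.append({"classifier": spec.name,
                                 "group": part["group"], "feature": name,
                                 "time_ms": np.nan,
                                 "importance": float(imp[f])})
            else:
                times = np.asarray(part["times"], dtype=float)
                for t in range(X.shape[1]):
                    imp = _fold_importances(X[:, t, :], y, spec,
                                            derive_seed(pseed, t), k,
                                            n_repeats)
                    for f, name in enumerate(names):
                        rows.append({"classifier": spec.name,
                                     "group": part["group"], "feature": name,
                                     "time_ms": float(times[t]),
                                     "importance": float(imp[f])})
    df = pd.DataFrame(rows)
    return (df.groupby(["classifier", "group", "feature", "time_ms"],
                       sort=False, dropna=False)["importance"]
            .mean().reset_index())
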