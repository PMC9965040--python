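"""Per-participant imbalanced-aware classification of stimulus type.

Protocol, in order, inside every fold of a stratified 10-fold CV:

1. balance the training split — the majority (frequent) class is randomly
   undersampled to the floor of the mean of the two class sizes, and the
   minority (rare) class is oversampled to the same size with
   SMOTE-style interpolation between minority nearest neighbours
   (neighbours found in the raw feature space);
2. shuffle the balanced training set;
3. fit min-max scaling on the balanced training set and apply it to both
   the training and the untouched, still-imbalanced test split;
4. fit the classifier and evaluate accuracy, precision, recall, F1 and
   AUROC on the test split with rare as the positive class.  AUROC uses
   continuous scores (decision function where available, otherwise the
   positive-class probability) via the rank-based Mann–Whitney identity.

The nine classifiers span three linear models (LDA, logistic regression,
linear-kernel SVC), three non-linear (RBF SVC, 3-NN, decision tree) and
three ensembles (random forest, AdaBoost, XGBoost; 100 estimators, max
depth 4).  For the temporal dataset the whole protocol is repeated
independently at every trimmed time point on the 8 selected features'
values at that time point; for the ERP statistical dataset it runs once.

Randomness: every (participant, time point, fold) context derives its own
seed from the master seed through ``derive_seed``, a SeedSequence-based
counter scheme, so results are reproducible and independent of execution
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .simgen import LABEL_RARE

CLASSIFIER_NAMES = ("lda", "logreg", "svc_lin", "svc_rbf", "knn", "tree",
                    "rf", "adaboost", "xgb")


def derive_seed(*keys: int) -> int:
    """Deterministic child seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(tuple(int(k) for k in keys))
               .generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; valid: {CLASSIFIER_NAMES}")

    def build(self, seed: int = 0):
        p = dict(self.params)
        if self.name == "lda":
            return LinearDiscriminantAnalysis(**p)
        if self.name == "logreg":
            p.setdefault("max_iter", 1000)
            return LogisticRegression(**p)
        if self.name == "svc_lin":
            return SVC(kernel="linear", random_state=seed, **p)
        if self.name == "svc_rbf":
            return SVC(kernel="rbf", probability=False, random_state=seed, **p)
        if self.name == "knn":
            p.setdefault("n_neighbors", 3)
            return KNeighborsClassifier(**p)
        if self.name == "tree":
            return DecisionTreeClassifier(random_state=seed, **p)
        if self.name == "rf":
            p.setdefault("n_estimators", 100)
            p.setdefault("max_depth", 4)
            return RandomForestClassifier(random_state=seed, **p)
        if self.name == "adaboost":
            p.setdefault("n_estimators", 100)
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=4),
                random_state=seed, **p)
        if self.name == "xgb":
            p.setdefault("n_estimators", 100)
            p.setdefault("max_depth", 4)
            return XGBClassifier(random_state=seed, eval_metric="logloss",
                                 verbosity=0, **p)
        raise AssertionError(self.name)


def default_classifier_specs(names=CLASSIFIER_NAMES) -> tuple[ClassifierSpec, ...]:
    return tuple(ClassifierSpec(n) for n in names)


# ---------------------------------------------------------------------------
# cross-validation plan

@dataclass
class FoldPlan:
    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    seed: int


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition: each fold's rare count differs by at
    most one across folds."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members "
                         f"than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in
             skf.split(np.zeros((len(labels), 1)), labels)]
    return FoldPlan(k=k, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# class balancing (undersample majority + SMOTE-oversample minority)

def _smote_points(minority: np.ndarray, n_new: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Interpolated synthetic minority points: x + u·(z − x) with z one of
    x's min(5, n−1) nearest minority neighbours and u ~ U(0, 1)."""
    n = minority.shape[0]
    if n < 2:
        raise ValueError("minority class needs at least 2 points for SMOTE")
    n_nb = min(5, n - 1)
    d = np.linalg.norm(minority[:, None, :] - minority[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nb_idx = np.argsort(d, axis=1)[:, :n_nb]
    base = rng.integers(n, size=n_new)
    pick = rng.integers(n_nb, size=n_new)
    x = minority[base]
    z = minority[nb_idx[base, pick]]
    u = rng.random(n_new)[:, None]
    return x + u * (z - x)


def balance_training(train_features: np.ndarray, train_labels: np.ndarray,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equalize training classes at floor of the mean class size.

    The majority class is undersampled without replacement; the minority
    class keeps its originals (subsampled if it already exceeds the
    target) and is topped up with SMOTE-interpolated points.  The result
    is shuffled.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    rng = np.random.default_rng(seed)
    n1 = int((y == LABEL_RARE).sum())
    n0 = int((y != LABEL_RARE).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present in the training split")
    minority_label = LABEL_RARE if n1 <= n0 else 1 - LABEL_RARE
    majority_label = 1 - minority_label
    target = (n0 + n1) // 2
    maj = np.flatnonzero(y == majority_label)
    mino = np.flatnonzero(y == minority_label)
    maj_keep = rng.choice(maj, size=min(target, maj.size), replace=False)
    X_min = X[mino]
    if mino.size >= target:
        keep = rng.choice(mino, size=target, replace=False)
        X_min_out = X[keep]
    else:
        synth = _smote_points(X_min, target - mino.size, rng)
        X_min_out = np.vstack([X_min, synth])
    X_out = np.vstack([X[maj_keep], X_min_out])
    y_out = np.concatenate([np.full(maj_keep.size, majority_label),
                            np.full(X_min_out.shape[0], minority_label)])
    perm = rng.permutation(X_out.shape[0])
    return X_out[perm], y_out[perm]


# ---------------------------------------------------------------------------
# min-max scaling fitted on training data only

@dataclass(frozen=True)
class MinMaxScaler:
    min_: np.ndarray
    range_: np.ndarray  # zero-range features map to 0


def minmax_scale_fit(train_features: np.ndarray) -> MinMaxScaler:
    X = np.asarray(train_features, dtype=float)
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    return MinMaxScaler(min_=lo, range_=np.where(rng_ == 0, 1.0, rng_))


def minmax_scale_apply(scaler: MinMaxScaler, features: np.ndarray) -> np.ndarray:
    """(x − min_train) / (max_train − min_train); values outside the
    training range are not clipped."""
    return (np.asarray(features, dtype=float) - scaler.min_) / scaler.range_


# ---------------------------------------------------------------------------
# metrics

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC: P(score_rare > score_frequent) + ½ P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == LABEL_RARE).sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUROC needs both classes in the test set")
    r = rankdata(scores)
    return float((r[y == LABEL_RARE].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


@dataclass
class MetricRecord:
    classifier: str
    fold: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    time_index: int | None = None


def _scores_from(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def evaluate_fold(spec: ClassifierSpec, train_X, train_y, test_X, test_y,
                  seed: int = 0, time_index: int | None = None,
                  fold: int = 0, return_model: bool = False):
    """Run the full in-fold protocol (balance, shuffle, scale, fit,
    evaluate on the imbalanced test split)."""
    test_y = np.asarray(test_y).astype(int)
    if len(np.unique(test_y)) < 2:
        warnings.warn(f"fold {fold}: single-class test split, record skipped")
        return None
    Xb, yb = balance_training(train_X, train_y, seed=derive_seed(seed, 0))
    scaler = minmax_scale_fit(Xb)
    Xb_s = minmax_scale_apply(scaler, Xb)
    Xt_s = minmax_scale_apply(scaler, np.asarray(test_X, dtype=float))
    if np.all(Xb_s == Xb_s[0]):
        # degenerate training split (every feature constant): no classifier
        # can discriminate, so emit the majority-class chance-level record
        if return_model:
            return None  # nothing to permute or retain
        pred = np.full(len(test_y), 1 - LABEL_RARE)
        return MetricRecord(
            classifier=spec.name, fold=fold,
            accuracy=float((pred == test_y).mean()),
            precision=0.0, recall=0.0, f1=0.0,
            auroc=0.5, time_index=time_index,
        )
    model = spec.build(seed=derive_seed(seed, 1))
    try:
        model.fit(Xb_s, yb)
        pred = model.predict(Xt_s)
        s = _scores_from(model, Xt_s)
    except Exception as exc:  # noqa: BLE001 - surface context
        raise RuntimeError(
            f"classifier {spec.name!r} failed on fold {fold}: {exc}") from exc
    pred = np.asarray(pred).astype(int)
    tp = int(((pred == LABEL_RARE) & (test_y == LABEL_RARE)).sum())
    fp = int(((pred == LABEL_RARE) & (test_y != LABEL_RARE)).sum())
    fn = int(((pred != LABEL_RARE) & (test_y == LABEL_RARE)).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    rec = MetricRecord(
        classifier=spec.name, fold=fold,
        accuracy=float((pred == test_y).mean()),
        precision=precision, recall=recall, f1=f1,
        auroc=auroc(s, test_y), time_index=time_index,
    )
    if return_model:
        return rec, model, scaler
    return rec


# ---------------------------------------------------------------------------
# participant-level decoding

@dataclass
class DecodingResult:
    """Long-form per-fold metric records for one or many participants."""

    records: pd.DataFrame  # participant, group, classifier, time_ms, fold, metrics

    def participant_scores(self, metric: str = "auroc") -> pd.DataFrame:
        """Fold-mean metric per participant × classifier (× time if present)."""
        keys = ["participant", "group", "classifier"]
        if self.records["time_ms"].notna().any():
            keys.append("time_ms")
        return (self.records.groupby(keys, sort=False)[metric]
                .mean().reset_index())

    def to_long(self) -> pd.DataFrame:
        return self.records.melt(
            id_vars=["participant", "group", "classifier", "time_ms", "fold"],
            value_vars=["accuracy", "precision", "recall", "f1", "auroc"],
            var_name="metric", value_name="value")

    @staticmethod
    def concat(results: list["DecodingResult"]) -> "DecodingResult":
        return DecodingResult(pd.concat([r.records for r in results],
                                        ignore_index=True))


def _decode_once(X: np.ndarray, y: np.ndarray,
                 specs: tuple[ClassifierSpec, ...], seed: int, k: int = 10,
                 time_index: int | None = None,
                 time_ms: float = np.nan,
                 participant: str = "", group: str = "") -> list[dict]:
    plan = stratified_kfold(y, k=k, seed=derive_seed(seed, 1000))
    rows = []
    for fold_i, (tr, te) in enumerate(plan.folds):
        fold_seed = derive_seed(seed, fold_i)
        for spec in specs:
            rec = evaluate_fold(spec, X[tr], y[tr], X[te], y[te],
                                seed=fold_seed, time_index=time_index,
                                fold=fold_i)
            if rec is None:
                continue
            rows.append({
                "participant": participant, "group": group,
                "classifier": spec.name, "time_ms": time_ms, "fold": fold_i,
                "accuracy": rec.accuracy, "precision": rec.precision,
                "recall": rec.recall, "f1": rec.f1, "auroc": rec.auroc,
            })
    return rows


def decode_static(features: np.ndarray, labels: np.ndarray,
                  specs: tuple[ClassifierSpec, ...], seed: int,
                  k: int = 10, participant: str = "",
                  group: str = "") -> DecodingResult:
    """Full CV over the time-independent feature matrix (one participant)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    rows = _decode_once(X, y, specs, seed, k=k, participant=participant,
                        group=group)
    return DecodingResult(pd.DataFrame(rows))


def decode_timecourse(values: np.ndarray, labels: np.ndarray,
                      times: np.ndarray, specs: tuple[ClassifierSpec, ...],
                      seed: int, k: int = 10, participant: str = "",
                      group: str = "") -> DecodingResult:
    """Repeat the whole CV protocol independently at every time point.

    ``values`` is (trials, time, features); the per-time-point run with
    derived seed ``derive_seed(seed, t)`` is identical to ``decode_static``
    on that time slice with the same seed.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    rows: list[dict] = []
    for t in range(values.shape[1]):
        rows.extend(_decode_once(values[:, t, :], y, specs,
                                 derive_seed(seed, t), k=k, time_index=t,
                                 time_ms=float(times[t]),
                                 participant=participant, group=group))
    return DecodingResult(pd.DataFrame(rows))
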