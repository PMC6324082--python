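"""Model construction: stump boosting, feature selection, CV, threshold calibration.

The classifier behind the translocation score is a gradient-boosted ensemble
of decision stumps (depth-1 trees) fit to the logistic loss.  Restricting
trees to a single split keeps the model additive in the features: each stump
contributes ``left_leaf`` when the feature is below its split point and
``right_leaf`` otherwise, so the ensemble's margin is a weighted sum of
per-feature indicator contributions — exactly the form of the scoring
module's weight table.

Per-feature importance is the aggregated signed leaf-score contribution
(right leaf minus left leaf, summed over every stump that splits on the
feature).  Features whose absolute importance exceeds a cutoff (default
0.02, strict inequality) survive feature selection.

Model quality is assessed by repeated stratified 5-fold cross-validation:
each repeat reshuffles the folds, held-out predictions are pooled, and the
ROC AUC plus precision–recall and Matthews-correlation curves are recorded
per repeat.

Two calibration rules turn scores into class boundaries: the lower cutoff
maximizes F1 over observed-score candidates, and the upper (high-confidence)
cutoff is the maximum score of any negative-set protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"


class TrainingError(ValueError):
    """Contract violation in training inputs or configuration."""


@dataclass
class TrainingConfig:
    """Hyperparameters of the boosting and cross-validation protocol.

    ``min_split_gain`` is the minimum second-order gain a stump must achieve
    to be accepted; boosting stops early once no split clears it.  This is
    the main guard against fitting pure-noise features on small cohorts.
    """

    folds: int = 5
    repeats: int = 100
    seed: int = 0
    learning_rate: float = 0.3
    n_rounds: int = 100
    importance_cutoff: float = 0.02
    reg_lambda: float = 1.0
    min_split_gain: float = 12.0
    max_bins: int = 32
    auc_mode: Literal["pooled", "per_fold"] = "pooled"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise TrainingError("folds must be >= 2")
        if self.importance_cutoff <= 0:
            raise TrainingError("importance cutoff must be > 0")


@dataclass(frozen=True)
class Stump:
    feature: str
    threshold: float
    left_leaf: float  # applied when value < threshold
    right_leaf: float  # applied when value >= threshold


@dataclass
class StumpEnsemble:
    """A fitted boosted-stump model (leaf values already learning-rate scaled)."""

    trees: list[Stump]
    feature_names: list[str]
    base_margin: float
    learning_rate: float

    def decision_function(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        margin = np.full(X.shape[0], self.base_margin)
        index = {name: j for j, name in enumerate(self.feature_names)}
        for stump in self.trees:
            below = X[:, index[stump.feature]] < stump.threshold
            margin += np.where(below, stump.left_leaf, stump.right_leaf)
        return margin

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def importances(self) -> pd.Series:
        """Signed per-feature importance: sum of (right - left) leaf scores."""
        imp = pd.Series(0.0, index=pd.Index(self.feature_names, name="feature"))
        for stump in self.trees:
            imp[stump.feature] += stump.right_leaf - stump.left_leaf
        return imp


def _as_matrix(X: pd.DataFrame | np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X[list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise TrainingError("feature matrix width does not match model features")
    return X


def split_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a labelled cohort frame into features and the binary label vector."""
    if LABEL_COLUMN not in cohort.columns:
        raise TrainingError(f"cohort lacks a {LABEL_COLUMN!r} column")
    if cohort.index.has_duplicates:
        raise TrainingError("cohort contains duplicated protein ids")
    y = cohort[LABEL_COLUMN].to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise TrainingError("labels must be binary 0/1")
    X = cohort.drop(columns=[LABEL_COLUMN])
    return X, y.astype(int)


def _candidate_splits(col: np.ndarray, max_bins: int) -> np.ndarray:
    """Midpoints between distinct values, quantile-thinned for continuous data."""
    uniq = np.unique(col[~np.isnan(col)])
    if uniq.size <= 1:
        return np.empty(0)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    if mids.size > max_bins:
        idx = np.linspace(0, mids.size - 1, max_bins).round().astype(int)
        mids = np.unique(mids[idx])
    return mids


def fit_stump_ensemble(
    cohort: pd.DataFrame,
    config: TrainingConfig | None = None,
) -> StumpEnsemble:
    """Boost depth-1 trees on a labelled cohort (logistic loss, exact greedy).

    Deterministic given the configuration: the greedy split search has no
    random component and ties are broken by feature order.  Raises on a
    single-class cohort.
    """
    config = config or TrainingConfig()
    X_df, y = split_cohort(cohort)
    if len(np.unique(y)) < 2:
        raise TrainingError("cohort must contain both classes")
    feature_names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)  # undefined topology treated as 0 (indicator-false)
    n = X.shape[0]

    # Precompute the below-threshold indicator for every candidate split.
    columns: list[tuple[int, float]] = []
    for j in range(X.shape[1]):
        for t in _candidate_splits(X[:, j], config.max_bins):
            columns.append((j, float(t)))
    if not columns:
        raise TrainingError("no splittable feature (all columns constant)")
    B = np.empty((n, len(columns)), dtype=np.float64)
    for k, (j, t) in enumerate(columns):
        B[:, k] = X[:, j] < t

    pos = y.mean()
    base_margin = float(np.log(pos / (1.0 - pos)))
    margin = np.full(n, base_margin)
    lam = config.reg_lambda
    trees: list[Stump] = []
    for _ in range(config.n_rounds):
        p = 1.0 / (1.0 + np.exp(-margin))
        g = p - y
        h = p * (1.0 - p)
        G, H = g.sum(), h.sum()
        GL = g @ B
        HL = h @ B
        GR, HR = G - GL, H - HL
        gain = GL**2 / (HL + lam) + GR**2 / (HR + lam) - G**2 / (H + lam)
        best = int(np.argmax(gain))
        if gain[best] <= config.min_split_gain:
            break
        j, t = columns[best]
        wl = -config.learning_rate * GL[best] / (HL[best] + lam)
        wr = -config.learning_rate * GR[best] / (HR[best] + lam)
        trees.append(Stump(feature_names[j], t, float(wl), float(wr)))
        margin += np.where(B[:, best] == 1.0, wl, wr)
    return StumpEnsemble(
        trees=trees,
        feature_names=feature_names,
        base_margin=base_margin,
        learning_rate=config.learning_rate,
    )


def fit_xgboost(cohort: pd.DataFrame, config: TrainingConfig | None = None):
    """Optional parity adapter: depth-1 gradient boosting via the xgboost engine.

    Returns the fitted ``xgboost.XGBClassifier``.  Used for cross-checks;
    the reference implementation is :func:`fit_stump_ensemble`.
    """
    import xgboost as xgb

    config = config or TrainingConfig()
    X, y = split_cohort(cohort)
    model = xgb.XGBClassifier(
        max_depth=1,
        n_estimators=config.n_rounds,
        learning_rate=config.learning_rate,
        reg_lambda=config.reg_lambda,
        gamma=config.min_split_gain,
        random_state=config.seed,
        eval_metric="logloss",
    )
    model.fit(X, y)
    return model


def select_features(
    ensemble: StumpEnsemble,
    cutoff: float = 0.02,
) -> set[str]:
    """Features with |signed importance| strictly greater than ``cutoff``."""
    if cutoff <= 0:
        raise TrainingError("cutoff must be > 0")
    imp = ensemble.importances()
    return set(imp.index[imp.abs() > cutoff])


@dataclass
class CVReport:
    """Repeated cross-validation results; one entry per repeat."""

    aucs: list[float]
    pr_curves: list[pd.DataFrame] = field(default_factory=list)
    mcc_curves: list[pd.DataFrame] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def min_auc(self) -> float:
        return float(np.min(self.aucs))

    @property
    def max_auc(self) -> float:
        return float(np.max(self.aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "repeats": len(self.aucs),
            "mean_auc": self.mean_auc,
            "min_auc": self.min_auc,
            "max_auc": self.max_auc,
            "std_auc": self.std_auc,
        }


def _mcc_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Matthews correlation at every observed-score threshold (>= rule)."""
    thresholds = np.unique(scores)
    pred = scores[None, :] >= thresholds[:, None]
    pos = labels == 1
    tp = (pred & pos).sum(axis=1).astype(float)
    fp = (pred & ~pos).sum(axis=1).astype(float)
    fn = ((~pred) & pos).sum(axis=1).astype(float)
    tn = ((~pred) & ~pos).sum(axis=1).astype(float)
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    return pd.DataFrame({"threshold": thresholds, "mcc": mcc})


def cross_validate(
    cohort: pd.DataFrame,
    config: TrainingConfig | None = None,
    keep_curves: bool = True,
) -> CVReport:
    """Repeated stratified k-fold CV of the stump ensemble.

    Each repeat re-randomizes the fold assignment from the run seed.  With
    ``auc_mode="pooled"`` (default) held-out predictions of all folds are
    pooled into one AUC per repeat; ``"per_fold"`` averages per-fold AUCs.
    """
    config = config or TrainingConfig()
    X, y = split_cohort(cohort)
    if len(cohort) < config.folds:
        raise TrainingError("cohort smaller than the number of folds")
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.folds:
        raise TrainingError(
            "too few samples of one class to stratify into "
            f"{config.folds} folds (class counts {counts.tolist()})"
        )
    aucs: list[float] = []
    pr_curves: list[pd.DataFrame] = []
    mcc_curves: list[pd.DataFrame] = []
    for repeat in range(config.repeats):
        run_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(repeat,)).generate_state(1)[0]
            % (2**31 - 1)
        )
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=run_seed
        )
        pooled_scores = np.empty(len(y))
        fold_aucs: list[float] = []
        for train_idx, test_idx in skf.split(X, y):
            fold = cohort.iloc[train_idx]
            ensemble = fit_stump_ensemble(fold, config)
            scores = ensemble.decision_function(X.iloc[test_idx])
            pooled_scores[test_idx] = scores
            if config.auc_mode == "per_fold":
                fold_aucs.append(float(roc_auc_score(y[test_idx], scores)))
        if config.auc_mode == "pooled":
            aucs.append(float(roc_auc_score(y, pooled_scores)))
        else:
            aucs.append(float(np.mean(fold_aucs)))
        if keep_curves:
            precision, recall, thresholds = precision_recall_curve(y, pooled_scores)
            pr_curves.append(
                pd.DataFrame(
                    {
                        "threshold": np.append(thresholds, np.inf),
                        "precision": precision,
                        "recall": recall,
                    }
                )
            )
            mcc_curves.append(_mcc_curve(pooled_scores, y))
    return CVReport(aucs=aucs, pr_curves=pr_curves, mcc_curves=mcc_curves)


@dataclass(frozen=True)
class ThresholdScan:
    """Result of the F1-maximizing threshold search."""

    threshold: float
    f1: float
    precision: float
    recall: float
    curves: pd.DataFrame  # threshold, recall, precision, fallout, f1


def f1_threshold_scan(
    scores: Sequence[float],
    labels: Sequence[int],
) -> ThresholdScan:
    """Scan observed scores as thresholds and maximize F1.

    A protein is predicted positive iff ``score >= threshold``.  Candidates
    are the sorted distinct scores; ties on F1 resolve to the smallest
    optimal threshold.  The full recall/precision/fallout/F1 curves are
    returned alongside the optimum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise TrainingError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise TrainingError("both classes required to calibrate a threshold")
    thresholds = np.unique(scores)
    pred = scores[None, :] >= thresholds[:, None]
    pos = labels == 1
    tp = (pred & pos).sum(axis=1).astype(float)
    fp = (pred & ~pos).sum(axis=1).astype(float)
    fn = float(pos.sum()) - tp
    tn = float((~pos).sum()) - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = tp / (tp + fn)
        fallout = np.where(fp + tn > 0, fp / (fp + tn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    best = int(np.argmax(f1))  # argmax returns the first (smallest) optimum
    curves = pd.DataFrame(
        {
            "threshold": thresholds,
            "recall": recall,
            "precision": precision,
            "fallout": fallout,
            "f1": f1,
        }
    )
    return ThresholdScan(
        threshold=float(thresholds[best]),
        f1=float(f1[best]),
        precision=float(precision[best]),
        recall=float(recall[best]),
        curves=curves,
    )


def high_confidence_cutoff(scores_negatives: Sequence[float]) -> float:
    """Largest score attained by any negative-set protein.

    Above this value no curated non-translocating protein lies, so scores
    beyond it are considered high-confidence predictions.
    """
    scores = np.asarray(scores_negatives, dtype=float)
    if scores.size == 0:
        raise TrainingError("need at least one negative-set score")
    return float(scores.max())
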