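"""Stage-aware classification: tuned boosted trees, transfer and one-vs-rest designs.

The classifier follows a fixed protocol: stratified 70/30 train/test split,
per-feature standardization fitted on the training portion only, a small grid
search (interaction depth 1-3 x 50/100/150 trees, shrinkage 0.1, minimum node
size 5) by stratified 4-fold cross-validation maximizing ROC area, and a final
refit at the winning grid point.  Three validation designs probe the
homogeneity of the disease signature: within-stage holdout (diagonal),
stage-to-stage transfer (train on stage i vs controls, test on stage j vs
held-out controls), and one-vs-rest among patients.  A random-forest learner
is available as a verification of the boosted-tree results, and a split-half
replication reruns the whole pipeline on random halves of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .normalization import NormalizedMatrix, fit_snm, log_cpm
from .profiles import PATIENT_STAGES, ProfileTable, prevalence_filter, to_cpm


class MLError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Tuning protocol for the stage classifiers."""

    interaction_depth: Sequence[int] = (1, 2, 3)
    n_trees: Sequence[int] = (50, 100, 150)
    shrinkage: float = 0.1
    min_node: int = 5
    subsample: float = 0.5
    cv_folds: int = 4
    test_fraction: float = 0.3
    scale_mode: str = "feature"  # "feature" (default) or "sample"
    learner: str = "gbm"  # "gbm" or "rf"
    rf_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not self.interaction_depth or not self.n_trees:
            raise MLError("parameter grid must be nonempty")
        if self.cv_folds < 2:
            raise MLError("cv_folds must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise MLError("test_fraction must lie in (0, 1)")
        if self.scale_mode not in ("feature", "sample"):
            raise MLError("scale_mode must be 'feature' or 'sample'")
        if self.learner not in ("gbm", "rf"):
            raise MLError("learner must be 'gbm' or 'rf'")


class StageClassifier(BaseEstimator, ClassifierMixin):
    """Grid-tuned stochastic gradient-boosted (or random-forest) classifier.

    Parameters mirror :class:`TrainConfig`; ``fit`` performs the stratified
    4-fold grid search over (interaction_depth x n_trees) maximizing CV
    AUROC and refits the best point on the full training data.  With
    ``learner="rf"`` a 500-tree random forest replaces the boosted ensemble
    and the grid is skipped (the forest has no comparable depth/trees grid in
    the protocol).

    Attributes
    ----------
    best_params_ : dict
        Winning grid point (gbm) or the fixed forest settings (rf).
    cv_results_ : pandas.DataFrame
        Mean CV AUROC per grid point.
    model_ : fitted sklearn estimator
    scaler_ : fitted StandardScaler or None (per-sample scaling is stateless)
    """

    def __init__(self, interaction_depth=(1, 2, 3), n_trees=(50, 100, 150),
                 shrinkage=0.1, min_node=5, subsample=0.5, cv_folds=4,
                 scale_mode="feature", learner="gbm", rf_trees=500,
                 random_state=0):
        self.interaction_depth = interaction_depth
        self.n_trees = n_trees
        self.shrinkage = shrinkage
        self.min_node = min_node
        self.subsample = subsample
        self.cv_folds = cv_folds
        self.scale_mode = scale_mode
        self.learner = learner
        self.rf_trees = rf_trees
        self.random_state = random_state

    # -- scaling ----------------------------------------------------------
    def _scale_fit(self, X):
        if self.scale_mode == "feature":
            self.scaler_ = StandardScaler()
            return self.scaler_.fit_transform(X)
        self.scaler_ = None
        return self._scale_sample(X)

    def _scale_apply(self, X):
        if self.scale_mode == "feature":
            return self.scaler_.transform(X)
        return self._scale_sample(X)

    @staticmethod
    def _scale_sample(X):
        X = np.asarray(X, dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def _make_learner(self, depth: int, trees: int):
        if self.learner == "rf":
            return RandomForestClassifier(n_estimators=self.rf_trees,
                                          min_samples_leaf=self.min_node,
                                          random_state=self.random_state)
        return GradientBoostingClassifier(
            max_depth=depth, n_estimators=trees, learning_rate=self.shrinkage,
            min_samples_leaf=self.min_node, subsample=self.subsample,
            random_state=self.random_state)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise MLError("features must be finite")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) != 2:
            raise MLError("StageClassifier is a binary classifier")
        if counts.min() < self.cv_folds:
            small = self.classes_[counts.argmin()]
            raise MLError(
                f"class {small!r} has only {counts.min()} training samples; "
                f"{self.cv_folds}-fold stratified CV needs at least "
                f"{self.cv_folds} per class — pool stages or reduce cv_folds")
        Xs = self._scale_fit(X)
        y_bin = (y == self.classes_[1]).astype(int)

        if self.learner == "rf":
            self.cv_results_ = pd.DataFrame()
            self.best_params_ = {"n_estimators": self.rf_trees}
            self.model_ = self._make_learner(0, 0).fit(Xs, y_bin)
            return self

        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                             random_state=self.random_state)
        folds = list(cv.split(Xs, y_bin))
        records = []
        for depth in self.interaction_depth:
            for trees in self.n_trees:
                aucs = []
                for tr, va in folds:
                    mdl = self._make_learner(depth, trees).fit(Xs[tr], y_bin[tr])
                    if len(np.unique(y_bin[va])) < 2:
                        continue
                    scores = mdl.predict_proba(Xs[va])[:, 1]
                    aucs.append(roc_auc_score(y_bin[va], scores))
                records.append({"interaction_depth": depth, "n_trees": trees,
                                "mean_cv_auroc": float(np.mean(aucs))})
        self.cv_results_ = pd.DataFrame(records)
        best = self.cv_results_["mean_cv_auroc"].idxmax()  # first max wins ties
        self.best_params_ = {
            "interaction_depth": int(self.cv_results_.loc[best, "interaction_depth"]),
            "n_trees": int(self.cv_results_.loc[best, "n_trees"])}
        self.model_ = self._make_learner(self.best_params_["interaction_depth"],
                                         self.best_params_["n_trees"]).fit(Xs, y_bin)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._scale_apply(np.asarray(X, dtype=float)))

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= 0.5, self.classes_[1], self.classes_[0])

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class probability (the score used for ROC/PR curves)."""
        return self.predict_proba(X)[:, 1]


@dataclass
class EvalResult:
    auroc: float
    aupr: float
    n_test: int
    roc: pd.DataFrame
    pr: pd.DataFrame


def evaluate(model, test_features, test_labels, positive=1) -> EvalResult:
    """ROC/PR curves, AUROC (trapezoid) and AUPR (step integral) on a test set."""
    y = np.asarray(test_labels)
    if len(np.unique(y)) < 2:
        raise MLError("test set contains a single class")
    y_bin = (y == positive).astype(int)
    scores = (model.decision_scores(test_features)
              if hasattr(model, "decision_scores")
              else model.predict_proba(test_features)[:, 1])
    fpr, tpr, _ = roc_curve(y_bin, scores)
    precision, recall, _ = precision_recall_curve(y_bin, scores)
    auroc = float(np.trapezoid(tpr, fpr))
    aupr = float(average_precision_score(y_bin, scores))
    return EvalResult(auroc=auroc, aupr=aupr, n_test=len(y),
                      roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
                      pr=pd.DataFrame({"recall": recall, "precision": precision}))


@dataclass
class FittedClassifier:
    model: StageClassifier
    train_index: np.ndarray
    test_index: np.ndarray
    holdout: EvalResult


def _classifier(config: TrainConfig) -> StageClassifier:
    return StageClassifier(
        interaction_depth=tuple(config.interaction_depth),
        n_trees=tuple(config.n_trees), shrinkage=config.shrinkage,
        min_node=config.min_node, subsample=config.subsample,
        cv_folds=config.cv_folds, scale_mode=config.scale_mode,
        learner=config.learner, rf_trees=config.rf_trees,
        random_state=config.seed)


def train_classifier(features, binary_labels, config: TrainConfig
                     ) -> FittedClassifier:
    """Fit the tuned classifier on a stratified 70/30 split; evaluate the 30%.

    ``features`` is samples x features; labels are binary (1 = case).
    """
    config.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(binary_labels)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, stratify=y,
        random_state=config.seed)
    model = _classifier(config).fit(X[train_idx], y[train_idx])
    result = evaluate(model, X[test_idx], y[test_idx])
    return FittedClassifier(model, train_idx, test_idx, result)


def variable_importance(model) -> pd.Series:
    """Split-gain relative influence per feature, normalized to sum 100."""
    est = model.model_ if isinstance(model, StageClassifier) else model
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    scores = imp * 100.0 / total if total > 0 else imp
    names = getattr(model, "feature_names_", None)
    index = names if names is not None else pd.RangeIndex(len(imp))
    return pd.Series(scores, index=index).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Validation designs


def _matrix(norm: NormalizedMatrix) -> tuple[np.ndarray, list[str]]:
    return norm.values.to_numpy(dtype=float).T, norm.feature_ids


@dataclass
class EvaluationMatrix:
    """Train-condition x test-condition grid of AUROC/AUPR with importances."""

    auroc: pd.DataFrame
    aupr: pd.DataFrame
    n_test: pd.DataFrame
    importance: dict = field(default_factory=dict)
    best_params: dict = field(default_factory=dict)


def stage_vs_control_matrix(norm: NormalizedMatrix, metadata: pd.DataFrame,
                            config: TrainConfig,
                            stages=PATIENT_STAGES) -> EvaluationMatrix:
    """Train each stage-vs-HC model; validate within stage and across stages.

    Controls are split once into a 70% train-eligible and 30% holdout pool,
    reused by every model so cells are comparable.  Diagonal cells test on
    the training stage's own 30% holdout plus the control holdout; an
    off-diagonal cell (i, j) tests model i on all stage-j patients (never
    seen in training) plus the same control holdout, avoiding any control
    leakage into transfer estimates.
    """
    config.validate()
    meta = metadata.loc[norm.sample_ids]
    X, feature_ids = _matrix(norm)
    stage_arr = meta["stage"].astype(str).to_numpy()
    rng_seed = config.seed

    hc_idx = np.where(stage_arr == "HC")[0]
    if len(hc_idx) < 4:
        raise MLError("need at least 4 control samples")
    hc_train, hc_hold = train_test_split(hc_idx, test_size=config.test_fraction,
                                         random_state=rng_seed)
    stages = [s for s in stages if (stage_arr == s).sum() >= 4]

    auroc = pd.DataFrame(np.nan, index=stages, columns=stages)
    aupr = pd.DataFrame(np.nan, index=stages, columns=stages)
    n_test = pd.DataFrame(0, index=stages, columns=stages)
    importance, best_params = {}, {}

    for si in stages:
        si_idx = np.where(stage_arr == si)[0]
        si_train, si_hold = train_test_split(
            si_idx, test_size=config.test_fraction, random_state=rng_seed)
        train = np.concatenate([hc_train, si_train])
        y_train = (stage_arr[train] != "HC").astype(int)
        model = _classifier(config).fit(X[train], y_train)
        model.feature_names_ = feature_ids
        importance[si] = variable_importance(model)
        best_params[si] = dict(model.best_params_)
        for sj in stages:
            test = (np.concatenate([hc_hold, si_hold]) if sj == si
                    else np.concatenate([hc_hold, np.where(stage_arr == sj)[0]]))
            res = evaluate(model, X[test], (stage_arr[test] != "HC").astype(int))
            auroc.loc[si, sj] = res.auroc
            aupr.loc[si, sj] = res.aupr
            n_test.loc[si, sj] = res.n_test
    return EvaluationMatrix(auroc, aupr, n_test, importance, best_params)


def one_vs_rest_models(norm: NormalizedMatrix, metadata: pd.DataFrame,
                       config: TrainConfig,
                       stages=PATIENT_STAGES) -> EvaluationMatrix:
    """One patient stage against the other three pooled (controls excluded)."""
    config.validate()
    meta = metadata.loc[norm.sample_ids]
    X, feature_ids = _matrix(norm)
    stage_arr = meta["stage"].astype(str).to_numpy()
    patient = np.isin(stage_arr, list(PATIENT_STAGES))
    Xp, sp = X[patient], stage_arr[patient]

    stages = [s for s in stages if (sp == s).sum() >= 4]
    auroc = pd.DataFrame(np.nan, index=stages, columns=["rest"])
    aupr = pd.DataFrame(np.nan, index=stages, columns=["rest"])
    n_test = pd.DataFrame(0, index=stages, columns=["rest"])
    importance, best_params = {}, {}
    for stage in stages:
        y = (sp == stage).astype(int)
        fitted = train_classifier(Xp, y, config)
        fitted.model.feature_names_ = feature_ids
        importance[stage] = variable_importance(fitted.model)
        best_params[stage] = dict(fitted.model.best_params_)
        auroc.loc[stage, "rest"] = fitted.holdout.auroc
        aupr.loc[stage, "rest"] = fitted.holdout.aupr
        n_test.loc[stage, "rest"] = fitted.holdout.n_test
    return EvaluationMatrix(auroc, aupr, n_test, importance, best_params)


def random_forest_check(norm: NormalizedMatrix, metadata: pd.DataFrame,
                        config: TrainConfig, stages=PATIENT_STAGES
                        ) -> EvaluationMatrix:
    """Rerun the transfer design with a random-forest learner for verification."""
    return stage_vs_control_matrix(norm, metadata,
                                   replace(config, learner="rf"), stages=stages)


# ---------------------------------------------------------------------------
# Split-half replication


def _stratified_halves(metadata: pd.DataFrame, seed: int
                       ) -> tuple[pd.Index, pd.Index]:
    rng = np.random.default_rng(seed)
    half_a, half_b = [], []
    for _, group in metadata.groupby(["study", "stage"], observed=True):
        ids = list(group.index)
        rng.shuffle(ids)
        mid = len(ids) // 2
        flip = rng.random() < 0.5  # odd groups do not always favor one half
        first, second = (half_a, half_b) if not flip else (half_b, half_a)
        first.extend(ids[:mid + len(ids) % 2])
        second.extend(ids[mid + len(ids) % 2:])
    return pd.Index(half_a), pd.Index(half_b)


def _half_pipeline(profile: ProfileTable, metadata: pd.DataFrame,
                   samples: pd.Index, min_cpm: float, min_samples: int):
    counts = profile.subset_samples(samples)
    meta = metadata.loc[samples]
    cpm = to_cpm(counts)
    features = prevalence_filter(cpm, min_cpm, min_samples).feature_ids
    norm = fit_snm(log_cpm(cpm), meta)
    return norm, meta, features


def split_half_replication(profile: ProfileTable, metadata: pd.DataFrame,
                           config: TrainConfig, min_cpm: float = 1.0,
                           min_samples: int = 3) -> pd.DataFrame:
    """Rerun the full pipeline on two random halves and cross-apply the models.

    Samples are halved stratified by study and stage; each half is filtered,
    normalized and used to train a patients-vs-controls classifier
    independently; each model is then tested on its own 30% holdout
    (within-half) and on every sample of the other half (cross-half).
    Returns a 4-row table of AUROC/AUPR per (model half, test half).
    """
    config.validate()
    ids_a, ids_b = _stratified_halves(metadata.loc[profile.sample_ids], config.seed)
    halves = {"A": ids_a, "B": ids_b}
    fitted, norms, metas, feats = {}, {}, {}, {}
    for name, ids in halves.items():
        norm, meta, features = _half_pipeline(profile, metadata, ids,
                                              min_cpm, min_samples)
        norms[name], metas[name], feats[name] = norm, meta, features
        X = norm.values.loc[features].to_numpy(dtype=float).T
        y = (meta["stage"] != "HC").astype(int).to_numpy()
        fitted[name] = train_classifier(X, y, config)

    rows = []
    for name, other in (("A", "B"), ("B", "A")):
        within = fitted[name].holdout
        rows.append((name, name, within.auroc, within.aupr, within.n_test))
        X_other = norms[other].values.loc[feats[name]].to_numpy(dtype=float).T
        y_other = (metas[other]["stage"] != "HC").astype(int).to_numpy()
        cross = evaluate(fitted[name].model, X_other, y_other)
        rows.append((name, other, cross.auroc, cross.aupr, cross.n_test))
    return pd.DataFrame(rows, columns=["model_half", "test_half", "auroc",
                                       "aupr", "n_test"])
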