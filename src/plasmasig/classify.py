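"""Feature selection by AUC-based random-forest backward elimination and
classifier evaluation over repeated random trisections.

The selection stage mirrors the AUC-oriented RF elimination scheme: fit a
random forest on the current feature set, score it by the AUC of its
out-of-bag class probabilities, drop the least important feature, and
repeat down to a single feature; the optimal subset is the smallest one
attaining the maximum OOB AUC.  Stability of membership is quantified as a
probability of selection across repeated cross-validated runs.

Evaluation trisects the cohort at random (stratified 2/3 train, 1/3
validation), tunes a linear-kernel SVM and a random forest inside the
training portion only, and aggregates the 100 validation ROC curves into
median AUC, a percentile interval, and 25/50/75 sensitivity quantile bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import (GridSearchCV, RepeatedStratifiedKFold,
                                     StratifiedKFold, StratifiedShuffleSplit)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import RunConfig

__all__ = ["univariate_auc", "aucrf_backward_eliminate",
           "probability_of_selection", "evaluate_classifiers",
           "FeatureSelectionResult", "CVEvaluation"]

SVM_COST_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
_SPECIFICITY_GRID = np.linspace(0.0, 1.0, 101)


def univariate_auc(values, labels) -> float:
    """Rank-based AUC: P(positive > negative) with ties counted 1/2."""
    y = np.asarray(labels)
    x = np.asarray(values, float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(y, x))


def _rf(cfg: RunConfig, seed: int, max_features=None) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=cfg.rf_ntree, min_samples_leaf=cfg.rf_nodesize,
        max_features=max_features if max_features is not None else "sqrt",
        oob_score=True, bootstrap=True, random_state=seed, n_jobs=1)


def _oob_auc(rf: RandomForestClassifier, y: np.ndarray) -> float:
    proba = rf.oob_decision_function_[:, 1]
    ok = ~np.isnan(proba)
    return float(roc_auc_score(y[ok], proba[ok]))


def _oob_permutation_importance(rf: RandomForestClassifier, X: np.ndarray,
                                y: np.ndarray, rng: np.random.Generator
                                ) -> np.ndarray:
    """Mean decrease in OOB accuracy when permuting each feature, per tree."""
    n, p = X.shape
    imp = np.zeros(p)
    from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                          _get_n_samples_bootstrap)
    nb = _get_n_samples_bootstrap(n, rf.max_samples, None)
    for tree in rf.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, nb, None)
        if len(oob) == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base = (tree.predict(Xo) == yo).mean()
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            imp[j] += base - (tree.predict(Xp) == yo).mean()
    return imp / len(rf.estimators_)


def aucrf_backward_eliminate(X, y, cfg: RunConfig, feature_names=None,
                             importance: str = "gini",
                             seed: int | None = None) -> pd.DataFrame:
    """Backward elimination ranked by RF importance, scored by OOB AUC.

    Returns the elimination path, one row per subset size, with columns
    ``size``, ``oob_auc``, ``features`` (tuple), ``dropped``, and
    ``optimal`` marking the smallest subset attaining the maximum OOB AUC.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features to eliminate")
    if len(np.unique(y)) != 2 or min(np.bincount(y)) < 2:
        raise ValueError("both classes must be present with >= 2 samples")
    names = list(feature_names) if feature_names is not None \
        else [f"f{j}" for j in range(p)]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    current = list(range(p))
    rows = []
    while current:
        rf = _rf(cfg, int(rng.integers(2 ** 31)))
        rf.fit(X[:, current], y)
        auc = _oob_auc(rf, y)
        if importance == "gini":
            imp = rf.feature_importances_
        elif importance == "permutation":
            imp = _oob_permutation_importance(rf, X[:, current], y, rng)
        else:
            raise ValueError(f"unknown importance {importance!r}")
        drop = current[int(np.argmin(imp))] if len(current) > 1 else None
        rows.append({"size": len(current), "oob_auc": auc,
                     "features": tuple(names[j] for j in current),
                     "importance": dict(zip((names[j] for j in current), imp)),
                     "dropped": names[drop] if drop is not None else None})
        if drop is None:
            break
        current.remove(drop)

    path = pd.DataFrame(rows)
    best = path["oob_auc"].max()
    # smallest subset achieving the maximum (ties favour fewer features)
    opt_size = path.loc[path["oob_auc"] >= best - 1e-12, "size"].min()
    path["optimal"] = path["size"] == opt_size
    return path


@dataclass
class FeatureSelectionResult:
    """Per-feature importance, probability of selection, and the final set."""

    candidates: list[str]
    elimination_path: pd.DataFrame       # on the full data
    optimal_subset: tuple[str, ...]
    prob_select: pd.Series
    mean_importance: pd.Series
    univariate_auc: pd.Series
    selected: list[str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        """Selection table: importance, prob of selection, flag, univariate
        AUC per candidate feature."""
        df = pd.DataFrame({
            "feature": self.candidates,
            "importance": self.mean_importance.reindex(self.candidates).values,
            "prob_select": self.prob_select.reindex(self.candidates).values,
            "selection": ["Y" if f in self.selected else "N"
                          for f in self.candidates],
            "univariate_auc": self.univariate_auc.reindex(
                self.candidates).values,
        })
        return df.sort_values("prob_select", ascending=False,
                              ignore_index=True)


def probability_of_selection(X, y, cfg: RunConfig, feature_names=None,
                             importance: str = "gini"
                             ) -> FeatureSelectionResult:
    """Repeated cross-validated elimination -> probability of selection.

    Runs `cfg.probsel_iterations` iterations of `cfg.cv_folds`-fold
    stratified splitting; on each training portion the backward elimination
    is rerun, and a feature's probability of selection is the fraction of
    runs in which it lands in the optimal subset.  Features with
    probability > `cfg.probsel_threshold` form the selected set.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    p = X.shape[1]
    names = list(feature_names) if feature_names is not None \
        else [f"f{j}" for j in range(p)]
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(cfg.probsel_iterations * (cfg.cv_folds + 1))

    counts = pd.Series(0.0, index=names)
    imp_sum = pd.Series(0.0, index=names)
    n_runs = 0
    si = 0
    for it in range(cfg.probsel_iterations):
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                              random_state=int(seeds[si] % (2 ** 31)))
        si += 1
        for train, _test in skf.split(X, y):
            path = aucrf_backward_eliminate(
                X[train], y[train], cfg, feature_names=names,
                importance=importance, seed=int(seeds[si] % (2 ** 31)))
            si += 1
            opt = path.loc[path["optimal"], "features"].iloc[0]
            for f in opt:
                counts[f] += 1
            full_imp = path.iloc[0]["importance"]
            for f, v in full_imp.items():
                imp_sum[f] += v
            n_runs += 1

    prob = counts / n_runs
    mean_imp = imp_sum / n_runs
    uauc = pd.Series({nm: max(a := univariate_auc(X[:, j], y), 1 - a)
                      for j, nm in enumerate(names)})
    full_path = aucrf_backward_eliminate(
        X, y, cfg, feature_names=names, importance=importance,
        seed=int(ss.generate_state(1, dtype=np.uint32)[0]))
    selected = [f for f in names if prob[f] > cfg.probsel_threshold]
    return FeatureSelectionResult(
        candidates=names, elimination_path=full_path,
        optimal_subset=full_path.loc[full_path["optimal"], "features"].iloc[0],
        prob_select=prob, mean_importance=mean_imp, univariate_auc=uauc,
        selected=selected, threshold=cfg.probsel_threshold)


@dataclass
class CVEvaluation:
    """Aggregated performance of the classifiers over random trisections."""

    auc: pd.DataFrame                   # per split x classifier
    median_auc: dict[str, float]
    auc_interval: dict[str, tuple[float, float]]  # 2.5/97.5 percentiles
    roc_bands: dict[str, pd.DataFrame]  # per classifier: grid x {q25,q50,q75}

    def summary(self) -> dict:
        return {clf: {"median_auc": self.median_auc[clf],
                      "ci_low": self.auc_interval[clf][0],
                      "ci_high": self.auc_interval[clf][1]}
                for clf in self.median_auc}


def _scale_split(X: np.ndarray, train: np.ndarray, test: np.ndarray):
    """Center/scale both portions using training statistics only."""
    scaler = StandardScaler().fit(X[train])
    return scaler.transform(X[train]), scaler.transform(X[test]), scaler


def _tuned_svm(Xtr, ytr, cfg: RunConfig, seed: int, tune: bool):
    if not tune:
        return SVC(kernel="linear", C=1.0).fit(Xtr, ytr)
    cv = RepeatedStratifiedKFold(n_splits=cfg.cv_folds,
                                 n_repeats=cfg.cv_repeats, random_state=seed)
    gs = GridSearchCV(SVC(kernel="linear"), {"C": list(SVM_COST_GRID)},
                      scoring="roc_auc", cv=cv, n_jobs=1)
    gs.fit(Xtr, ytr)
    return gs.best_estimator_


def _tuned_rf(Xtr, ytr, cfg: RunConfig, seed: int, tune: bool):
    p = Xtr.shape[1]
    base = RandomForestClassifier(n_estimators=cfg.rf_ntree,
                                  min_samples_leaf=cfg.rf_nodesize,
                                  random_state=seed, n_jobs=1)
    if not tune or p == 1:
        base.set_params(max_features=min(p, max(1, int(np.sqrt(p)))))
        return base.fit(Xtr, ytr)
    cv = RepeatedStratifiedKFold(n_splits=cfg.cv_folds,
                                 n_repeats=cfg.cv_repeats, random_state=seed)
    gs = GridSearchCV(base, {"max_features": list(range(1, p + 1))},
                      scoring="roc_auc", cv=cv, n_jobs=1)
    gs.fit(Xtr, ytr)
    return gs.best_estimator_


def evaluate_classifiers(X, y, cfg: RunConfig, tune: bool = True
                         ) -> CVEvaluation:
    """Evaluate linear-SVM and RF classifiers over random trisections.

    Each of `cfg.eval_splits` stratified splits trains on 2/3 of the
    samples and scores the held-out third; centering/scaling and all
    hyperparameter tuning use the training portion only.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(cfg.eval_splits * 3)
    splitter = StratifiedShuffleSplit(n_splits=cfg.eval_splits,
                                      test_size=1 / 3,
                                      random_state=int(seeds[0] % (2 ** 31)))
    aucs = {"SVM": [], "RF": []}
    sens = {"SVM": [], "RF": []}
    si = 1
    for train, test in splitter.split(X, y):
        Xtr, Xte, _ = _scale_split(X, train, test)
        ytr, yte = y[train], y[test]
        svm = _tuned_svm(Xtr, ytr, cfg, int(seeds[si] % (2 ** 31)), tune)
        rf = _tuned_rf(Xtr, ytr, cfg, int(seeds[si + 1] % (2 ** 31)), tune)
        si += 2
        for name, score in (("SVM", svm.decision_function(Xte)),
                            ("RF", rf.predict_proba(Xte)[:, 1])):
            aucs[name].append(roc_auc_score(yte, score))
            fpr, tpr, _ = roc_curve(yte, score)
            sens[name].append(np.interp(_SPECIFICITY_GRID, fpr, tpr))

    auc_df = pd.DataFrame(aucs)
    med, ci, bands = {}, {}, {}
    for name in aucs:
        a = np.asarray(aucs[name])
        med[name] = float(np.median(a))
        ci[name] = (float(np.percentile(a, 2.5)),
                    float(np.percentile(a, 97.5)))
        S = np.vstack(sens[name])
        bands[name] = pd.DataFrame({
            "one_minus_specificity": _SPECIFICITY_GRID,
            "q25": np.percentile(S, 25, axis=0),
            "q50": np.percentile(S, 50, axis=0),
            "q75": np.percentile(S, 75, axis=0),
        })
    return CVEvaluation(auc=auc_df, median_auc=med, auc_interval=ci,
                        roc_bands=bands)
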