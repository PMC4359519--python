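"""Metastasis classification from gene set activity scores.

Feature selection by two-sided Wilcoxon rank-sum test (normal
approximation, tie- and continuity-corrected) with BH control, followed by
a random-forest classifier evaluated by repeated stratified k-fold
cross-validation; out-of-fold class probabilities are pooled per repeat
and summarized as a mean AUC.  Feature lists may be transferred across
cohorts: only the set names move, the model is retrained in the
evaluation cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .engine import GsasMatrix
from .survival import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelection:
    selected: list[str]
    table: pd.DataFrame  # index: set name; columns: statistic, p, q
    source: str = ""
    q_threshold: float = 0.01


@dataclass
class CvEvaluation:
    aucs: list[float]  # one per repeat
    mean_auc: float
    roc_points: pd.DataFrame  # pooled over repeats: fpr, tpr, threshold
    importances: pd.Series  # mean decrease in impurity, averaged over folds
    seed: int
    n_folds: int
    n_repeats: int


def _align_labels(gsas: GsasMatrix, labels: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    common = [s for s in gsas.sample_ids if s in labels.index and not pd.isna(labels.loc[s])]
    y = labels.loc[common].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return gsas.data[common], y


def select_features(
    gsas: GsasMatrix, labels: pd.Series, q_threshold: float = 0.01, source: str = ""
) -> FeatureSelection:
    """Gene sets whose scores differ between the two label classes.

    Two-sided Wilcoxon rank-sum per set (normal approximation with
    continuity and tie correction); sets with BH q below the threshold are
    selected.
    """
    data, y = _align_labels(gsas, labels)
    case = data.loc[:, y == 1].to_numpy()
    ctrl = data.loc[:, y == 0].to_numpy()
    stats = np.empty(data.shape[0])
    pvals = np.empty(data.shape[0])
    for i in range(data.shape[0]):
        a, b = case[i], ctrl[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            stats[i], pvals[i] = len(a) * len(b) / 2.0, 1.0
            continue
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        stats[i], pvals[i] = float(res.statistic), float(res.pvalue)
    q = bh_fdr(pvals)
    table = pd.DataFrame({"statistic": stats, "p": pvals, "q": q}, index=data.index)
    selected = list(table.index[table["q"] < q_threshold])
    logger.info("selected %d of %d sets at FDR < %g", len(selected), len(table), q_threshold)
    return FeatureSelection(selected, table, source=source, q_threshold=q_threshold)


def evaluate_cv(
    gsas: GsasMatrix,
    labels: pd.Series,
    features: FeatureSelection | list[str],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> CvEvaluation:
    """Repeated stratified k-fold CV of a random forest on selected features.

    Per repeat, out-of-fold class probabilities are pooled and an AUC
    computed; the headline number is the mean over repeats.  Degenerate
    folds (a training fold with one class) trigger a re-draw, at most 10
    times.
    """
    names = features.selected if isinstance(features, FeatureSelection) else list(features)
    names = [n for n in names if n in gsas.data.index]
    if not names:
        raise ValueError("no selected features present in this matrix")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    data, y = _align_labels(gsas, labels)
    x = data.loc[names].T.to_numpy()  # samples x features

    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    importance_sum = np.zeros(len(names))
    n_fits = 0
    for _ in range(repeats):
        for attempt in range(10):
            split_seed = int(rng.integers(2**31 - 1))
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)
            plan = list(skf.split(x, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in plan):
                break
            logger.warning("fold draw %d had a single-class training fold; redrawing", attempt)
        else:
            raise ValueError("could not draw valid stratified folds")
        prob = np.empty(len(y))
        for tr, te in plan:
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
            )
            rf.fit(x[tr], y[tr])
            prob[te] = rf.predict_proba(x[te])[:, list(rf.classes_).index(1)]
            importance_sum += rf.feature_importances_
            n_fits += 1
        aucs.append(float(roc_auc_score(y, prob)))
        pooled_scores.append(prob)
        pooled_truth.append(y)
    all_prob = np.concatenate(pooled_scores)
    all_truth = np.concatenate(pooled_truth)
    fpr, tpr, thr = roc_curve(all_truth, all_prob)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    importances = pd.Series(importance_sum / n_fits, index=names).sort_values(ascending=False)
    mean_auc = float(np.mean(aucs))
    logger.info("mean AUC %.3f over %d repeats (%d features)", mean_auc, repeats, len(names))
    return CvEvaluation(aucs, mean_auc, roc_points, importances, seed, folds, repeats)
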