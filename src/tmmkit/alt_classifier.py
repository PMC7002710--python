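"""Random-forest classifier of active telomere maintenance mechanism.

Eight features summarize a tumor's telomeric footprint: telomere-content
tumor/control log2 ratio, number of telomere insertions, number of genomic
breakpoints, and the divergences of TGAGGG, TCAGGG, TTGGGG, TTCGGG, and
TTTGGG singletons from their expected occurrence. A random forest trained on
ATRX/DAXX-trunc (ALT) versus TERT-mod (telomerase) samples outputs a vote
fraction interpretable as an ALT probability.

Because telomerase-driven tumors heavily outnumber ALT tumors, each
cross-validation training fold down-samples the majority class to the
minority size; every labeled sample is scored exactly once out-of-fold, and
the pooled out-of-fold scores give ROC/AUC and the 0.5-threshold operating
point.

Also provides the group-comparison statistics used throughout the analysis:
two-sided Wilcoxon rank-sum tests with Bonferroni or Benjamini-Hochberg
adjustment, Spearman correlation, and the linear models predicting telomere
insertions from telomere content and breakpoint abundance with and without an
interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
import warnings
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CLASSIFIER_FEATURES

__all__ = [
    "ALT_LABEL",
    "TERT_LABEL",
    "ClassifierReport",
    "build_feature_matrix",
    "train_classifier",
    "predict_alt_probability",
    "rank_sum_test",
    "adjust_pvalues",
    "spearman",
    "insertion_models",
]

ALT_LABEL = "ATRX_DAXX_trunc"
TERT_LABEL = "TERT_mod"


@dataclass
class ClassifierReport:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    oof_scores: pd.Series  # out-of-fold ALT probability per labeled sample
    roc_points: pd.DataFrame  # fpr, tpr, threshold on pooled scores
    feature_importances: pd.Series
    fold_sizes: list[tuple[int, int]] = field(default_factory=list)  # per-fold (n_alt, n_tert) after down-sampling


def build_feature_matrix(
    content_ratios: pd.Series,
    insertion_counts: pd.Series,
    breakpoint_counts: pd.Series,
    divergences: pd.DataFrame,
    tmm_groups: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Join the upstream per-sample outputs into the 8-feature matrix.

    All inputs are indexed by sample_id. Labels come from the TMM annotation:
    ATRX/DAXX-trunc and the TERT-mod subtypes (TERTp_mut, TERTp_SV, TERT_amp,
    TERT_mult) are labeled; mixed, non-trunc, and wild-type samples are
    "unlabeled" and excluded from training but retained for prediction.
    Samples with any missing feature are dropped.
    """
    for s in (content_ratios, insertion_counts, breakpoint_counts, tmm_groups):
        if s.index.has_duplicates:
            raise ValueError("duplicate sample_id in input")
    X = pd.DataFrame(
        {
            "content_log2_ratio": content_ratios,
            "n_telomere_insertions": insertion_counts,
            "n_breakpoints": breakpoint_counts,
        }
    )
    for pat in ("TGAGGG", "TCAGGG", "TTGGGG", "TTCGGG", "TTTGGG"):
        X[f"divergence_{pat}"] = divergences[f"divergence_{pat}"]
    X = X[list(CLASSIFIER_FEATURES)].dropna()
    tert_groups = {"TERTp_mut", "TERTp_SV", "TERT_amp", "TERT_mult"}
    labels = pd.Series("unlabeled", index=X.index, name="label")
    groups = tmm_groups.reindex(X.index)
    labels[groups == ALT_LABEL] = ALT_LABEL
    labels[groups.isin(tert_groups)] = TERT_LABEL
    return X, labels


def _downsample(y: np.ndarray, idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample: majority reduced to minority size."""
    classes, counts = np.unique(y[idx], return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        members = idx[y[idx] == c]
        if len(members) > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.append(members)
    return np.sort(np.concatenate(keep))


def train_classifier(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    n_folds: int = 10,
    n_trees: int = 500,
    threshold: float = 0.5,
    downsample: bool = True,
) -> tuple[ClassifierReport, RandomForestClassifier]:
    """Cross-validated, down-sampled random forest for ALT vs telomerase.

    Stratified ``n_folds``-fold CV; within each training fold the majority
    class is randomly down-sampled to the minority class size (per fold,
    preventing leakage across folds). Out-of-fold ALT probabilities are
    pooled for ROC/AUC; sensitivity (ALT recall) and specificity are reported
    at the given probability threshold. The returned model is refit on the
    full (down-sampled) labeled set for later prediction.
    """
    labeled = y[y != "unlabeled"].index
    X = X.loc[labeled]
    y = y.loc[labeled]
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("training requires both classes")
    counts = y.value_counts()
    if counts.min() < n_folds:
        raise ValueError(f"need at least {n_folds} samples per class for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    y_arr = (y == ALT_LABEL).to_numpy().astype(int)  # ALT is the positive class
    X_arr = X.to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y_arr), np.nan)
    fold_sizes = []
    importances = np.zeros(X_arr.shape[1])
    for k, (train_idx, test_idx) in enumerate(skf.split(X_arr, y_arr)):
        if downsample:
            train_idx = _downsample(y_arr, train_idx, rng)
        n_alt = int(y_arr[train_idx].sum())
        fold_sizes.append((n_alt, len(train_idx) - n_alt))
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(X_arr[train_idx], y_arr[train_idx])
        pos_col = list(clf.classes_).index(1)
        oof[test_idx] = clf.predict_proba(X_arr[test_idx])[:, pos_col]
        importances += clf.feature_importances_
    assert not np.isnan(oof).any(), "every labeled sample must be scored once out-of-fold"
    auc = float(roc_auc_score(y_arr, oof))
    fpr, tpr, thr = roc_curve(y_arr, oof)
    pred_pos = oof >= threshold
    tp = int((pred_pos & (y_arr == 1)).sum())
    fn = int((~pred_pos & (y_arr == 1)).sum())
    tn = int((~pred_pos & (y_arr == 0)).sum())
    fp = int((pred_pos & (y_arr == 0)).sum())
    report = ClassifierReport(
        auc=auc,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        threshold=threshold,
        oof_scores=pd.Series(oof, index=y.index, name="alt_probability"),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        feature_importances=pd.Series(importances / n_folds, index=X.columns),
        fold_sizes=fold_sizes,
    )
    final_idx = np.arange(len(y_arr))
    if downsample:
        final_idx = _downsample(y_arr, final_idx, rng)
    final = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt",
        random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
    )
    final.fit(X_arr[final_idx], y_arr[final_idx])
    return report, final


def predict_alt_probability(model: RandomForestClassifier, X: pd.DataFrame) -> pd.Series:
    """Per-sample ALT probability (fraction of trees voting ALT).

    Samples with missing features receive no prediction and are dropped from
    the result.
    """
    complete = X.dropna()
    pos_col = list(model.classes_).index(1)
    probs = model.predict_proba(complete.to_numpy())[:, pos_col]
    return pd.Series(probs, index=complete.index, name="alt_probability")


def rank_sum_test(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small tie-free inputs)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; rank-sum test is degenerate", stacklevel=2)
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else ("exact" if len(pooled) <= 30 else "auto")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: "bonferroni" or "bh" (Benjamini-Hochberg)."""
    method_map = {"bonferroni": "bonferroni", "bh": "fdr_bh"}
    if method not in method_map:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(np.asarray(pvalues, dtype=float), method=method_map[method])[1]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and p-value (rank-based, robust to outliers)."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def insertion_models(data: pd.DataFrame) -> dict[str, sm.regression.linear_model.RegressionResultsWrapper]:
    """OLS models of telomere-insertion counts on content and breakpoints.

    Fits ``n_insertions ~ content + breakpoints`` with and without the
    interaction term and returns both fitted models keyed "additive" and
    "interaction". ``data`` needs columns n_insertions, content, breakpoints.
    """
    additive = smf.ols("n_insertions ~ content + breakpoints", data=data).fit()
    interaction = smf.ols("n_insertions ~ content * breakpoints", data=data).fit()
    return {"additive": additive, "interaction": interaction}
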