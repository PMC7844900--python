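"""LC-vs-BLN diagnostic classification.

A cross-validated random-forest classifier with per-fold importance-based
feature selection, evaluated by pooled out-of-fold ROC/AUC with an
operating point at Youden's J, plus the DeLong test for comparing
correlated AUCs and a two-sample serum-marker test.

The modelling surface follows the Model/Results convention:
``DiagnosticModel(features, labels, config).fit()`` returns a
``DiagnosticResults`` carrying out-of-fold scores, AUC, sensitivity /
specificity at the chosen cutoff, the selected features and per-fold
importances, with a ``summary()`` table and a ``plot_roc()`` helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold

logger = logging.getLogger(__name__)


@dataclass
class CvConfig:
    """Cross-validation and forest settings.

    6 folds, stratified, 500 trees with sqrt(p) features per split.
    ``top_m_per_fold`` enables importance-based selection inside each
    training fold (None disables selection).
    """

    k: int = 6
    stratified: bool = True
    seed: int = 0
    n_trees: int = 500
    top_m_per_fold: Optional[int] = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class RocPoint:
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocPoint:
    """AUC by the rank (Mann-Whitney) formulation with ties counted 1/2,
    and the operating point maximizing Youden's J (ties -> lower cutoff).

    A sample is predicted positive when its score >= cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    best = None
    for c in np.unique(s):              # ascending: ties -> lower cutoff
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, sens, spec, c)
    _, sens, spec, cutoff = best
    return RocPoint(float(auc), float(sens), float(spec), float(cutoff))


def _placements(scores: np.ndarray, y: np.ndarray
                ) -> Tuple[float, np.ndarray, np.ndarray]:
    """DeLong structural components: AUC, V10 (per positive), V01 (per
    negative), with ties counted 1/2."""
    x = scores[y == 1][:, None]
    z = scores[y == 0][None, :]
    psi = (x > z).astype(float) + 0.5 * (x == z)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> Tuple[float, float, float]:
    """Two-sided DeLong test for two correlated ROC curves on the same
    samples. Returns (auc_a, auc_b, p).

    Uses the placement-value variance estimate; identical score vectors
    give p = 1 exactly.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must share length")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(a, y)
    auc_b, v10_b, v01_b = _placements(b, y)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def select_features(fold_importances: pd.DataFrame,
                    top_m_per_fold: int) -> List[str]:
    """Union over folds of each fold's top-m features by importance.

    ``fold_importances`` is folds x features. Ties are broken by feature
    id order; m exceeding the feature count selects all features (with a
    warning).
    """
    features = list(fold_importances.columns)
    if top_m_per_fold >= len(features):
        if top_m_per_fold > len(features):
            logger.warning("top_m_per_fold=%d exceeds the %d features; "
                           "selecting all", top_m_per_fold, len(features))
        return sorted(features)
    selected: set = set()
    for _, row in fold_importances.iterrows():
        order = sorted(features, key=lambda f: (-row[f], f))
        selected.update(order[:top_m_per_fold])
    return sorted(selected)


def reduction_pct(n_selected: int, n_candidates: int) -> float:
    """Feature-size reduction as a percentage (e.g. 47 of 293 -> 84.0)."""
    return round(100.0 * (1.0 - n_selected / n_candidates), 1)


@dataclass
class DiagnosticResults:
    """Out-of-fold evaluation of a cross-validated diagnostic model."""

    oof_scores: pd.Series
    labels: pd.Series
    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    selected_features: List[str]
    fold_importances: pd.DataFrame
    config: CvConfig

    def summary(self) -> str:
        lines = [
            "Cross-validated diagnostic model",
            "================================",
            f"samples:            {len(self.oof_scores)}"
            f" ({int((self.labels == 1).sum())} pos /"
            f" {int((self.labels == 0).sum())} neg)",
            f"folds:              {self.config.k}"
            f" (stratified={self.config.stratified})",
            f"trees per forest:   {self.config.n_trees}",
            f"AUC (pooled OOF):   {self.auc:.3f}",
            f"sensitivity:        {100 * self.sensitivity:.1f}%",
            f"specificity:        {100 * self.specificity:.1f}%",
            f"cutoff (Youden J):  {self.cutoff:.4g}",
        ]
        if self.config.top_m_per_fold is not None:
            n_cand = self.fold_importances.shape[1]
            n_sel = len(self.selected_features)
            lines.append(
                f"features:           {n_sel} of {n_cand} selected "
                f"({reduction_pct(n_sel, n_cand):.1f}% reduction)")
        return "\n".join(lines)

    def roc_points(self) -> pd.DataFrame:
        """FPR/TPR pairs over all score cutoffs (for plotting/export)."""
        s = self.oof_scores.to_numpy()
        y = self.labels.to_numpy()
        rows = [(1.0, 1.0)]
        for c in np.unique(s):
            pred = s >= c
            rows.append((float((pred & (y == 0)).sum() / (y == 0).sum()),
                         float((pred & (y == 1)).sum() / (y == 1).sum())))
        rows.append((0.0, 0.0))
        return pd.DataFrame(sorted(set(rows)), columns=["fpr", "tpr"])

    def plot_roc(self, ax=None, label: Optional[str] = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.roc_points()
        ax.plot(pts["fpr"], pts["tpr"],
                label=label or f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


class DiagnosticModel:
    """Cross-validated random-forest classifier for LC vs BLN plasma.

    ``features`` is a samples x features DataFrame without missing values
    (impute upstream); ``labels`` are 1 = LC, 0 = BLN aligned to its
    index. When ``config.top_m_per_fold`` is set, each training fold
    first fits a forest on all features, keeps that fold's top-m by
    importance, and refits on the reduced set before scoring the held-out
    fold — the selection never sees the test fold.
    """

    def __init__(self, features: pd.DataFrame, labels: Sequence[int],
                 config: Optional[CvConfig] = None):
        if features.isna().any().any():
            raise ValueError("features contain missing values; "
                             "impute before modelling")
        self.features = features
        self.labels = pd.Series(np.asarray(labels).astype(int),
                                index=features.index, name="label")
        if self.labels.nunique() != 2:
            raise ValueError("labels must contain exactly two classes")
        self.config = config or CvConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       config: Optional[CvConfig] = None
                       ) -> "DiagnosticModel":
        labels = df[label_col]
        return cls(df.drop(columns=[label_col]), labels, config)

    def fit(self) -> DiagnosticResults:
        cfg = self.config
        X = self.features.to_numpy(float)
        y = self.labels.to_numpy()
        if cfg.stratified:
            splitter = StratifiedKFold(cfg.k, shuffle=True,
                                       random_state=cfg.seed)
            splits = splitter.split(X, y)
        else:
            splitter = KFold(cfg.k, shuffle=True, random_state=cfg.seed)
            splits = splitter.split(X)

        oof = np.full(len(y), np.nan)
        importances = []
        cols = list(self.features.columns)
        for fold, (tr, te) in enumerate(splits):
            if len(np.unique(y[tr])) < 2:
                raise ValueError(
                    "a training fold lacks one class; use stratified "
                    "cross-validation")
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees, max_features="sqrt",
                random_state=cfg.seed + fold, n_jobs=1)
            rf.fit(X[tr], y[tr])
            imp = pd.Series(rf.feature_importances_, index=cols)
            importances.append(imp)
            use = list(range(len(cols)))
            if cfg.top_m_per_fold is not None:
                fold_sel = select_features(imp.to_frame().T,
                                           cfg.top_m_per_fold)
                use = [cols.index(f) for f in fold_sel]
                rf = RandomForestClassifier(
                    n_estimators=cfg.n_trees, max_features="sqrt",
                    random_state=cfg.seed + fold, n_jobs=1)
                rf.fit(X[tr][:, use], y[tr])
            oof[te] = rf.predict_proba(X[te][:, use])[:, 1]

        fold_imp = pd.DataFrame(importances,
                                index=[f"fold{j + 1}" for j in
                                       range(len(importances))])
        if cfg.top_m_per_fold is not None:
            selected = select_features(fold_imp, cfg.top_m_per_fold)
        else:
            selected = cols
        roc = roc_auc(oof, y)
        return DiagnosticResults(
            oof_scores=pd.Series(oof, index=self.features.index,
                                 name="oof_score"),
            labels=self.labels, auc=roc.auc, sensitivity=roc.sensitivity,
            specificity=roc.specificity, cutoff=roc.cutoff,
            selected_features=selected, fold_importances=fold_imp,
            config=cfg)


def cv_oof_scores(features: pd.DataFrame, labels: Sequence[int],
                  config: Optional[CvConfig] = None) -> DiagnosticResults:
    """Functional wrapper: fit a :class:`DiagnosticModel` and return its
    results."""
    return DiagnosticModel(features, labels, config).fit()


def _raw_score_eval(score: pd.Series, labels: pd.Series) -> DiagnosticResults:
    """Evaluate a raw univariate score (no model fitting) as a classifier."""
    roc = roc_auc(score.to_numpy(float), labels.to_numpy())
    return DiagnosticResults(
        oof_scores=score.rename("oof_score"), labels=labels,
        auc=roc.auc, sensitivity=roc.sensitivity,
        specificity=roc.specificity, cutoff=roc.cutoff,
        selected_features=[score.name or "score"],
        fold_importances=pd.DataFrame(), config=CvConfig())


def combine_omics(dmr_features: pd.DataFrame, mut_score: pd.Series,
                  cea: Optional[pd.Series], labels: pd.Series,
                  config: Optional[CvConfig] = None
                  ) -> Dict[str, DiagnosticResults]:
    """Evaluate single-analyte and combined diagnostic models on the
    samples with complete measurements.

    Returns a dict of evaluations: 'methylation' (CV forest on DMR
    betas), 'mutation' and 'cea' (raw-score ROC, as for a univariate
    marker), 'methylation+mutation', and — when CEA is supplied —
    'methylation+mutation+cea'. All models are evaluated on the identical
    sample intersection so their AUCs are DeLong-comparable.
    """
    config = config or CvConfig()
    ids = dmr_features.dropna().index.intersection(mut_score.dropna().index)
    ids = ids.intersection(labels.dropna().index)
    if cea is not None:
        ids = ids.intersection(cea.dropna().index)
    if len(ids) == 0:
        raise ValueError("no sample has complete measurements for all "
                         "requested analytes")
    feats = dmr_features.loc[ids]
    mut = mut_score.loc[ids].astype(float).rename("wsumaf")
    y = labels.loc[ids].astype(int)

    out: Dict[str, DiagnosticResults] = {}
    out["methylation"] = DiagnosticModel(feats, y, config).fit()
    out["mutation"] = _raw_score_eval(mut, y)
    bi = feats.assign(wsumaf=mut)
    out["methylation+mutation"] = DiagnosticModel(bi, y, config).fit()
    if cea is not None:
        cea_al = cea.loc[ids].astype(float).rename("cea")
        out["cea"] = _raw_score_eval(cea_al, y)
        tri = bi.assign(cea=cea_al)
        out["methylation+mutation+cea"] = DiagnosticModel(tri, y,
                                                          config).fit()
    return out


def marker_test(values_pos: Sequence[float], values_neg: Sequence[float],
                equal_var: bool = True) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test plus ROC AUC for one serum marker.

    Returns (t statistic, p, AUC of the raw marker with positives coded
    1). Equal-variance Student's t by default; ``equal_var=False`` gives
    Welch's test. Degenerate zero-variance, equal-mean groups return
    (0, 1, auc).
    """
    a = np.asarray(values_pos, dtype=float)
    b = np.asarray(values_neg, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):
        t, p = 0.0, 1.0
    scores = np.concatenate([a, b])
    y = np.concatenate([np.ones(a.size, int), np.zeros(b.size, int)])
    return float(t), float(p), roc_auc(scores, y).auc
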