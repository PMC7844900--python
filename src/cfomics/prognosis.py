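"""Survival modelling: L1-penalized Cox feature selection, the
methylation prognostic score (MPS), bi-omics risk grouping, Kaplan-Meier
/ log-rank analysis, and nested Cox model comparison.

The MPS of a sample is the dot product of the penalized-Cox coefficients
with the sample's selected DMR methylation betas; combining it with the
mutation burden (wSUMAF) yields the bi-omics prognosis group: high risk
iff the mutation score is above 0 AND the MPS is above the training-set
median.

Fitting follows the Model/Results convention: ``PenalizedCoxModel(...)
.fit()`` returns a ``PenalizedCoxFit``; ``compare_nested_cox`` returns a
``CoxCompareResult``; both expose ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)


@dataclass
class PenaltyConfig:
    """How the L1 penalty strength is chosen.

    mode='target' (default) walks the regularization path and keeps the
    strongest penalty whose active set is closest to ``target_features``
    (12, the size of the published prognostic signature); mode='cv'
    chooses the path alpha maximizing k-fold cross-validated concordance;
    mode='fixed' uses ``alpha`` as given.
    """

    mode: str = "target"
    target_features: int = 12
    alpha: Optional[float] = None
    cv_k: int = 5
    l1_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("target", "cv", "fixed"):
            raise ValueError("mode must be 'target', 'cv' or 'fixed'")
        if self.mode == "fixed" and self.alpha is None:
            raise ValueError("mode='fixed' requires alpha")


@dataclass
class PenalizedCoxFit:
    """Results of an L1-penalized Cox fit."""

    coefficients: pd.Series          # all features; zero outside `selected`
    penalty: float
    selected: List[str]
    train_ids: List[str]

    def summary(self) -> str:
        lines = ["Penalized Cox fit",
                 "=================",
                 f"training samples:  {len(self.train_ids)}",
                 f"penalty (alpha):   {self.penalty:.5g}",
                 f"selected features: {len(self.selected)} of "
                 f"{len(self.coefficients)}"]
        for name in self.selected:
            lines.append(f"  {name:<24s} {self.coefficients[name]:+.4f}")
        return "\n".join(lines)


class PenalizedCoxModel:
    """L1-penalized Cox proportional-hazards model on feature matrices.

    ``features`` is samples x features (no missing values), ``survival``
    a table with sample_id, time_months and event aligned to the feature
    index. ``fit()`` maximizes the L1-penalized partial likelihood along
    a regularization path and picks the penalty per ``PenaltyConfig``.
    """

    def __init__(self, features: pd.DataFrame, survival: pd.DataFrame,
                 config: Optional[PenaltyConfig] = None):
        surv = survival.set_index("sample_id") \
            if "sample_id" in survival.columns else survival
        surv = surv.loc[features.index]
        if int(surv["event"].sum()) == 0:
            raise ValueError("no events in the training data")
        if int(surv["event"].sum()) < 2:
            raise ValueError("need at least 2 events")
        if features.isna().any().any():
            raise ValueError("features contain missing values")
        self.features = features
        self.time = surv["time_months"].to_numpy(float)
        self.event = surv["event"].to_numpy(int)
        self.config = config or PenaltyConfig()

    def _path(self) -> Tuple[np.ndarray, np.ndarray]:
        y = Surv.from_arrays(self.event.astype(bool), self.time)
        model = CoxnetSurvivalAnalysis(l1_ratio=self.config.l1_ratio,
                                       n_alphas=100, fit_baseline_model=False)
        model.fit(self.features.to_numpy(float), y)
        return np.asarray(model.alphas_), np.asarray(model.coef_)

    def _choose_alpha(self, alphas: np.ndarray, coefs: np.ndarray) -> float:
        cfg = self.config
        if cfg.mode == "fixed":
            return float(cfg.alpha)
        if cfg.mode == "target":
            n_active = (np.abs(coefs) > 0).sum(axis=0)
            # alphas_ descend; pick the closest active-set size, breaking
            # ties toward the stronger penalty (earlier on the path)
            gap = np.abs(n_active - cfg.target_features)
            return float(alphas[int(np.argmin(gap))])
        # mode == "cv": k-fold concordance along a subsampled path
        from sklearn.model_selection import KFold
        from sksurv.metrics import concordance_index_censored

        grid = alphas[:: max(1, len(alphas) // 20)]
        kf = KFold(cfg.cv_k, shuffle=True, random_state=cfg.seed)
        X = self.features.to_numpy(float)
        best_alpha, best_score = float(grid[0]), -np.inf
        for a in grid:
            scores = []
            for tr, te in kf.split(X):
                if self.event[tr].sum() < 2 or self.event[te].sum() < 1:
                    continue
                y_tr = Surv.from_arrays(self.event[tr].astype(bool),
                                        self.time[tr])
                m = CoxnetSurvivalAnalysis(l1_ratio=cfg.l1_ratio,
                                           alphas=[a],
                                           fit_baseline_model=False)
                try:
                    m.fit(X[tr], y_tr)
                except (ValueError, ArithmeticError):
                    continue
                risk = m.predict(X[te])
                if np.allclose(risk, risk[0]):
                    scores.append(0.5)
                    continue
                c = concordance_index_censored(
                    self.event[te].astype(bool), self.time[te], risk)[0]
                scores.append(c)
            if scores and np.mean(scores) > best_score:
                best_score, best_alpha = float(np.mean(scores)), float(a)
        return best_alpha

    def fit(self) -> PenalizedCoxFit:
        alphas, coefs = self._path()
        alpha = self._choose_alpha(alphas, coefs)
        y = Surv.from_arrays(self.event.astype(bool), self.time)
        final = CoxnetSurvivalAnalysis(l1_ratio=self.config.l1_ratio,
                                       alphas=[alpha],
                                       fit_baseline_model=False)
        final.fit(self.features.to_numpy(float), y)
        coef = pd.Series(final.coef_[:, 0], index=self.features.columns,
                         name="coef")
        selected = list(coef.index[coef.abs() > 0])
        return PenalizedCoxFit(coefficients=coef, penalty=alpha,
                               selected=selected,
                               train_ids=list(self.features.index))


def fit_penalized_cox(features: pd.DataFrame, survival: pd.DataFrame,
                      config: Optional[PenaltyConfig] = None
                      ) -> PenalizedCoxFit:
    """Functional wrapper over :class:`PenalizedCoxModel`."""
    return PenalizedCoxModel(features, survival, config).fit()


def mps(beta: pd.DataFrame, fit: PenalizedCoxFit) -> pd.Series:
    """Methylation prognostic score: coefficient-weighted sum of the
    selected DMR betas per sample.

    Raises KeyError naming the first selected feature absent from
    ``beta``. Zero-coefficient features never contribute.
    """
    for name in fit.selected:
        if name not in beta.columns:
            raise KeyError(f"selected feature {name!r} missing from the "
                           "beta matrix")
    if not fit.selected:
        return pd.Series(0.0, index=beta.index, name="mps")
    vals = beta[fit.selected].to_numpy(float) @ \
        fit.coefficients[fit.selected].to_numpy(float)
    return pd.Series(vals, index=beta.index, name="mps")


def risk_group(mut_score: pd.Series, mps_score: pd.Series,
               mps_cutoff: float) -> pd.Series:
    """Bi-omics prognosis group: 'high' iff wSUMAF > 0 AND MPS > cutoff.

    Scores exactly at a boundary fall in the low group (strict
    inequalities). Samples missing either score are excluded with a
    warning.
    """
    ids = mut_score.dropna().index.intersection(mps_score.dropna().index)
    n_lost = max(len(mut_score), len(mps_score)) - len(ids)
    if n_lost > 0:
        logger.warning("excluding %d sample(s) missing a prognosis score",
                       n_lost)
    high = (mut_score.loc[ids] > 0) & (mps_score.loc[ids] > mps_cutoff)
    return pd.Series(np.where(high, "high", "low"), index=ids,
                     name="risk_group")


@dataclass
class KmResult:
    """Kaplan-Meier curves per group plus the log-rank test."""

    curves: Dict[str, pd.DataFrame]   # group -> (time, survival) points
    statistic: float
    df: int
    p: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for group, pts in self.curves.items():
            ax.step(pts["time"], pts["survival"], where="post", label=group)
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.05)
        ax.legend(title=f"log-rank p = {self.p:.3g}")
        return ax


def km_logrank(survival: pd.DataFrame, groups: pd.Series) -> KmResult:
    """Product-limit survival curves per group and the log-rank test.

    ``survival`` carries sample_id, time_months, event; ``groups`` maps
    sample_id to a group label (>= 2 groups, each non-empty). When no
    events occur at all the test is undefined and p is NaN (flagged by a
    warning).
    """
    surv = survival.set_index("sample_id") \
        if "sample_id" in survival.columns else survival
    ids = surv.index.intersection(groups.index)
    surv = surv.loc[ids]
    grp = groups.loc[ids]
    levels = sorted(grp.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    curves = {}
    for g in levels:
        sel = grp == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[sel, "time_months"], surv.loc[sel, "event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(g)] = sf
    if int(surv["event"].sum()) == 0:
        logger.warning("all subjects censored; log-rank p undefined")
        return KmResult(curves, float("nan"), len(levels) - 1, float("nan"))
    res = multivariate_logrank_test(surv["time_months"], grp, surv["event"])
    return KmResult(curves, float(res.test_statistic), len(levels) - 1,
                    float(res.p_value))


@dataclass
class CoxCompareResult:
    """Nested Cox model comparison (A subset of B)."""

    concordance_a: float
    concordance_b: float
    lrt_statistic: float
    df: int
    p: float
    fit_a: CoxPHFitter = field(repr=False, default=None)
    fit_b: CoxPHFitter = field(repr=False, default=None)

    def summary(self) -> str:
        return "\n".join([
            "Nested Cox model comparison",
            "===========================",
            f"concordance (reduced): {self.concordance_a:.3f}",
            f"concordance (full):    {self.concordance_b:.3f}",
            f"LRT chi2 = {self.lrt_statistic:.3f} on {self.df} df, "
            f"p = {self.p:.3g}",
        ])


def compare_nested_cox(survival: pd.DataFrame, covariates: pd.DataFrame,
                       covars_a: Sequence[str],
                       covars_b: Sequence[str]) -> CoxCompareResult:
    """Fit two nested unpenalized Cox models and compare them.

    ``covars_a`` must be a subset of ``covars_b``. Reports Harrell's
    concordance per model and the likelihood-ratio test p-value with
    df = |B| - |A|; identical covariate sets give statistic 0, p = 1.
    Ties in the partial likelihood use the Efron approximation
    (lifelines' default).
    """
    set_a, set_b = set(covars_a), set(covars_b)
    if not set_a <= set_b:
        raise ValueError("covars_a must be a subset of covars_b")
    surv = survival.set_index("sample_id") \
        if "sample_id" in survival.columns else survival
    df_all = covariates.join(surv[["time_months", "event"]], how="inner")

    def _fit(cols):
        cph = CoxPHFitter()
        cph.fit(df_all[list(cols) + ["time_months", "event"]],
                duration_col="time_months", event_col="event")
        return cph

    fit_a = _fit(sorted(set_a))
    if set_a == set_b:
        return CoxCompareResult(fit_a.concordance_index_,
                                fit_a.concordance_index_, 0.0, 0, 1.0,
                                fit_a, fit_a)
    fit_b = _fit(sorted(set_b))
    lrt = max(0.0, 2.0 * (fit_b.log_likelihood_ - fit_a.log_likelihood_))
    dof = len(set_b) - len(set_a)
    p = float(stats.chi2.sf(lrt, dof))
    return CoxCompareResult(fit_a.concordance_index_,
                            fit_b.concordance_index_, lrt, dof, p,
                            fit_a, fit_b)


def split_survival(survival: pd.DataFrame, test_frac: float = 0.3,
                   seed: int = 0) -> Tuple[List[str], List[str]]:
    """Stratified (by event status) train/test split of sample ids."""
    from sklearn.model_selection import train_test_split

    ids = survival["sample_id"].to_numpy()
    train, test = train_test_split(ids, test_size=test_frac,
                                   random_state=seed,
                                   stratify=survival["event"].to_numpy())
    return list(train), list(test)
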