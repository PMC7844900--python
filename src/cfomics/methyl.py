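"""Regional methylation ratios, tumor-vs-NAT DMR calling, hierarchical
clustering and plasma feature matrices.

The regional methylation ratio (beta) of a region is the pooled
methylated-count / total-count over its CpGs; a region x sample entry is
missing when sequencing depth is insufficient. Differentially methylated
regions (DMRs) are called from paired tumor / adjacent-normal (NAT)
tissue betas with an effect-size threshold on the mean difference
("methy.diff") plus a BH-corrected paired test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class DmrParams:
    """Thresholds for DMR calling.

    ``diff_threshold`` is the minimum absolute tumor-minus-NAT mean beta
    difference (0.2, the methy.diff cutoff); ``q_threshold`` the BH FDR
    level; regions need ``min_region_depth`` pooled reads and ``min_cpg``
    covered CpGs to yield a beta, and ``min_pairs`` non-missing pairs to
    be tested. ``test`` selects the paired test ('wilcoxon' or 'ttest').
    """

    diff_threshold: float = 0.2
    q_threshold: float = 0.05
    min_region_depth: int = 10
    min_cpg: int = 3
    min_pairs: int = 10
    test: str = "wilcoxon"

    def __post_init__(self):
        if not (0.0 < self.diff_threshold < 1.0):
            raise ValueError("diff_threshold must be in (0, 1)")
        if self.test not in ("wilcoxon", "ttest"):
            raise ValueError("test must be 'wilcoxon' or 'ttest'")


def _region_ids(regions: pd.DataFrame) -> pd.Series:
    if "region_id" in regions.columns:
        return regions["region_id"]
    return (regions["chrom"].astype(str) + ":"
            + regions["start"].astype(str) + "-"
            + regions["end"].astype(str))


def regional_beta(cpg_counts: pd.DataFrame, regions: pd.DataFrame,
                  min_region_depth: int = 10,
                  min_cpg: int = 3) -> pd.DataFrame:
    """Pool CpG counts into per-region, per-sample methylation ratios.

    ``cpg_counts`` is a long table (sample_id, chrom, pos0, pos1,
    meth_count, total_count); ``regions`` holds non-overlapping
    (chrom, start, end) intervals, 0-based half-open. Returns a long
    table (region_id, sample_id, beta, n_cpg, depth) where beta is NaN
    when depth < ``min_region_depth`` or covered CpGs < ``min_cpg``.
    """
    regions = regions.copy()
    if (regions["end"] <= regions["start"]).any():
        bad = regions[regions["end"] <= regions["start"]].iloc[0]
        raise ValueError(
            f"region {bad['chrom']}:{bad['start']}-{bad['end']} is empty")
    regions["region_id"] = _region_ids(regions)
    bad_counts = ((cpg_counts["meth_count"] < 0)
                  | (cpg_counts["meth_count"] > cpg_counts["total_count"]))
    if bad_counts.any():
        raise ValueError("meth_count must satisfy 0 <= meth <= total")

    pieces = []
    for chrom, reg_c in regions.groupby("chrom", sort=False):
        reg_c = reg_c.sort_values("start")
        cpg_c = cpg_counts[cpg_counts["chrom"] == chrom]
        if len(cpg_c) == 0:
            continue
        starts = reg_c["start"].to_numpy()
        ends = reg_c["end"].to_numpy()
        idx = np.searchsorted(starts, cpg_c["pos0"].to_numpy(),
                              side="right") - 1
        inside = (idx >= 0) & (cpg_c["pos0"].to_numpy() < ends[
            np.clip(idx, 0, len(ends) - 1)])
        assigned = cpg_c.loc[inside].copy()
        assigned["region_id"] = reg_c["region_id"].to_numpy()[idx[inside]]
        pieces.append(assigned)

    if not pieces:
        return pd.DataFrame(
            columns=["region_id", "sample_id", "beta", "n_cpg", "depth"])
    assigned = pd.concat(pieces, ignore_index=True)
    grouped = assigned.groupby(["region_id", "sample_id"]).agg(
        meth=("meth_count", "sum"), depth=("total_count", "sum"),
        n_cpg=("pos0", "nunique")).reset_index()
    ok = (grouped["depth"] >= min_region_depth) & (grouped["n_cpg"] >= min_cpg)
    grouped["beta"] = np.where(ok, grouped["meth"] / grouped["depth"], np.nan)
    return grouped[["region_id", "sample_id", "beta", "n_cpg", "depth"]]


def beta_matrix(beta_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long regional-beta table into samples x regions."""
    return beta_long.pivot(index="sample_id", columns="region_id",
                           values="beta")


def _paired_p(diffs: np.ndarray, test: str) -> float:
    if np.allclose(diffs, 0.0):
        return 1.0
    if test == "ttest":
        return float(stats.ttest_1samp(diffs, 0.0).pvalue)
    try:
        return float(stats.wilcoxon(diffs).pvalue)
    except ValueError:   # e.g. all differences zero after rounding
        return 1.0


def call_dmrs(tumor_beta: pd.DataFrame, nat_beta: pd.DataFrame,
              params: Optional[DmrParams] = None) -> pd.DataFrame:
    """Call DMRs from paired tumor / NAT regional betas.

    Both inputs are regions x pairs matrices with identical, aligned
    columns (one column per tissue pair). Per region with at least
    ``min_pairs`` non-missing pairs, the mean paired difference and a
    paired test p-value are computed; p-values are BH-corrected across
    tested regions and a DMR is emitted iff q < ``q_threshold`` and
    |mean_diff| > ``diff_threshold``. Direction is hyper for positive
    differences (tumor more methylated), hypo for negative.
    """
    params = params or DmrParams()
    if list(tumor_beta.columns) != list(nat_beta.columns):
        raise ValueError("tumor and NAT matrices must share pair columns")
    common = tumor_beta.index.intersection(nat_beta.index)
    t = tumor_beta.loc[common].to_numpy(float)
    n = nat_beta.loc[common].to_numpy(float)
    diffs = t - n
    ok_pairs = ~np.isnan(diffs)

    tested_regions, mean_diffs, pvals = [], [], []
    for i, region in enumerate(common):
        d = diffs[i, ok_pairs[i]]
        if d.size < params.min_pairs:
            continue
        tested_regions.append(region)
        mean_diffs.append(float(d.mean()))
        pvals.append(_paired_p(d, params.test))

    if not tested_regions:
        logger.warning("no region passed the missingness filter")
        return pd.DataFrame(columns=["region_id", "mean_diff", "direction",
                                     "p", "q"])
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({"region_id": tested_regions,
                        "mean_diff": mean_diffs, "p": pvals, "q": q})
    out = out[(out["q"] < params.q_threshold)
              & (out["mean_diff"].abs() > params.diff_threshold)].copy()
    out["direction"] = np.where(out["mean_diff"] > 0, "hyper", "hypo")
    if len(out) == 0:
        logger.warning("no DMR passed the thresholds")
    return out[["region_id", "mean_diff", "direction", "p", "q"]] \
        .reset_index(drop=True)


def cluster_samples(beta: pd.DataFrame, n_clusters: int = 2
                    ) -> Tuple[pd.Series, np.ndarray, List[str]]:
    """Agglomerative clustering of samples on their beta profiles.

    Distances are Euclidean on pairwise-complete entries (missing values
    tolerated, as in heatmaps with insufficient-depth gaps); linkage is
    average. Samples with all features missing are excluded with a
    warning. Returns (cluster labels 1..k, scipy linkage matrix, kept
    sample ids).
    """
    if len(beta) < 2:
        raise ValueError("need at least 2 samples to cluster")
    all_missing = beta.isna().all(axis=1)
    if all_missing.any():
        logger.warning("excluding %d sample(s) with all-missing features",
                       int(all_missing.sum()))
    kept = beta.loc[~all_missing]
    dist = nan_euclidean_distances(kept.to_numpy(float))
    finite = np.isfinite(dist)
    if not finite.all():
        # pairs with no overlapping features: push them far apart
        dist[~finite] = np.nanmax(dist[finite]) * 1.01
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return (pd.Series(labels, index=kept.index, name="cluster"),
            linkage, list(kept.index))


def plasma_features(plasma_beta: pd.DataFrame,
                    dmr_regions: Sequence[str]
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a plasma beta matrix to DMR features and impute gaps.

    Features absent from the plasma matrix (or never measured) are
    dropped with a warning; remaining missing entries are imputed with
    that feature's cohort median. Returns (feature matrix, boolean mask of
    imputed entries).
    """
    present = [r for r in dmr_regions if r in plasma_beta.columns]
    dropped = [r for r in dmr_regions if r not in plasma_beta.columns]
    feats = plasma_beta[present].copy()
    all_missing = feats.isna().all(axis=0)
    if all_missing.any():
        dropped += list(feats.columns[all_missing])
        feats = feats.loc[:, ~all_missing]
    if dropped:
        logger.warning("dropped %d DMR feature(s) absent from the plasma "
                       "assay: %s", len(dropped), dropped[:5])
    imputed = feats.isna()
    feats = feats.fillna(feats.median(axis=0))
    return feats, imputed
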