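"""Clonal-hematopoiesis filtering, AF correlation, mutation burden scores
and cohort summary statistics.

Clonal hematopoiesis (CH) seeds plasma cfDNA with blood-derived somatic
variants that masquerade as tumor signal; matching each cfDNA variant
against the same patient's white-blood-cell (WBC) genomic DNA separates
tumor-derived ("somatic") from WBC-shared variants. The per-sample burden
scores are SUMAF (sum of somatic allele fractions) and wSUMAF (hotspot-
weighted sum, median-centered so the cohort splits at zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos_1based", "ref", "alt"]
MATCH_KEY = ["patient_id"] + VARIANT_KEY


@dataclass
class WeightScheme:
    """Hotspot weighting for wSUMAF.

    TCGA driver hotspots and COSMIC hotspots are up-weighted relative to
    other variants; a variant carrying both flags combines the two
    weights by ``combine_rule`` ('max' or 'sum').
    """

    w_base: float = 1.0
    w_tcga: float = 3.0
    w_cosmic: float = 2.0
    combine_rule: str = "max"

    def __post_init__(self):
        if min(self.w_base, self.w_tcga, self.w_cosmic) <= 0:
            raise ValueError("weights must be > 0")
        if self.w_tcga < self.w_base or self.w_cosmic < self.w_base:
            raise ValueError("hotspot weights must be >= w_base")
        if self.combine_rule not in ("max", "sum"):
            raise ValueError("combine_rule must be 'max' or 'sum'")

    def weight(self, tcga: bool, cosmic: bool) -> float:
        if tcga and cosmic:
            return (max(self.w_tcga, self.w_cosmic)
                    if self.combine_rule == "max"
                    else self.w_tcga + self.w_cosmic)
        if tcga:
            return self.w_tcga
        if cosmic:
            return self.w_cosmic
        return self.w_base


def filter_ch(cf_variants: pd.DataFrame,
              wbc_variants: pd.DataFrame
              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cfDNA variants into tumor-derived and WBC-shared.

    A cfDNA variant is WBC-shared iff a WBC record with the identical
    (patient_id, chrom, pos, ref, alt) key exists. The partition is
    exhaustive and disjoint. Patients absent from the WBC table keep all
    their variants as somatic (WBC was only assayed for cfDNA-positive
    participants); a warning is logged for them.
    """
    if len(cf_variants) == 0:
        return cf_variants.copy(), cf_variants.copy()
    if len(wbc_variants) == 0:
        return cf_variants.copy(), cf_variants.iloc[0:0].copy()
    missing = set(cf_variants["patient_id"]) - set(wbc_variants["patient_id"])
    if missing:
        logger.warning(
            "%d patient(s) have cfDNA variants but no WBC record; their "
            "variants are retained as somatic", len(missing))
    wbc_keys = wbc_variants[MATCH_KEY].drop_duplicates()
    merged = cf_variants.merge(wbc_keys, on=MATCH_KEY, how="left",
                               indicator=True)
    shared_mask = (merged["_merge"] == "both").to_numpy()
    somatic = cf_variants.loc[~shared_mask].copy()
    shared = cf_variants.loc[shared_mask].copy()
    return somatic, shared


def shared_af_pairs(cf_variants: pd.DataFrame,
                    wbc_variants: pd.DataFrame) -> pd.DataFrame:
    """AF pairs (cf_af, wbc_af) for variants found in both compartments."""
    wbc = wbc_variants[MATCH_KEY + ["af"]].rename(columns={"af": "wbc_af"})
    wbc = wbc.drop_duplicates(subset=MATCH_KEY)
    merged = cf_variants.merge(wbc, on=MATCH_KEY, how="inner")
    return merged.rename(columns={"af": "cf_af"})[["cf_af", "wbc_af"]]


def af_correlation(cf_af: Sequence[float],
                   wbc_af: Sequence[float]) -> float:
    """Pearson correlation of cfDNA vs WBC allele fractions on log10 scale."""
    cf = np.asarray(cf_af, dtype=float)
    wbc = np.asarray(wbc_af, dtype=float)
    if cf.shape != wbc.shape:
        raise ValueError("cf_af and wbc_af must have equal length")
    if cf.size < 3:
        raise ValueError("need at least 3 AF pairs for a correlation")
    if np.any(cf <= 0) or np.any(wbc <= 0):
        raise ValueError("allele fractions must be > 0 for log scaling")
    r, _ = stats.pearsonr(np.log10(cf), np.log10(wbc))
    return float(r)


def sumaf(afs: Iterable[float]) -> float:
    """Sum of somatic allele fractions for one sample (0 when none)."""
    total = 0.0
    for af in afs:
        if not (0.0 < af <= 1.0):
            raise ValueError(f"allele fraction {af} outside (0, 1]")
        total += af
    return total


def wsumaf(variants: pd.DataFrame,
           weights: Optional[WeightScheme] = None) -> float:
    """Hotspot-weighted sum of allele fractions for one sample's variants.

    ``variants`` needs ``af``, ``tcga_hotspot`` and ``cosmic_hotspot``
    columns. Equals :func:`sumaf` when all weights are 1.
    """
    weights = weights or WeightScheme()
    total = 0.0
    for row in variants.itertuples(index=False):
        if not (0.0 < row.af <= 1.0):
            raise ValueError(f"allele fraction {row.af} outside (0, 1]")
        total += weights.weight(bool(row.tcga_hotspot),
                                bool(row.cosmic_hotspot)) * row.af
    return total


def center_score(scores: Sequence[float]) -> np.ndarray:
    """Subtract the cohort median so the score's sign splits the cohort."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot center an empty score vector")
    return arr - np.median(arr)


def score_samples(somatic_variants: pd.DataFrame,
                  sample_ids: Sequence[str],
                  weights: Optional[WeightScheme] = None) -> pd.DataFrame:
    """Per-sample SUMAF / wSUMAF table over a cohort.

    Samples without somatic variants score 0; ``wsumaf`` is the raw
    weighted sum centered at the cohort median, so ``wsumaf > 0`` marks
    the high-burden half of the cohort.
    """
    weights = weights or WeightScheme()
    by_sample = dict(tuple(somatic_variants.groupby("sample_id"))) \
        if len(somatic_variants) else {}
    rows = []
    for sid in sample_ids:
        sub = by_sample.get(sid)
        if sub is None or len(sub) == 0:
            rows.append({"sample_id": sid, "sumaf": 0.0, "wsumaf_raw": 0.0})
        else:
            rows.append({"sample_id": sid, "sumaf": sumaf(sub["af"]),
                         "wsumaf_raw": wsumaf(sub, weights)})
    out = pd.DataFrame(rows, columns=["sample_id", "sumaf", "wsumaf_raw"])
    out["wsumaf"] = center_score(out["wsumaf_raw"].to_numpy())
    return out


def chi_squared(table) -> Tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x k count table.

    No continuity correction (matches how the cohort contrasts are
    reported). Returns (statistic, degrees of freedom, two-sided p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x k table with r, k >= 2")
    if np.any(arr < 0):
        raise ValueError("counts must be >= 0")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("every row and column marginal must be > 0")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _group_stats(cf: pd.DataFrame, shared_mask: np.ndarray,
                 samples: pd.DataFrame) -> dict:
    n_samples = len(samples)
    n_variants = len(cf)
    n_shared = int(shared_mask.sum())
    somatic = cf.loc[~shared_mask]
    pos_samples = somatic["sample_id"].nunique()
    hot = (somatic["tcga_hotspot"].astype(bool)
           | somatic["cosmic_hotspot"].astype(bool))
    gene_freq = {}
    if n_samples and len(somatic):
        per_gene = somatic.groupby("gene")["sample_id"].nunique()
        gene_freq = (per_gene / n_samples).sort_values(
            ascending=False).to_dict()
    return {
        "n_samples": n_samples,
        "n_cf_variants": n_variants,
        "n_shared": n_shared,
        "n_somatic": n_variants - n_shared,
        "shared_frac": n_shared / n_variants if n_variants else float("nan"),
        "n_positive_samples": int(pos_samples),
        "positive_frac": (pos_samples / n_samples if n_samples
                          else float("nan")),
        "hotspot_frac": (float(hot.mean()) if len(somatic)
                         else float("nan")),
        "gene_frequencies": gene_freq,
    }


def cohort_summary(cf_variants: pd.DataFrame, wbc_variants: pd.DataFrame,
                   samples: pd.DataFrame) -> dict:
    """Per-group variant summary with between-group chi-squared tests.

    For each label group: sample and variant counts, fraction of samples
    with at least one somatic (post-CH-filter) variant, WBC-shared
    fraction, hotspot fraction among somatic variants, and oncoplot-style
    per-gene mutation frequencies. Between the two groups, chi-squared
    tests compare the positive-sample fraction and the shared fraction.
    """
    _, shared = filter_ch(cf_variants, wbc_variants)
    shared_idx = shared.index
    groups = {}
    for label, samp in samples.groupby("label"):
        cf_g = cf_variants[cf_variants["sample_id"].isin(samp["sample_id"])]
        mask = cf_g.index.isin(shared_idx)
        groups[label] = _group_stats(cf_g, mask, samp)

    tests = {"positive_frac_p": None, "shared_frac_p": None}
    labels = sorted(groups)
    if len(labels) == 2:
        a, b = (groups[k] for k in labels)
        try:
            _, _, p = chi_squared([
                [a["n_positive_samples"],
                 a["n_samples"] - a["n_positive_samples"]],
                [b["n_positive_samples"],
                 b["n_samples"] - b["n_positive_samples"]]])
            tests["positive_frac_p"] = p
        except ValueError:
            pass
        try:
            _, _, p = chi_squared([
                [a["n_shared"], a["n_somatic"]],
                [b["n_shared"], b["n_somatic"]]])
            tests["shared_frac_p"] = p
        except ValueError:
            pass
    return {"groups": groups, "tests": tests}


def annotate_hotspots(variants: pd.DataFrame,
                      hotspots: pd.DataFrame) -> pd.DataFrame:
    """Set tcga_hotspot / cosmic_hotspot flags from a hotspot key table."""
    out = variants.copy()
    for source, col in (("TCGA", "tcga_hotspot"), ("COSMIC", "cosmic_hotspot")):
        keys = hotspots.loc[hotspots["source"] == source, VARIANT_KEY]
        keys = set(map(tuple, keys.to_numpy()))
        out[col] = [tuple(row) in keys
                    for row in out[VARIANT_KEY].to_numpy()]
    return out
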