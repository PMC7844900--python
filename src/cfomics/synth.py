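"""Synthetic multi-analyte liquid-biopsy cohorts.

Generates plasma cfDNA variant tables with a tunable clonal-hematopoiesis
(CH) admixture, matched white-blood-cell (WBC) variant tables, duplex-UMI
read observations, tumor/NAT tissue methylation counts with planted
differentially methylated regions (DMRs), plasma regional methylation
matrices, serum CEA, and proportional-hazards survival times — everything
the downstream mutation, methylation, diagnostic and prognostic analyses
consume, with the statistical structure those analyses assume.

Every generator is deterministic given its spec's ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

BASES = np.array(["A", "C", "G", "T"])

# Synthetic driver-gene panel: (gene, chrom, anchor position). Coordinates
# are artificial; weights skew mutation counts toward TP53/EGFR as seen in
# lung-cancer cfDNA panels.
GENE_PANEL = [
    ("TP53", "chr17", 7_570_000, 6.0), ("EGFR", "chr7", 55_240_000, 3.0),
    ("PTPN11", "chr12", 112_880_000, 2.5), ("APC", "chr5", 112_100_000, 2.5),
    ("APOB", "chr2", 21_220_000, 2.5), ("KMT2C", "chr7", 151_840_000, 2.0),
    ("KMT2D", "chr12", 49_420_000, 2.0), ("KRAS", "chr12", 25_380_000, 2.0),
    ("CSMD3", "chr8", 113_230_000, 2.0), ("ATM", "chr11", 108_090_000, 1.5),
    ("CBL", "chr11", 119_070_000, 1.5), ("STAT3", "chr17", 40_460_000, 1.5),
    ("BRAF", "chr7", 140_450_000, 1.0), ("PIK3CA", "chr3", 178_910_000, 1.0),
    ("ALK", "chr2", 29_410_000, 1.0), ("MET", "chr7", 116_310_000, 1.0),
    ("ERBB2", "chr17", 37_840_000, 1.0), ("STK11", "chr19", 1_200_000, 1.0),
    ("NF1", "chr17", 29_420_000, 1.0), ("RET", "chr10", 43_570_000, 1.0),
]

LC_STAGES = ["0", "IA", "IB", "II", "III", "IV"]
LC_STAGE_PROBS = [0.02, 0.42, 0.23, 0.13, 0.15, 0.05]
SMOKING_LEVELS = ["current", "ex", "never"]
SMOKING_PROBS_LC = [0.23, 0.16, 0.61]
SMOKING_PROBS_BLN = [0.16, 0.09, 0.75]


class SpecValidationError(ValueError):
    """A generator spec field violates its invariant."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{fieldname}: {msg}")


@dataclass
class CohortSpec:
    """Cohort-level parameters for the plasma mutation generator.

    Defaults mirror the study conditions: 128 lung-cancer (LC) and 94
    benign-lung-nodule (BLN) participants; 68% / 42% of samples carry at
    least one detectable cfDNA variant; 20.7% / 39.1% of cfDNA variants are
    WBC-shared (clonal hematopoiesis); allele fractions follow a truncated
    log10-normal spanning 0.03%-6% with median near 0.13%.
    """

    n_lc: int = 128
    n_bln: int = 94
    pos_frac_lc: float = 0.68
    pos_frac_bln: float = 0.42
    ch_frac_lc: float = 0.207
    ch_frac_bln: float = 0.391
    af_log10_mean: float = -2.886   # 10**-2.886 ~ 0.13%
    af_log10_sd: float = 0.55
    af_min: float = 0.0003
    af_max: float = 0.06
    hotspot_frac: float = 0.35
    mean_variants_per_positive: float = 2.0
    cea_mean_lc: float = 4.5
    cea_mean_bln: float = 3.5
    cea_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("pos_frac_lc", "pos_frac_bln", "ch_frac_lc",
                     "ch_frac_bln", "hotspot_frac"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"probability {v} outside [0, 1]")
        _check(self.af_min < self.af_max, "af_min", "must be < af_max")
        _check(self.af_min > 0, "af_min", "must be > 0")
        _check(self.n_lc >= 0, "n_lc", "must be >= 0")
        _check(self.n_bln >= 0, "n_bln", "must be >= 0")
        _check(self.mean_variants_per_positive > 0,
               "mean_variants_per_positive", "must be > 0")


@dataclass
class MethylSpec:
    """Parameters for tissue/plasma methylation generation.

    The default planted hyper:hypo ratio (40:3) scales the 293:22 split
    expected for lung tumors, where promoter hypermethylation dominates.
    ``plasma_attenuation`` dilutes the tissue effect size in plasma, where
    tumor DNA is a minority of cfDNA.
    """

    n_regions: int = 250
    n_hyper: int = 40
    n_hypo: int = 3
    delta_beta: float = 0.3
    plasma_attenuation: float = 0.5
    coverage_mean: float = 30.0
    n_cpg_per_region: int = 10
    dropout_rate: float = 0.05
    n_pairs: int = 25
    region_size: int = 200
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_hyper + self.n_hypo <= self.n_regions,
               "n_hyper", "n_hyper + n_hypo must be <= n_regions")
        _check(0.0 <= self.delta_beta <= 1.0, "delta_beta",
               "must be in [0, 1] (0 = null, no planted signal)")
        _check(0.0 <= self.plasma_attenuation <= 1.0, "plasma_attenuation",
               "must be in [0, 1]")
        _check(0.0 <= self.dropout_rate < 1.0, "dropout_rate",
               "must be in [0, 1)")
        _check(self.coverage_mean > 0, "coverage_mean", "must be > 0")
        _check(self.n_pairs >= 1, "n_pairs", "must be >= 1")
        _check(self.n_cpg_per_region >= 1, "n_cpg_per_region", "must be >= 1")


@dataclass
class SurvivalSpec:
    """Exponential proportional-hazards generator for overall survival.

    ``baseline_rate`` is in events per month; the default 0.02 puts the
    baseline median near 35 months with administrative censoring at 60.
    """

    baseline_rate: float = 0.02
    log_hr_mut: float = 0.5
    log_hr_mps: float = 0.5
    censor_time: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.baseline_rate > 0, "baseline_rate", "must be > 0")
        _check(self.censor_time > 0, "censor_time", "must be > 0")


@dataclass
class Cohort:
    """Output bundle of :func:`generate_cohort`."""

    samples: pd.DataFrame
    cf_variants: pd.DataFrame
    wbc_variants: pd.DataFrame
    hotspots: pd.DataFrame


@dataclass
class MethylationData:
    """Output bundle of :func:`generate_methylation`."""

    tissue_counts: pd.DataFrame     # long CpG counts for tumor+NAT samples
    tissue_pairs: pd.DataFrame      # pair_id, tumor_sample, nat_sample
    regions: pd.DataFrame           # region_id, chrom, start, end
    plasma_beta: pd.DataFrame       # samples x region_id, NaN = dropout
    truth: pd.DataFrame             # region_id, direction for planted DMRs


def _truncated_log10_normal(rng, n, mean, sd, lo, hi):
    a = (np.log10(lo) - mean) / sd
    b = (np.log10(hi) - mean) / sd
    z = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return 10.0 ** z


def _draw_truncated_poisson(rng, lam: float) -> int:
    """Poisson(lam) conditioned on >= 1 by inverse CDF on the tail."""
    u = rng.uniform(stats.poisson.cdf(0, lam), 1.0)
    return int(stats.poisson.ppf(u, lam))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate sample metadata, cfDNA and WBC variant tables and a hotspot
    table for an LC + BLN cohort.

    Every WBC-shared cfDNA variant gets a matching WBC record (same
    patient, same variant key) whose allele fraction equals the cfDNA AF
    times log10-normal noise (sigma 0.2), reproducing the strong observed
    cfDNA/WBC AF correlation for clonal-hematopoiesis variants.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    rows = []
    for i in range(spec.n_lc):
        rows.append({
            "sample_id": f"LC{i + 1:04d}", "patient_id": f"P{i + 1:04d}",
            "label": "LC",
            "stage": rng.choice(LC_STAGES, p=LC_STAGE_PROBS),
            "smoking": rng.choice(SMOKING_LEVELS, p=SMOKING_PROBS_LC),
            "cea": max(0.1, rng.normal(spec.cea_mean_lc, spec.cea_sd)),
        })
    for i in range(spec.n_bln):
        rows.append({
            "sample_id": f"BLN{i + 1:04d}",
            "patient_id": f"P{spec.n_lc + i + 1:04d}",
            "label": "BLN", "stage": "NA",
            "smoking": rng.choice(SMOKING_LEVELS, p=SMOKING_PROBS_BLN),
            "cea": max(0.1, rng.normal(spec.cea_mean_bln, spec.cea_sd)),
        })
    samples = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "label", "stage",
                       "smoking", "cea"])

    gene_names = [g[0] for g in GENE_PANEL]
    gene_w = np.array([g[3] for g in GENE_PANEL])
    gene_w = gene_w / gene_w.sum()
    gene_info = {g[0]: (g[1], g[2]) for g in GENE_PANEL}

    cf_rows, wbc_rows, hotspot_rows = [], [], []
    hotspot_seen = set()
    for _, s in samples.iterrows():
        is_lc = s["label"] == "LC"
        pos_frac = spec.pos_frac_lc if is_lc else spec.pos_frac_bln
        ch_frac = spec.ch_frac_lc if is_lc else spec.ch_frac_bln
        if rng.uniform() >= pos_frac:
            continue
        n_var = _draw_truncated_poisson(rng, spec.mean_variants_per_positive)
        afs = _truncated_log10_normal(
            rng, n_var, spec.af_log10_mean, spec.af_log10_sd,
            spec.af_min, spec.af_max)
        for af in afs:
            gene = rng.choice(gene_names, p=gene_w)
            chrom, anchor = gene_info[gene]
            pos = int(anchor + rng.integers(0, 5000))
            ref = rng.choice(BASES)
            alt = rng.choice(BASES[BASES != ref])
            depth = int(rng.integers(1500, 4000))
            lo = max(1, int(np.ceil(spec.af_min * depth)))
            hi = max(lo, int(np.floor(spec.af_max * depth)))
            alt_count = int(np.clip(round(af * depth), lo, hi))
            is_hot = rng.uniform() < spec.hotspot_frac
            tcga = cosmic = False
            if is_hot:
                u = rng.uniform()
                tcga = u < 0.6
                cosmic = u >= 0.4   # overlap 0.4-0.6 carries both flags
                key = (chrom, pos, ref, alt)
                if key not in hotspot_seen:
                    hotspot_seen.add(key)
                    if tcga:
                        hotspot_rows.append(
                            {"chrom": chrom, "pos_1based": pos, "ref": ref,
                             "alt": alt, "source": "TCGA"})
                    if cosmic:
                        hotspot_rows.append(
                            {"chrom": chrom, "pos_1based": pos, "ref": ref,
                             "alt": alt, "source": "COSMIC"})
            cf_rows.append({
                "sample_id": s["sample_id"], "patient_id": s["patient_id"],
                "chrom": chrom, "pos_1based": pos, "ref": ref, "alt": alt,
                "alt_count": alt_count, "depth": depth,
                "af": alt_count / depth, "gene": gene,
                "tcga_hotspot": tcga, "cosmic_hotspot": cosmic,
            })
            if rng.uniform() < ch_frac:
                wbc_af = (alt_count / depth) * 10.0 ** rng.normal(0.0, 0.2)
                wbc_af = float(np.clip(wbc_af, 1e-6, 1.0))
                wbc_depth = int(rng.integers(1500, 4000))
                wbc_alt = max(1, round(wbc_af * wbc_depth))
                wbc_rows.append({
                    "sample_id": s["sample_id"] + "_WBC",
                    "patient_id": s["patient_id"],
                    "chrom": chrom, "pos_1based": pos, "ref": ref, "alt": alt,
                    "alt_count": wbc_alt, "depth": wbc_depth,
                    "af": wbc_alt / wbc_depth, "gene": gene,
                    "tcga_hotspot": tcga, "cosmic_hotspot": cosmic,
                })

    variant_cols = ["sample_id", "patient_id", "chrom", "pos_1based", "ref",
                    "alt", "alt_count", "depth", "af", "gene",
                    "tcga_hotspot", "cosmic_hotspot"]
    cf = pd.DataFrame(cf_rows, columns=variant_cols)
    wbc = pd.DataFrame(wbc_rows, columns=variant_cols)
    hotspots = pd.DataFrame(
        hotspot_rows, columns=["chrom", "pos_1based", "ref", "alt", "source"])
    return Cohort(samples, cf, wbc, hotspots)


def generate_reads(truth_variant: Mapping, n_molecules: int,
                   family_size_mean: float = 5.0, error_rate: float = 0.005,
                   umi_len: int = 6, seed: int = 0,
                   patient_id: str = "P0001") -> pd.DataFrame:
    """Simulate duplex-UMI read observations over one variant site.

    ``truth_variant`` maps ``chrom``, ``pos`` (0-based), ``ref``, ``alt``
    and ``af`` (fraction of original molecules carrying the alternate
    allele). Each original molecule receives a random fragment span
    covering the site and a UMI pair; it yields at least one read on each
    strand (1 + Poisson per strand, so the expected family size is
    ``family_size_mean``), and each read base is substituted independently
    with probability ``error_rate``.
    """
    if not (0.0 <= error_rate < 0.5):
        raise SpecValidationError(
            f"error_rate: {error_rate} outside [0, 0.5)")
    if umi_len < 1:
        raise SpecValidationError("umi_len: must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = truth_variant["chrom"]
    pos = int(truth_variant["pos"])
    ref, alt = truth_variant["ref"], truth_variant["alt"]
    af = float(truth_variant.get("af", 0.0))
    per_strand_extra = max(family_size_mean / 2.0 - 1.0, 0.0)

    rows = []
    for _ in range(n_molecules):
        start = pos - int(rng.integers(20, 120))
        end = pos + int(rng.integers(20, 120))
        umi_a = "".join(rng.choice(BASES, size=umi_len))
        umi_b = "".join(rng.choice(BASES, size=umi_len))
        true_base = alt if rng.uniform() < af else ref
        for strand in ("top", "bottom"):
            n_reads = 1 + rng.poisson(per_strand_extra)
            # bottom-strand reads see the UMI pair in swapped order
            ua, ub = (umi_a, umi_b) if strand == "top" else (umi_b, umi_a)
            for _ in range(n_reads):
                base = true_base
                if rng.uniform() < error_rate:
                    base = rng.choice(BASES[BASES != true_base])
                q = int(rng.choice([25, 33, 37], p=[0.05, 0.25, 0.70]))
                rows.append({
                    "patient_id": patient_id, "chrom": chrom,
                    "frag_start": start, "frag_end": end, "strand": strand,
                    "umi_a": ua, "umi_b": ub,
                    "alleles": f"{pos}:{base}", "baseq": f"{pos}:{q}",
                })
    return pd.DataFrame(rows, columns=["patient_id", "chrom", "frag_start",
                                       "frag_end", "strand", "umi_a",
                                       "umi_b", "alleles", "baseq"])


def _beta_noise(rng, mu, nu, size=None):
    """Beta-distributed value(s) with mean mu and precision nu."""
    mu = np.clip(mu, 0.02, 0.98)
    return rng.beta(mu * nu, (1.0 - mu) * nu, size=size)


def generate_methylation(spec: MethylSpec,
                         samples: pd.DataFrame) -> MethylationData:
    """Simulate tissue CpG counts for tumor/NAT pairs with planted DMRs,
    plus a plasma regional-beta matrix with attenuated group differences.

    Planted hyper regions have tumor-minus-NAT mean beta difference
    ``delta_beta`` (hypo: ``-delta_beta``); in plasma the LC-minus-BLN
    difference is ``delta_beta * plasma_attenuation``. With
    ``delta_beta == 0`` nothing is planted and the truth list is empty.
    """
    spec.validate()
    if "label" not in samples.columns:
        raise SpecValidationError("samples: table must carry a 'label' column")
    rng = np.random.default_rng(spec.seed)
    nr = spec.n_regions
    d = spec.delta_beta

    direction = np.array([""] * nr, dtype=object)
    if d > 0:
        direction[: spec.n_hyper] = "hyper"
        direction[spec.n_hyper: spec.n_hyper + spec.n_hypo] = "hypo"

    # NAT baseline means, kept away from the clip boundary so the planted
    # shift survives intact
    base = np.empty(nr)
    null_mask = direction == ""
    base[null_mask] = rng.beta(0.8, 0.8, size=int(null_mask.sum()))
    base[direction == "hyper"] = rng.uniform(
        0.05, max(0.06, 0.93 - d), size=int((direction == "hyper").sum()))
    base[direction == "hypo"] = rng.uniform(
        min(0.94, 0.07 + d), 0.95, size=int((direction == "hypo").sum()))
    tumor_mean = base.copy()
    tumor_mean[direction == "hyper"] += d
    tumor_mean[direction == "hypo"] -= d

    regions = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(nr) * 1000,
        "end": np.arange(nr) * 1000 + spec.region_size,
    })
    regions.insert(0, "region_id", [
        f"chr1:{s}-{e}" for s, e in zip(regions["start"], regions["end"])])

    pair_ids = [f"PAIR{i + 1:03d}" for i in range(spec.n_pairs)]
    tissue_pairs = pd.DataFrame({
        "pair_id": pair_ids,
        "tumor_sample": [p + "_T" for p in pair_ids],
        "nat_sample": [p + "_N" for p in pair_ids],
    })

    cpg_offsets = np.arange(spec.n_cpg_per_region) * 15
    count_rows = []
    for mean_vec, col in ((tumor_mean, "tumor_sample"), (base, "nat_sample")):
        for sid in tissue_pairs[col]:
            beta_rs = _beta_noise(rng, mean_vec, 60.0)
            for r in range(nr):
                starts = regions["start"].iloc[r] + cpg_offsets
                totals = rng.poisson(spec.coverage_mean,
                                     size=spec.n_cpg_per_region)
                meths = rng.binomial(totals, beta_rs[r])
                for p0, t, m in zip(starts, totals, meths):
                    count_rows.append((sid, "chr1", int(p0), int(p0) + 2,
                                       int(m), int(t)))
    tissue_counts = pd.DataFrame(
        count_rows,
        columns=["sample_id", "chrom", "pos0", "pos1",
                 "meth_count", "total_count"])

    # Per-sample signal weight models heterogeneous circulating-tumor-DNA
    # fraction: gamma with mean 1, capped so no plasma shift exceeds the
    # tissue effect size. BLN plasma carries no tumor signal.
    shift_dir = np.where(direction == "hyper", 1.0,
                         np.where(direction == "hypo", -1.0, 0.0))
    plasma_shift = d * spec.plasma_attenuation * shift_dir

    plasma_rows = {}
    for _, s in samples.iterrows():
        if s["label"] == "LC":
            w = min(rng.gamma(2.0, 0.5),
                    1.0 / max(spec.plasma_attenuation, 1e-9))
        else:
            w = 0.0
        mu = base + w * plasma_shift
        vals = _beta_noise(rng, mu, 80.0)
        drop = rng.uniform(size=nr) < spec.dropout_rate
        vals = np.where(drop, np.nan, vals)
        plasma_rows[s["sample_id"]] = vals
    plasma_beta = pd.DataFrame.from_dict(
        plasma_rows, orient="index", columns=regions["region_id"].tolist())
    plasma_beta.index.name = "sample_id"

    truth = pd.DataFrame({
        "region_id": regions["region_id"][direction != ""],
        "direction": direction[direction != ""],
    }).reset_index(drop=True)
    return MethylationData(tissue_counts, tissue_pairs, regions,
                           plasma_beta, truth)


def generate_survival(spec: SurvivalSpec,
                      scores: pd.DataFrame) -> pd.DataFrame:
    """Draw exponential survival times under proportional hazards.

    ``scores`` must carry ``sample_id`` plus ``mut`` and/or ``mps``
    columns (a missing column contributes zero log-hazard). The hazard for
    sample *i* is ``baseline_rate * exp(log_hr_mut*mut_i +
    log_hr_mps*mps_i)``; times are administratively censored at
    ``censor_time`` (event = 0).
    """
    spec.validate()
    mut = scores["mut"].to_numpy(float) if "mut" in scores.columns \
        else np.zeros(len(scores))
    mps = scores["mps"].to_numpy(float) if "mps" in scores.columns \
        else np.zeros(len(scores))
    if not (np.all(np.isfinite(mut)) and np.all(np.isfinite(mps))):
        raise SpecValidationError("scores: must be finite")
    rng = np.random.default_rng(spec.seed)
    rate = spec.baseline_rate * np.exp(
        spec.log_hr_mut * mut + spec.log_hr_mps * mps)
    t = rng.exponential(1.0 / rate)
    event = (t <= spec.censor_time).astype(int)
    time = np.minimum(t, spec.censor_time)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({
        "sample_id": scores["sample_id"].to_numpy(),
        "time_months": time, "event": event,
    })


def spec_from_dict(cls, d: Mapping):
    """Build a spec dataclass from a plain mapping (e.g. parsed YAML)."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise SpecValidationError(
            f"unknown field(s) {sorted(unknown)} for {cls.__name__}")
    return cls(**d)
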