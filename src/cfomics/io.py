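"""Readers and writers for the plain-text tables the pipeline exchanges.

All tables are tab-separated with a header row. Coordinates follow the
BED convention (0-based, half-open) except variant tables, which carry a
1-based ``pos_1based`` column as in VCF.
"""

from __future__ import annotations

import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "patient_id", "label", "stage", "smoking", "cea"]
VARIANT_COLUMNS = [
    "sample_id", "patient_id", "chrom", "pos_1based", "ref", "alt",
    "alt_count", "depth", "af", "gene", "tcga_hotspot", "cosmic_hotspot",
]
HOTSPOT_COLUMNS = ["chrom", "pos_1based", "ref", "alt", "source"]
CPG_COLUMNS = ["sample_id", "chrom", "pos0", "pos1", "meth_count", "total_count"]
REGION_COLUMNS = ["chrom", "start", "end"]
SURVIVAL_COLUMNS = ["sample_id", "time_months", "event"]
READ_COLUMNS = [
    "patient_id", "chrom", "frag_start", "frag_end", "strand",
    "umi_a", "umi_b", "alleles", "baseq",
]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_variants(path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("tcga_hotspot", "cosmic_hotspot"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    """Samples x regions matrix; NaN written as 'NA'."""
    matrix.to_csv(path, sep="\t", index=True, index_label="sample_id", na_rep="NA")


def read_beta_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    regions[REGION_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_regions_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS,
                       usecols=[0, 1, 2])
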