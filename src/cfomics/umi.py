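"""Duplex-UMI consensus generation and error-corrected variant calling.

Reads tagged with duplex unique molecular identifiers (UMIs) are grouped
into families representing single original cfDNA molecules (one family =
one fragment span + one canonical UMI pair, so both strands of a molecule
collapse together), each family is reduced to a per-position consensus
with strand-aware error correction, and variants are called from molecule
counts under configurable stringency thresholds.

Coordinates are 0-based half-open internally; emitted variant tables use
1-based positions (VCF convention).
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

_UMI_RE_CACHE: dict = {}


def _umi_re(umi_len: int):
    if umi_len not in _UMI_RE_CACHE:
        _UMI_RE_CACHE[umi_len] = re.compile(r"^[ACGTN]{%d}$" % umi_len)
    return _UMI_RE_CACHE[umi_len]


@dataclass
class ReadObservation:
    """One sequenced read reduced to its informative positions."""

    patient_id: str
    chrom: str
    frag_start: int
    frag_end: int
    strand: str                      # "top" | "bottom"
    umi_a: str
    umi_b: str
    alleles: Dict[int, str]          # 0-based position -> base
    baseq: Dict[int, int]            # 0-based position -> Phred quality

    def __post_init__(self):
        if self.frag_start >= self.frag_end:
            raise ValueError(
                f"fragment [{self.frag_start}, {self.frag_end}) is empty")
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be top/bottom, got {self.strand!r}")


@dataclass
class UmiFamily:
    """All reads sharing one fragment span and canonical UMI pair."""

    key: Tuple[str, int, int, str, str]
    reads: List[ReadObservation] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass
class ConsensusMolecule:
    """Duplex-resolved consensus of one original DNA molecule."""

    family_key: Tuple[str, int, int, str, str]
    n_reads_top: int
    n_reads_bottom: int
    consensus_alleles: Dict[int, str]
    duplex: bool

    @property
    def chrom(self) -> str:
        return self.family_key[0]


@dataclass
class ConsensusParams:
    """Stringency thresholds for consensus building and variant calling.

    Defaults follow common stringent duplex-sequencing practice: a 90%
    within-strand majority, Phred >= 30 bases, duplex-only evidence, and
    at least 3 supporting molecules over at least 100 informative
    molecules per site. All are configurable.
    """

    min_family_size: int = 1
    min_per_strand: int = 1
    majority_frac: float = 0.9
    min_baseq: int = 30
    require_duplex: bool = True
    min_alt_molecules: int = 3
    min_depth_molecules: int = 100
    max_n_frac: float = 0.2

    def __post_init__(self):
        if not (0.5 < self.majority_frac <= 1.0):
            raise ValueError("majority_frac must be in (0.5, 1]")
        for name in ("min_family_size", "min_per_strand",
                     "min_alt_molecules", "min_depth_molecules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def parse_reads_table(df: pd.DataFrame) -> List[ReadObservation]:
    """Parse the read-observation TSV schema into objects.

    ``alleles``/``baseq`` columns hold ';'-joined ``pos:value`` entries at
    0-based positions.
    """
    reads = []
    for row in df.itertuples(index=False):
        alleles = {int(p): b for p, b in
                   (tok.split(":") for tok in str(row.alleles).split(";"))}
        baseq = {int(p): int(q) for p, q in
                 (tok.split(":") for tok in str(row.baseq).split(";"))}
        reads.append(ReadObservation(
            patient_id=row.patient_id, chrom=row.chrom,
            frag_start=int(row.frag_start), frag_end=int(row.frag_end),
            strand=row.strand, umi_a=row.umi_a, umi_b=row.umi_b,
            alleles=alleles, baseq=baseq))
    return reads


def group_families(reads: Iterable[ReadObservation],
                   umi_len: int = 6) -> List[UmiFamily]:
    """Assign each read to exactly one UMI family.

    The family key is (chrom, frag_start, frag_end, canonical UMI pair),
    with the canonical pair being the lexicographically ordered
    ``(umi_a, umi_b)`` so top- and bottom-strand reads of one molecule
    land in the same family. Reads with a malformed UMI (wrong length or
    alphabet) are rejected, with the count logged.
    """
    pattern = _umi_re(umi_len)
    families: Dict[tuple, UmiFamily] = {}
    n_rejected = 0
    for r in reads:
        if not (pattern.match(r.umi_a) and pattern.match(r.umi_b)):
            n_rejected += 1
            continue
        pair = tuple(sorted((r.umi_a, r.umi_b)))
        key = (r.chrom, r.frag_start, r.frag_end, pair[0], pair[1])
        fam = families.get(key)
        if fam is None:
            families[key] = fam = UmiFamily(key=key)
        fam.reads.append(r)
    if n_rejected:
        logger.warning("rejected %d read(s) with malformed UMI tags",
                       n_rejected)
    return list(families.values())


def collapse_family(family: UmiFamily,
                    params: ConsensusParams) -> Optional[ConsensusMolecule]:
    """Reduce one UMI family to a duplex consensus molecule.

    Per position, bases below ``min_baseq`` are dropped; each strand's
    consensus is the base reaching at least ``majority_frac`` of that
    strand's surviving bases, else N; when both strands have coverage the
    duplex consensus is their common base or N on disagreement. Returns
    None (dropped) for families smaller than ``min_family_size`` or with
    an N fraction above ``max_n_frac``.
    """
    if family.size == 0:
        return None
    if family.size < params.min_family_size:
        return None
    n_top = sum(1 for r in family.reads if r.strand == "top")
    n_bottom = family.size - n_top

    per_strand: Dict[str, Dict[int, Counter]] = {
        "top": defaultdict(Counter), "bottom": defaultdict(Counter)}
    positions = set()
    for r in family.reads:
        for pos, base in r.alleles.items():
            positions.add(pos)
            if r.baseq.get(pos, 0) >= params.min_baseq:
                per_strand[r.strand][pos][base] += 1

    consensus: Dict[int, str] = {}
    for pos in positions:
        strand_calls = []
        for strand in ("top", "bottom"):
            counts = per_strand[strand].get(pos)
            if not counts:
                continue
            total = sum(counts.values())
            base, cnt = counts.most_common(1)[0]
            strand_calls.append(base if cnt / total >= params.majority_frac
                                else "N")
        if not strand_calls:
            consensus[pos] = "N"     # all evidence below quality threshold
        elif len(strand_calls) == 1:
            consensus[pos] = strand_calls[0]
        else:
            consensus[pos] = (strand_calls[0]
                              if strand_calls[0] == strand_calls[1] else "N")

    if consensus:
        n_frac = sum(1 for b in consensus.values() if b == "N") / len(consensus)
        if n_frac > params.max_n_frac:
            return None
    duplex = (n_top >= params.min_per_strand
              and n_bottom >= params.min_per_strand)
    return ConsensusMolecule(
        family_key=family.key, n_reads_top=n_top, n_reads_bottom=n_bottom,
        consensus_alleles=consensus, duplex=duplex)


def collapse_families(families: Iterable[UmiFamily],
                      params: ConsensusParams) -> List[ConsensusMolecule]:
    """Collapse every family; dropped molecules are counted in the log."""
    molecules, n_dropped = [], 0
    for fam in families:
        mol = collapse_family(fam, params)
        if mol is None:
            n_dropped += 1
        else:
            molecules.append(mol)
    if n_dropped:
        logger.info("dropped %d degenerate famil(ies) during consensus",
                    n_dropped)
    return molecules


def call_variants(molecules: Iterable[ConsensusMolecule],
                  reference: Mapping[Tuple[str, int], str],
                  params: ConsensusParams,
                  sample_id: str = "S1",
                  patient_id: str = "P1") -> pd.DataFrame:
    """Call single-nucleotide variants from consensus molecule counts.

    ``reference`` maps (chrom, 0-based position) to the reference base and
    must cover every position any molecule reports. Per site the depth is
    the number of qualifying molecules (duplex-only when
    ``require_duplex``) with a non-N consensus; a call on the most
    frequent non-reference base is emitted iff its molecule count is at
    least ``min_alt_molecules`` and the depth at least
    ``min_depth_molecules``. Positions with no molecule coverage yield no
    call. Output uses 1-based positions.
    """
    site_counts: Dict[Tuple[str, int], Counter] = defaultdict(Counter)
    for mol in molecules:
        if params.require_duplex and not mol.duplex:
            continue
        for pos, base in mol.consensus_alleles.items():
            if base == "N":
                continue
            site_counts[(mol.chrom, pos)][base] += 1

    rows = []
    for (chrom, pos), counts in sorted(site_counts.items()):
        if (chrom, pos) not in reference:
            raise KeyError(
                f"reference allele unknown at {chrom}:{pos} (0-based)")
        ref = reference[(chrom, pos)]
        depth = sum(counts.values())
        alts = [(b, c) for b, c in counts.items() if b != ref]
        if not alts:
            continue
        alt, alt_count = max(alts, key=lambda bc: (bc[1], bc[0]))
        if alt_count >= params.min_alt_molecules \
                and depth >= params.min_depth_molecules:
            rows.append({
                "sample_id": sample_id, "patient_id": patient_id,
                "chrom": chrom, "pos_1based": pos + 1, "ref": ref,
                "alt": alt, "alt_count": alt_count, "depth": depth,
                "af": alt_count / depth, "gene": "",
                "tcga_hotspot": False, "cosmic_hotspot": False,
            })
    return pd.DataFrame(rows, columns=[
        "sample_id", "patient_id", "chrom", "pos_1based", "ref", "alt",
        "alt_count", "depth", "af", "gene", "tcga_hotspot",
        "cosmic_hotspot"])


def write_vcf(calls: pd.DataFrame, path) -> None:
    """Write calls as a minimal single-sample VCF (SNVs only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,'
                 'Description="Molecule allele fraction">\n')
        fh.write('##INFO=<ID=ALT_MOL,Number=1,Type=Integer,'
                 'Description="Alt consensus molecules">\n')
        fh.write('##INFO=<ID=DEPTH_MOL,Number=1,Type=Integer,'
                 'Description="Total consensus molecules">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            info = (f"AF={row.af:.6g};ALT_MOL={row.alt_count};"
                    f"DEPTH_MOL={row.depth}")
            fh.write(f"{row.chrom}\t{row.pos_1based}\t.\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t{info}\n")
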