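"""Shared record types for the dual-reference SV scan.

Coordinate convention: 0-based half-open everywhere in memory; 1-based
inclusive only in written report formats (VCF, GFF3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


class SvType(str, Enum):
    INSERTION = "insertion"  # sequence present in genome B, absent in genome A
    DELETION = "deletion"    # sequence present in genome A, absent in genome B


class Call(str, Enum):
    REF_A = "REF_A"
    REF_B = "REF_B"
    HET = "HET"
    MISSING = "MISSING"


#: dosage of the B allele implied by each genotype class
CALL_DOSAGE = {Call.REF_A: 0, Call.HET: 1, Call.REF_B: 2}


@dataclass
class StructuralVariant:
    """An indel between two assemblies, with breakpoints in both coordinate systems.

    For a deletion, ``ref_end - ref_start == size`` and the locus collapses to
    the single point ``b_start`` in genome B.  For an insertion,
    ``ref_start == ref_end`` (breakpoint in A) and ``b_end - b_start == size``.
    """

    id: str
    ref_name: str
    ref_start: int
    ref_end: int
    size: int
    type: SvType
    origin: str = "within_alignment"  # or "between_alignment"
    query_name: Optional[str] = None
    query_start: Optional[int] = None
    query_end: Optional[int] = None
    alt_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"SV {self.id}: size must be >= 1, got {self.size}")
        if self.type == SvType.DELETION and self.ref_end - self.ref_start != self.size:
            raise ValueError(
                f"SV {self.id}: deletion ref span {self.ref_end - self.ref_start} != size {self.size}"
            )
        if self.type == SvType.INSERTION and self.ref_end != self.ref_start:
            raise ValueError(f"SV {self.id}: insertion must have ref_end == ref_start")

    @property
    def b_start(self) -> Optional[int]:
        return self.query_start

    @property
    def b_end(self) -> Optional[int]:
        return self.query_end


@dataclass
class AlignmentBlock:
    """One whole-genome-alignment record (PAF line) between genome A (ref) and B (query)."""

    ref_name: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    cigar: str
    mapq: int = 60

    def cigar_ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)


_CIGAR_OPS = set("MIDNSHP=X")
_REF_CONSUMING = set("MDN=X")
_QUERY_CONSUMING = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; unknown ops raise."""
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch not in _CIGAR_OPS:
                raise ValueError(f"unknown CIGAR op {ch!r} in {cigar!r}")
            if not num:
                raise ValueError(f"CIGAR op {ch!r} without length in {cigar!r}")
            ops.append((int(num), ch))
            num = ""
    if num:
        raise ValueError(f"trailing digits in CIGAR {cigar!r}")
    return ops


def cigar_spans(ops: list[tuple[int, str]]) -> tuple[int, int]:
    """(ref_consumed, query_consumed) lengths of a parsed CIGAR."""
    ref = sum(n for n, op in ops if op in _REF_CONSUMING)
    qry = sum(n for n, op in ops if op in _QUERY_CONSUMING)
    return ref, qry


@dataclass
class SvGenotypeCall:
    sv_id: str
    accession: str
    call: Call
    support_a: int = 0
    support_b: int = 0

    @property
    def dosage(self) -> Optional[int]:
        return CALL_DOSAGE.get(self.call)


class GenotypeMatrix:
    """Loci x accessions dosage matrix (B-allele count 0/1/2, NaN = missing).

    Carries group labels per accession and per-locus call rate / minor allele
    frequency, recomputed from the dosages on construction.
    """

    def __init__(self, dosages: pd.DataFrame, groups: pd.Series):
        groups = groups.reindex(dosages.columns)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])
            raise ValueError(f"accessions without group label: {missing}")
        self.dosages = dosages.astype(float)
        self.groups = groups.astype(str)
        self._recompute_metadata()

    def _recompute_metadata(self) -> None:
        d = self.dosages
        n = d.shape[1]
        called = d.notna().sum(axis=1)
        self.call_rate = called / n if n else called.astype(float)
        with np.errstate(invalid="ignore"):
            freq = d.sum(axis=1, skipna=True) / (2.0 * called)
        self.maf = pd.concat([freq, 1.0 - freq], axis=1).min(axis=1)

    @property
    def loci(self) -> pd.Index:
        return self.dosages.index

    @property
    def accessions(self) -> pd.Index:
        return self.dosages.columns

    def subset_loci(self, loci) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[loci], self.groups)

    def group_accessions(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]


@dataclass
class FreqRecord:
    sv_id: str
    n_wild_alleles: int
    n_cult_alleles: int
    b_count_wild: int
    b_count_cult: int

    @property
    def freq_wild(self) -> float:
        return self.b_count_wild / self.n_wild_alleles

    @property
    def freq_cult(self) -> float:
        return self.b_count_cult / self.n_cult_alleles


@dataclass
class SelectionResult:
    sv_id: str
    p: float
    q: float
    selected: bool


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:]) if b_start > a_end]


@dataclass
class SvContext:
    sv_id: str
    category: str  # exonic | intronic | upstream | downstream | intergenic
    gene_id: Optional[str] = None
    distance_to_gene: Optional[int] = None


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_snps: int
    pi_wild: Optional[float] = None
    pi_cult: Optional[float] = None
    fst: Optional[float] = None
    outlier_fst: bool = False
    outlier_pi_ratio: bool = False

    @property
    def pi_ratio(self) -> Optional[float]:
        if self.pi_wild is None or self.pi_cult is None or self.pi_cult == 0:
            return None
        return self.pi_wild / self.pi_cult
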