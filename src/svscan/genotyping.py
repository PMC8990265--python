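"""Dual-reference SV genotyping from breakpoint-spanning clean reads.

For every SV each accession's reads are screened against both assemblies: a
read supports an allele when it cleanly spans the breakpoint window on that
assembly — fully covering the window, with no insertion/deletion/clip
touching it, and an overall mismatch fraction (NM / aligned length) of at
most ``max_mismatch_frac`` (3% by default, the classification rule of the
study design).  Support counts a (allele A) and b (allele B) then give the
genotype: total < min_depth -> MISSING; b/(a+b) <= 1-hom_frac -> REF_A;
>= hom_frac -> REF_B; otherwise HET.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .models import Call, GenotypeMatrix, StructuralVariant, SvGenotypeCall, SvType

logger = logging.getLogger(__name__)


@dataclass
class GenotypingParams:
    w: int = 20                    # breakpoint flank, bp
    min_depth: int = 4             # minimum informative spanning reads
    hom_frac: float = 0.8          # homozygous call threshold on b/(a+b)
    max_mismatch_frac: float = 0.03


def sv_windows(svs: Iterable[StructuralVariant], w: int
               ) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    """Breakpoint windows per assembly.

    On the assembly carrying the extra sequence the window brackets the left
    breakpoint of that sequence; on the other assembly it brackets the fused
    junction point.  Either way only reads from the matching haplotype can
    span it without an indel, which is the dual-reference signal.
    """
    trees_a: dict[str, IntervalTree] = defaultdict(IntervalTree)
    trees_b: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for sv in svs:
        if sv.query_name is None or sv.query_start is None:
            raise ValueError(f"SV {sv.id} lacks genome-B coordinates")
        trees_a[sv.ref_name].addi(max(0, sv.ref_start - w), sv.ref_start + w, sv.id)
        trees_b[sv.query_name].addi(max(0, sv.query_start - w), sv.query_start + w, sv.id)
    return trees_a, trees_b


def read_supports_allele(record: pysam.AlignedSegment, window: tuple[int, int],
                         max_mismatch_frac: float = 0.03) -> bool:
    """True iff the alignment cleanly spans [win_start, win_end).

    Clean: primary mapped record whose aligned reference span contains the
    window, with no I/D/N op intersecting it (an insertion counts when its
    breakpoint falls strictly inside), and NM / aligned-length within the
    mismatch budget.  Records without NM are skipped (treated as no support).
    """
    win_start, win_end = window
    if record.is_unmapped or record.is_secondary or record.is_supplementary:
        return False
    if record.reference_start > win_start or record.reference_end < win_end:
        return False
    try:
        nm = record.get_tag("NM")
    except KeyError:
        logger.warning("read %s: NM tag missing; skipped", record.query_name)
        return False
    ref_pos = record.reference_start
    aligned = 0
    for op, length in record.cigartuples:
        if op in (0, 7, 8):          # M, =, X
            aligned += length
            ref_pos += length
        elif op == 1:                # I: breakpoint strictly inside the window
            if win_start < ref_pos < win_end:
                return False
        elif op in (2, 3):           # D, N
            if ref_pos < win_end and ref_pos + length > win_start:
                return False
            ref_pos += length
        # S/H/P consume no reference and cannot sit inside a spanned window
    if aligned == 0:
        return False
    return nm / aligned <= max_mismatch_frac


def _collect_supports(sam_path: str | Path, trees: Mapping[str, IntervalTree],
                      max_mismatch_frac: float) -> dict[str, set[str]]:
    """Map sv_id -> set of read names cleanly spanning its window in this file."""
    supports: dict[str, set[str]] = defaultdict(set)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in trees:
                continue
            for iv in trees[rec.reference_name].overlap(rec.reference_start,
                                                        rec.reference_end or rec.reference_start + 1):
                if read_supports_allele(rec, (iv.begin, iv.end), max_mismatch_frac):
                    mate = "/2" if rec.is_read2 else "/1"
                    supports[iv.data].add(rec.query_name + mate)
    return supports


def classify_counts(a: int, b: int, params: GenotypingParams) -> Call:
    t = a + b
    if t < params.min_depth:
        return Call.MISSING
    f = b / t
    eps = 1e-9  # keep the thresholds inclusive under float round-off
    if f <= (1 - params.hom_frac) + eps:
        return Call.REF_A
    if f >= params.hom_frac - eps:
        return Call.REF_B
    return Call.HET


def genotype_accession(accession: str, sam_a: str | Path, sam_b: str | Path,
                       svs: list[StructuralVariant],
                       params: GenotypingParams = GenotypingParams()
                       ) -> list[SvGenotypeCall]:
    """Genotype every SV for one accession from its alignments to both assemblies."""
    trees_a, trees_b = sv_windows(svs, params.w)
    sup_a = _collect_supports(sam_a, trees_a, params.max_mismatch_frac)
    sup_b = _collect_supports(sam_b, trees_b, params.max_mismatch_frac)
    calls = []
    for sv in svs:
        names_a = sup_a.get(sv.id, set())
        names_b = sup_b.get(sv.id, set())
        dual = names_a & names_b        # uninformative: qualifies on both references
        a = len(names_a - dual)
        b = len(names_b - dual)
        calls.append(SvGenotypeCall(sv_id=sv.id, accession=accession,
                                    call=classify_counts(a, b, params),
                                    support_a=a, support_b=b))
    return calls


def genotype_population(sam_a_by_acc: Mapping[str, str], sam_b_by_acc: Mapping[str, str],
                        svs: list[StructuralVariant], groups: pd.Series,
                        params: GenotypingParams = GenotypingParams()
                        ) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Genotype all accessions; returns (matrix, per-accession summary, supports)."""
    all_calls: list[SvGenotypeCall] = []
    for acc in groups.index:
        all_calls.extend(genotype_accession(acc, sam_a_by_acc[acc], sam_b_by_acc[acc],
                                            svs, params))
    matrix, summary = build_genotype_matrix(all_calls, groups)
    supports = {(c.sv_id, c.accession): (c.support_a, c.support_b) for c in all_calls}
    return matrix, summary, supports


def build_genotype_matrix(calls: Iterable[SvGenotypeCall], groups: pd.Series
                          ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Assemble the loci x accessions dosage matrix and per-accession class shares.

    The summary gives, per accession, the percentage of genotyped loci in each
    class (REF_A / HET / REF_B summing to 100) plus the missing rate; a pooled
    row aggregates locus-level counts across all accessions.
    """
    seen: set[tuple[str, str]] = set()
    data: dict[str, dict[str, float]] = defaultdict(dict)
    counts: dict[str, dict[Call, int]] = defaultdict(lambda: defaultdict(int))
    for c in calls:
        key = (c.sv_id, c.accession)
        if key in seen:
            raise ValueError(f"duplicate genotype call for {key}")
        seen.add(key)
        data[c.accession][c.sv_id] = np.nan if c.call == Call.MISSING else float(c.dosage)
        counts[c.accession][c.call] += 1

    dosages = pd.DataFrame(data).reindex(columns=list(groups.index))
    matrix = GenotypeMatrix(dosages, groups)

    rows = []
    pooled = defaultdict(int)
    for acc in groups.index:
        cc = counts[acc]
        genotyped = cc[Call.REF_A] + cc[Call.HET] + cc[Call.REF_B]
        total = genotyped + cc[Call.MISSING]
        for call, n in cc.items():
            pooled[call] += n
        if genotyped == 0:
            logger.warning("accession %s: no genotyped loci; excluded from summary", acc)
            continue
        rows.append({
            "accession": acc, "group": groups[acc],
            "pct_ref_a": 100.0 * cc[Call.REF_A] / genotyped,
            "pct_het": 100.0 * cc[Call.HET] / genotyped,
            "pct_ref_b": 100.0 * cc[Call.REF_B] / genotyped,
            "missing_rate": cc[Call.MISSING] / total if total else np.nan,
            "n_genotyped": genotyped,
        })
    summary = pd.DataFrame(rows)
    g_pool = pooled[Call.REF_A] + pooled[Call.HET] + pooled[Call.REF_B]
    if g_pool and len(summary):
        pooled_row = {
            "accession": "__pooled__", "group": "all",
            "pct_ref_a": 100.0 * pooled[Call.REF_A] / g_pool,
            "pct_het": 100.0 * pooled[Call.HET] / g_pool,
            "pct_ref_b": 100.0 * pooled[Call.REF_B] / g_pool,
            "missing_rate": pooled[Call.MISSING] / (g_pool + pooled[Call.MISSING]),
            "n_genotyped": g_pool,
        }
        summary = pd.concat([summary, pd.DataFrame([pooled_row])], ignore_index=True)
    return matrix, summary


def filter_matrix(matrix: GenotypeMatrix, min_call_rate: float = 0.70,
                  min_maf: float = 0.03) -> GenotypeMatrix:
    """Drop loci with call rate < min_call_rate or MAF < min_maf (inclusive thresholds)."""
    keep = matrix.loci[(matrix.call_rate >= min_call_rate) & (matrix.maf >= min_maf)]
    if len(keep) == 0:
        logger.warning("filter_matrix: no locus passes call_rate >= %.2f and MAF >= %.3f",
                       min_call_rate, min_maf)
    return matrix.subset_loci(keep)
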