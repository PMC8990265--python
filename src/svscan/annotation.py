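"""Genic-context classification of SVs and SV-to-gene mapping.

Each SV gets exactly one category with precedence
exonic > intronic > upstream > downstream > intergenic; upstream/downstream
flanks are strand-aware (upstream = 5' of the gene on its own strand).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, StructuralVariant, SvContext

logger = logging.getLogger(__name__)

CATEGORIES = ["exonic", "intronic", "upstream", "downstream", "intergenic"]
DEFAULT_FLANK = 2_000


def _sv_interval(sv: StructuralVariant) -> tuple[int, int]:
    """Any-base-overlap interval; insertions are half-open single-base breakpoints."""
    if sv.ref_end > sv.ref_start:
        return sv.ref_start, sv.ref_end
    return sv.ref_start, sv.ref_start + 1


class _GeneIndex:
    def __init__(self, genes: Iterable[GeneModel], upstream_bp: int, downstream_bp: int):
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.genes = list(genes)
        for g in self.genes:
            up, down = (upstream_bp, downstream_bp) if g.strand != "-" else (
                downstream_bp, upstream_bp)
            lo = max(0, g.start - up)
            hi = g.end + down
            self.trees[g.chrom].addi(lo, hi, g)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        return [iv.data for iv in self.trees[chrom].overlap(start, end)]


def _categorize(sv_start: int, sv_end: int, gene: GeneModel,
                upstream_bp: int, downstream_bp: int) -> str | None:
    """Category of an SV interval w.r.t. one gene, or None if outside its flanks."""
    if sv_start < gene.end and sv_end > gene.start:
        exons = gene.exons or [(gene.start, gene.end)]
        if any(sv_start < ee and sv_end > es for es, ee in exons):
            return "exonic"
        return "intronic"
    if gene.strand != "-":
        up_iv = (gene.start - upstream_bp, gene.start)
        down_iv = (gene.end, gene.end + downstream_bp)
    else:
        up_iv = (gene.end, gene.end + upstream_bp)
        down_iv = (gene.start - downstream_bp, gene.start)
    if sv_start < up_iv[1] and sv_end > up_iv[0]:
        return "upstream"
    if sv_start < down_iv[1] and sv_end > down_iv[0]:
        return "downstream"
    return None


_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}


def classify_sv_context(sv: StructuralVariant, genes: _GeneIndex | list[GeneModel],
                        upstream_bp: int = DEFAULT_FLANK,
                        downstream_bp: int = DEFAULT_FLANK) -> SvContext:
    """Single-category genic context for one SV (highest-precedence gene wins)."""
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(
        genes, upstream_bp, downstream_bp)
    s, e = _sv_interval(sv)
    if sv.ref_name not in index.trees:
        logger.warning("SV %s on %s: chromosome absent from annotation", sv.id, sv.ref_name)
        return SvContext(sv_id=sv.id, category="intergenic")
    best: tuple[int, str, GeneModel] | None = None
    for gene in index.overlapping(sv.ref_name, s, e):
        cat = _categorize(s, e, gene, upstream_bp, downstream_bp)
        if cat is None:
            continue
        key = (_PRECEDENCE[cat], gene.gene_id)
        if best is None or key < (best[0], best[2].gene_id):
            best = (_PRECEDENCE[cat], cat, gene)
    if best is None:
        return SvContext(sv_id=sv.id, category="intergenic")
    gene = best[2]
    if s < gene.end and e > gene.start:
        dist = 0
    elif s >= gene.end:
        dist = s - gene.end
    else:
        dist = gene.start - e
    return SvContext(sv_id=sv.id, category=best[1], gene_id=gene.gene_id,
                     distance_to_gene=dist)


def classify_all(svs: Iterable[StructuralVariant], genes: list[GeneModel],
                 upstream_bp: int = DEFAULT_FLANK,
                 downstream_bp: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Context table for an SV set; one row per SV."""
    index = _GeneIndex(genes, upstream_bp, downstream_bp)
    rows = []
    for sv in svs:
        ctx = classify_sv_context(sv, index, upstream_bp, downstream_bp)
        rows.append({"sv_id": ctx.sv_id, "category": ctx.category,
                     "gene_id": ctx.gene_id, "distance_to_gene": ctx.distance_to_gene})
    return pd.DataFrame(rows, columns=["sv_id", "category", "gene_id", "distance_to_gene"])


def map_svs_to_genes(svs: Iterable[StructuralVariant], genes: list[GeneModel],
                     flank_bp: int = DEFAULT_FLANK) -> pd.DataFrame:
    """All (sv_id, gene_id) pairs where the SV overlaps gene span +/- flank."""
    index = _GeneIndex(genes, flank_bp, flank_bp)
    rows = []
    for sv in svs:
        s, e = _sv_interval(sv)
        if sv.ref_name not in index.trees:
            continue
        for gene in sorted(index.overlapping(sv.ref_name, s, e), key=lambda g: g.gene_id):
            rows.append({"sv_id": sv.id, "gene_id": gene.gene_id})
    return pd.DataFrame(rows, columns=["sv_id", "gene_id"])


def category_counts(context_table: pd.DataFrame) -> dict[str, int]:
    counts = context_table["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}
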