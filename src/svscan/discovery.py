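"""Indel discovery between two assemblies from a whole-genome alignment.

Two call paths, in the style of unique-anchor alignment SV callers:

* within-alignment: every I/D CIGAR operation in the size window becomes a
  call with exact breakpoints in both assemblies;
* between-alignment: for adjacent well-anchored alignment blocks on the same
  (query, ref, strand), the difference between the reference gap and the
  query gap is called as an insertion (query excess) or deletion (reference
  excess).

Coordinates are 0-based half-open; insertions are zero-width breakpoints on
the reference with the inserted sequence living in the query assembly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .models import AlignmentBlock, StructuralVariant, SvType, parse_cigar

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10        # smallest indel reported
DEFAULT_MAX_SIZE = 50_000    # size cap (a filter, above the largest expected call)
DEFAULT_MIN_ANCHOR = 1_000   # unique-anchor length for between-alignment calls


def call_within_alignment_indels(block: AlignmentBlock, min_size: int = DEFAULT_MIN_SIZE,
                                 max_size: int = DEFAULT_MAX_SIZE) -> list[StructuralVariant]:
    """Walk the CIGAR; each I/D run with length in [min_size, max_size] is one call."""
    out: list[StructuralVariant] = []
    ref_pos = block.ref_start
    q_pos = block.query_start
    for n, op in parse_cigar(block.cigar):
        if op in "M=X":
            ref_pos += n
            q_pos += n
        elif op == "I":
            if min_size <= n <= max_size:
                out.append(StructuralVariant(
                    id="", ref_name=block.ref_name, ref_start=ref_pos, ref_end=ref_pos,
                    size=n, type=SvType.INSERTION, origin="within_alignment",
                    query_name=block.query_name, query_start=q_pos, query_end=q_pos + n))
            q_pos += n
        elif op in "DN":
            if min_size <= n <= max_size:
                out.append(StructuralVariant(
                    id="", ref_name=block.ref_name, ref_start=ref_pos, ref_end=ref_pos + n,
                    size=n, type=SvType.DELETION, origin="within_alignment",
                    query_name=block.query_name, query_start=q_pos, query_end=q_pos))
            ref_pos += n
        elif op in "SH":
            if op == "S":
                q_pos += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} in alignment block")
    return out


def call_between_alignment_indels(blocks: Iterable[AlignmentBlock],
                                  min_size: int = DEFAULT_MIN_SIZE,
                                  max_size: int = DEFAULT_MAX_SIZE,
                                  min_anchor: int = DEFAULT_MIN_ANCHOR) -> list[StructuralVariant]:
    """Net indels between adjacent anchors.

    Blocks are grouped by (query_name, ref_name, strand); within a group, for
    each adjacent pair sorted by ref_start, ``net = query_gap - ref_gap``
    becomes an insertion (net >= min_size) or deletion (-net >= min_size).
    Pairs with an overlap on either axis, a gap above max_size, or a flanking
    anchor shorter than min_anchor are skipped.
    """
    groups: dict[tuple, list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.query_name, b.ref_name, b.strand), []).append(b)
    out: list[StructuralVariant] = []
    for (qname, rname, strand), grp in sorted(groups.items()):
        if any(grp[i].ref_start > grp[i + 1].ref_start for i in range(len(grp) - 1)):
            raise ValueError("alignment blocks must be sorted by ref_start within a group")
        for prev, nxt in zip(grp, grp[1:]):
            if (prev.ref_end - prev.ref_start < min_anchor
                    or nxt.ref_end - nxt.ref_start < min_anchor):
                logger.debug("anchor below %d bp between %s:%d and %d; skipped",
                             min_anchor, rname, prev.ref_end, nxt.ref_start)
                continue
            ref_gap = nxt.ref_start - prev.ref_end
            if strand == "+":
                query_gap = nxt.query_start - prev.query_end
                q_lo = prev.query_end
            else:
                # query coords already forward-normalized; on '-' the query runs
                # backwards along the reference, so the gap precedes prev
                query_gap = prev.query_start - nxt.query_end
                q_lo = nxt.query_end
            if ref_gap < 0 or query_gap < 0:
                logger.debug("overlapping anchors at %s:%d; skipped", rname, prev.ref_end)
                continue
            if ref_gap > max_size or query_gap > max_size:
                logger.debug("gap above max_size at %s:%d; skipped", rname, prev.ref_end)
                continue
            net = query_gap - ref_gap
            if net >= min_size:
                out.append(StructuralVariant(
                    id="", ref_name=rname, ref_start=prev.ref_end, ref_end=prev.ref_end,
                    size=net, type=SvType.INSERTION, origin="between_alignment",
                    query_name=qname, query_start=q_lo, query_end=q_lo + net))
            elif -net >= min_size:
                out.append(StructuralVariant(
                    id="", ref_name=rname, ref_start=prev.ref_end,
                    ref_end=prev.ref_end - net, size=-net, type=SvType.DELETION,
                    origin="between_alignment",
                    query_name=qname, query_start=q_lo, query_end=q_lo))
    return out


def merge_and_filter_svs(calls: Iterable[StructuralVariant],
                         min_size: int = DEFAULT_MIN_SIZE,
                         max_size: int = DEFAULT_MAX_SIZE,
                         breakpoint_tol: int = 10,
                         size_tol_frac: float = 0.10) -> list[StructuralVariant]:
    """Deduplicate and size-filter, preferring within-alignment calls.

    Calls of the same type whose ref breakpoints lie within ``breakpoint_tol``
    bp and whose sizes agree within ``size_tol_frac`` are collapsed; stable
    ids sv00000.. are assigned in (ref_name, ref_start) order.
    """
    kept: list[StructuralVariant] = []
    pool = [c for c in calls if min_size <= c.size <= max_size]
    pool.sort(key=lambda s: (s.ref_name, s.ref_start, 0 if s.origin == "within_alignment" else 1))
    for c in pool:
        dup = False
        for k in reversed(kept):
            if k.ref_name != c.ref_name:
                break
            if c.ref_start - k.ref_start > breakpoint_tol + max_size:
                break
            if (k.type == c.type
                    and abs(k.ref_start - c.ref_start) <= breakpoint_tol
                    and abs(k.ref_end - c.ref_end) <= breakpoint_tol + abs(k.size - c.size)
                    and abs(k.size - c.size) <= size_tol_frac * max(k.size, c.size)):
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda s: (s.ref_name, s.ref_start, s.ref_end))
    for i, sv in enumerate(kept):
        sv.id = f"sv{i:05d}"
    return kept


def fill_insertion_sequences(svs: list[StructuralVariant],
                             genome_b: Mapping[str, np.ndarray]) -> None:
    """Attach inserted sequence from the query assembly to insertion calls."""
    for sv in svs:
        if sv.type == SvType.INSERTION and sv.alt_seq is None and sv.query_name is not None:
            seq = genome_b[sv.query_name][sv.query_start:sv.query_end]
            sv.alt_seq = seq.tobytes().decode("ascii")


def discover_svs(paf_path: str | Path, min_size: int = DEFAULT_MIN_SIZE,
                 max_size: int = DEFAULT_MAX_SIZE, min_anchor: int = DEFAULT_MIN_ANCHOR,
                 genome_b: Optional[Mapping[str, np.ndarray]] = None
                 ) -> tuple[list[StructuralVariant], dict]:
    """Full discovery: parse PAF, run both callers, merge, optionally add alt_seq."""
    from .io import parse_paf

    blocks, report = parse_paf(paf_path)
    calls = []
    for b in blocks:
        calls.extend(call_within_alignment_indels(b, min_size, max_size))
    calls.extend(call_between_alignment_indels(blocks, min_size, max_size, min_anchor))
    svs = merge_and_filter_svs(calls, min_size, max_size)
    if genome_b is not None:
        fill_insertion_sequences(svs, genome_b)
    report["n_calls"] = len(svs)
    return svs, report
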