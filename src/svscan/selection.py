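"""Wild-vs-cultivated allele-frequency differentiation scan.

Per SV the diploid genotypes are collapsed to B-allele counts in each group
(2 alleles per genotyped accession, MISSING excluded), a two-sided Fisher
exact test compares the 2x2 allele table, p-values are Benjamini-Hochberg
adjusted across all tested SVs, and loci with corrected P < alpha are flagged
as under selection.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import FreqRecord, GenotypeMatrix, SelectionResult

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def group_allele_frequencies(matrix: GenotypeMatrix,
                             wild_label: str = "wild",
                             cult_label: str = "cultivated") -> list[FreqRecord]:
    """B-allele counts and frequencies per group; loci with an empty group skipped."""
    wild = matrix.group_accessions(wild_label)
    cult = matrix.group_accessions(cult_label)
    if len(wild) == 0 or len(cult) == 0:
        raise ValueError("both groups must contain at least one accession")
    dw = matrix.dosages[wild]
    dc = matrix.dosages[cult]
    records: list[FreqRecord] = []
    for sv_id in matrix.loci:
        nw = int(dw.loc[sv_id].notna().sum()) * 2
        nc = int(dc.loc[sv_id].notna().sum()) * 2
        if nw == 0 or nc == 0:
            logger.warning("locus %s: a group has no genotyped accession; skipped", sv_id)
            continue
        records.append(FreqRecord(
            sv_id=sv_id,
            n_wild_alleles=nw, n_cult_alleles=nc,
            b_count_wild=int(dw.loc[sv_id].sum(skipna=True)),
            b_count_cult=int(dc.loc[sv_id].sum(skipna=True)),
        ))
    return records


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (minimum-likelihood rule).

    A zero row or column margin carries no information about association and
    returns p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        logger.debug("degenerate 2x2 margin; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if np.isnan(p).any():
        bad = np.flatnonzero(np.isnan(p))
        raise ValueError(f"NaN p-value at positions {bad.tolist()}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_svs(freq_records: list[FreqRecord], alpha: float = DEFAULT_ALPHA
               ) -> list[SelectionResult]:
    """Fisher test per SV on [[b_wild, nonB_wild], [b_cult, nonB_cult]] + BH-FDR."""
    pvals = [
        fisher_exact_2x2([
            [r.b_count_wild, r.n_wild_alleles - r.b_count_wild],
            [r.b_count_cult, r.n_cult_alleles - r.b_count_cult],
        ])
        for r in freq_records
    ]
    qvals = bh_fdr(pvals)
    return [SelectionResult(sv_id=r.sv_id, p=p, q=float(q), selected=bool(q < alpha))
            for r, p, q in zip(freq_records, pvals, qvals)]


def selection_table(freq_records: list[FreqRecord],
                    results: list[SelectionResult]) -> pd.DataFrame:
    """FreqRecord + SelectionResult merged into one tidy report table."""
    rows = []
    res_by_id = {r.sv_id: r for r in results}
    for fr in freq_records:
        r = res_by_id.get(fr.sv_id)
        if r is None:
            continue
        rows.append({
            "sv_id": fr.sv_id,
            "n_wild_alleles": fr.n_wild_alleles, "n_cult_alleles": fr.n_cult_alleles,
            "b_count_wild": fr.b_count_wild, "b_count_cult": fr.b_count_cult,
            "freq_wild": fr.freq_wild, "freq_cult": fr.freq_cult,
            "fisher_p": r.p, "fdr_q": r.q, "selected": r.selected,
        })
    return pd.DataFrame(rows)


def run_selection_scan(matrix: GenotypeMatrix, alpha: float = DEFAULT_ALPHA
                       ) -> pd.DataFrame:
    records = group_allele_frequencies(matrix)
    results = select_svs(records, alpha=alpha)
    return selection_table(records, results)
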