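"""Windowed population-genetic statistics on a biallelic SNP panel.

Implements the sequence-level selection evidence of a two-population
domestication scan: per-window nucleotide diversity pi (per group),
Weir-Cockerham (1984) F_ST in ratio-of-sums form, empirical top-fraction
outlier flagging, LD-decay r^2 binned by distance, and genotype PCA.

Windows are non-overlapping tiles (15 kb default); pi is normalized by the
full window length, matching the common VCFtools convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 15_000
DEFAULT_TOP_FRACTION = 0.05


@dataclass
class SnpPanel:
    """Biallelic SNP sites + accessions x sites dosage matrix + group labels."""

    sites: pd.DataFrame          # columns: id, chrom, pos (0-based)
    dosages: pd.DataFrame        # accessions x site-ids, values 0/1/2/NaN
    groups: pd.Series            # accession -> group label

    def __post_init__(self) -> None:
        for chrom, sub in self.sites.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions must be strictly increasing on {chrom}")

    def group_dosages(self, group: str) -> np.ndarray:
        accs = self.groups.index[self.groups == group]
        return self.dosages.loc[accs].to_numpy(dtype=float)

    @classmethod
    def from_vcf(cls, vcf_path, groups: pd.Series) -> "SnpPanel":
        from .io import read_snp_panel
        sites, dosages = read_snp_panel(vcf_path)
        return cls(sites=sites, dosages=dosages.loc[groups.index], groups=groups)


def _site_pi(dos: np.ndarray) -> np.ndarray:
    """Per-site unbiased pi: (n/(n-1)) * 2p(1-p), n = non-missing allele count."""
    called = ~np.isnan(dos)
    n = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / n
        pi = np.where(n > 1, n / (n - 1) * 2.0 * p * (1.0 - p), np.nan)
    pi[n == 0] = np.nan
    return pi


def _windows_for(chrom_len: int, window_bp: int) -> np.ndarray:
    edges = np.arange(0, chrom_len + window_bp, window_bp)
    return edges


def window_pi(panel: SnpPanel, group: str, window_bp: int = DEFAULT_WINDOW_BP,
              chrom_lens: Optional[Mapping[str, int]] = None) -> pd.DataFrame:
    """Per-window pi for one group: sum of per-site pi over window length.

    Monomorphic (and unobserved) positions contribute zero; a window whose
    sites are all missing reports NaN rather than zero.
    """
    dos = panel.group_dosages(group)
    if dos.shape[0] == 0:
        raise ValueError(f"group {group!r} is empty")
    pi_site = _site_pi(dos)
    rows = []
    for chrom, sub in panel.sites.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        length = (chrom_lens or {}).get(chrom, int(pos.max()) + 1 if len(pos) else window_bp)
        edges = _windows_for(length, window_bp)
        which = np.digitize(pos, edges) - 1
        for w in range(len(edges) - 1):
            in_w = which == w
            vals = pi_site[idx[in_w]]
            n_snps = int(in_w.sum())
            if n_snps and np.all(np.isnan(vals)):
                pi = np.nan
            else:
                pi = float(np.nansum(vals)) / window_bp
            rows.append({"chrom": chrom, "start": int(edges[w]), "end": int(edges[w + 1]),
                         "n_snps": n_snps, "pi": pi})
    return pd.DataFrame(rows)


def weir_cockerham_components(n1, p1, h1, n2, p2, h2):
    """Per-site Weir-Cockerham (1984) variance components (a, b, c), two populations.

    n_i: genotyped individuals, p_i: allele frequency, h_i: observed
    heterozygote proportion in population i.  Vectorized over sites.
    """
    n1, p1, h1 = (np.asarray(x, dtype=float) for x in (n1, p1, h1))
    n2, p2, h2 = (np.asarray(x, dtype=float) for x in (n2, p2, h2))
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
                       / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, b, c


def _group_site_stats(dos: np.ndarray):
    called = ~np.isnan(dos)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n)
        h = (dos == 1).sum(axis=0) / n
    return n, p, h


def window_fst(panel: SnpPanel, window_bp: int = DEFAULT_WINDOW_BP,
               chrom_lens: Optional[Mapping[str, int]] = None,
               group_labels: Sequence[str] = ("wild", "cultivated")) -> pd.DataFrame:
    """Ratio-of-sums Weir-Cockerham F_ST per window (and per-site components).

    Sites with fewer than two genotyped accessions in either group are
    excluded; a window with no usable site reports NaN.
    """
    g1, g2 = group_labels
    d1 = panel.group_dosages(g1)
    d2 = panel.group_dosages(g2)
    n1, p1, h1 = _group_site_stats(d1)
    n2, p2, h2 = _group_site_stats(d2)
    usable = (n1 >= 2) & (n2 >= 2)
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    a = np.where(usable, a, np.nan)
    denom_site = a + b + c
    rows = []
    for chrom, sub in panel.sites.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        length = (chrom_lens or {}).get(chrom, int(pos.max()) + 1 if len(pos) else window_bp)
        edges = _windows_for(length, window_bp)
        which = np.digitize(pos, edges) - 1
        for w in range(len(edges) - 1):
            sel = idx[which == w]
            sel = sel[usable[sel]]
            if len(sel) == 0:
                fst = np.nan
            else:
                num = np.nansum(a[sel])
                den = np.nansum(denom_site[sel])
                fst = num / den if den > 0 else np.nan
            rows.append({"chrom": chrom, "start": int(edges[w]), "end": int(edges[w + 1]),
                         "n_snps": int(len(sel)), "fst": fst})
    return pd.DataFrame(rows)


def genome_fst(panel: SnpPanel, group_labels: Sequence[str] = ("wild", "cultivated")
               ) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham estimate across all usable sites."""
    d1 = panel.group_dosages(group_labels[0])
    d2 = panel.group_dosages(group_labels[1])
    n1, p1, h1 = _group_site_stats(d1)
    n2, p2, h2 = _group_site_stats(d2)
    usable = (n1 >= 2) & (n2 >= 2)
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    num = np.nansum(a[usable])
    den = np.nansum((a + b + c)[usable])
    return float(num / den) if den > 0 else float("nan")


def window_stats(panel: SnpPanel, window_bp: int = DEFAULT_WINDOW_BP,
                 chrom_lens: Optional[Mapping[str, int]] = None) -> pd.DataFrame:
    """Combined per-window table: pi per group, pi ratio (wild/cultivated), F_ST."""
    pw = window_pi(panel, "wild", window_bp, chrom_lens).rename(columns={"pi": "pi_wild"})
    pc = window_pi(panel, "cultivated", window_bp, chrom_lens).rename(columns={"pi": "pi_cult"})
    fst = window_fst(panel, window_bp, chrom_lens)
    df = pw.merge(pc[["chrom", "start", "pi_cult"]], on=["chrom", "start"])
    df = df.merge(fst[["chrom", "start", "fst"]], on=["chrom", "start"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pi_ratio"] = df["pi_wild"] / df["pi_cult"]
    df.loc[~np.isfinite(df["pi_ratio"]), "pi_ratio"] = np.nan
    return df


def top_fraction_outliers(stats: pd.DataFrame, fraction: float = DEFAULT_TOP_FRACTION,
                          metrics: Sequence[str] = ("fst", "pi_ratio")) -> pd.DataFrame:
    """Flag windows at or above the empirical (1-fraction) quantile per metric.

    With fewer than 1/fraction informative windows only the maximum is
    flagged.  Ties at the threshold are all flagged (documented tie rule).
    """
    out = stats.copy()
    for metric in metrics:
        vals = out[metric].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        col = f"outlier_{metric}"
        if len(finite) == 0:
            out[col] = False
            continue
        if len(finite) < 1.0 / fraction:
            logger.warning("only %d informative windows for %s; flagging the maximum only",
                           len(finite), metric)
            thr = finite.max()
        else:
            thr = np.quantile(finite, 1.0 - fraction, method="higher")
        out[col] = np.isfinite(vals) & (vals >= thr)
    return out


def ld_decay(panel: SnpPanel, group: str, max_dist: int = 50_000,
             bin_bp: int = 1_000) -> pd.DataFrame:
    """Distance-binned mean r^2 between SNP dosages within each chromosome.

    r^2 is the squared Pearson correlation of dosage vectors over
    pairwise-complete accessions; monomorphic or zero-variance pairs are
    skipped.
    """
    dos = panel.group_dosages(group)
    sums = np.zeros(int(np.ceil(max_dist / bin_bp)))
    counts = np.zeros_like(sums, dtype=int)
    for chrom, sub in panel.sites.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        cols = dos[:, idx]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                dist = pos[j] - pos[i]
                if dist > max_dist:
                    break
                x, y = cols[:, i], cols[:, j]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                b = min(int(max(dist - 1, 0) // bin_bp), len(sums) - 1)
                sums[b] += r * r
                counts[b] += 1
    rows = []
    for b in range(len(sums)):
        rows.append({"dist_lo": b * bin_bp, "dist_hi": (b + 1) * bin_bp,
                     "mean_r2": sums[b] / counts[b] if counts[b] else np.nan,
                     "n_pairs": int(counts[b])})
    return pd.DataFrame(rows)


def genotype_pca(dosages: pd.DataFrame, k: int = 10, scale: bool = False
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of an accessions x loci dosage matrix.

    Missing dosages are mean-imputed per locus and columns centered
    (optionally scaled by sqrt(2p(1-p))); coordinates come from a full SVD
    with a deterministic sign convention (largest-|coordinate| entry of each
    PC made positive).  Returns (coordinates, explained variance ratio).
    """
    X = dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(X)
    X = np.where(nan_mask, col_mean[None, :], X)
    X = X - col_mean[None, :]
    if scale:
        p = col_mean / 2.0
        denom = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
        X = X / denom[None, :]
    rank = int(np.linalg.matrix_rank(X)) if min(X.shape) else 0
    if k > max(rank, 1):
        logger.warning("k=%d exceeds matrix rank %d; truncating", k, rank)
    k_eff = max(1, min(k, min(X.shape)))
    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k_eff] * S[:k_eff]
    for j in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    total_var = float((S**2).sum())
    evr = (S[:k_eff] ** 2) / total_var if total_var > 0 else np.zeros(k_eff)
    out = pd.DataFrame(coords, index=dosages.index,
                       columns=[f"PC{j + 1}" for j in range(k_eff)])
    return out, evr
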