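"""Synthetic dual-genome, population and resequencing-read generator.

Emulates the study design every downstream stage needs: a pair of assemblies
("A" = wild-type reference, "B" = the second assembly) differing only by
planted indels (10 bp - 20 kb, most < 100 bp) and SNPs; a two-group diploid
population (28 wild / 32 cultivated by default) whose background loci follow
the Balding-Nichols model and whose "selected" loci carry a large wild-vs-
cultivated allele-frequency shift; and paired-end reads with exact truth
alignments (SAM) against both assemblies, so genotyping can be validated
without an external aligner.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as svio
from .models import AlignmentBlock, GeneModel, StructuralVariant, SvType

_CODE2ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_ASCII2CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII2CODE[_b] = _i


class CapacityError(ValueError):
    """Requested SV count cannot be placed at the required spacing."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults mirror the study design: 28 wild + 32 cultivated diploid
    accessions, SV sizes 10 bp to 20 kb with 87.7% below 100 bp, 150 bp
    paired-end reads from ~450 bp inserts.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 200_000
    n_sv: int = 100
    sv_size_min: int = 10
    sv_size_max: int = 20_000
    frac_small: float = 0.877
    snp_rate: float = 5e-4
    n_wild: int = 28
    n_cult: int = 32
    n_selected_sv: int = 10
    min_freq_shift: float = 0.6
    fst_background: float = 0.05
    depth: float = 20.0
    read_len: int = 150
    insert_size: int = 450
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_background < 1.0):
            raise ValueError("fst_background must be in (0, 1)")
        if self.sv_size_min < 1:
            raise ValueError("sv_size_min must be >= 1")
        if not (0.0 <= self.frac_small <= 1.0):
            raise ValueError("frac_small must be in [0, 1]")
        if self.sv_size_max < self.sv_size_min:
            raise ValueError("sv_size_max < sv_size_min")
        if self.read_len > self.chrom_len:
            raise ValueError("read_len exceeds chrom_len")
        if self.insert_size < self.read_len:
            raise ValueError("insert_size must be >= read_len")
        if self.n_selected_sv > self.n_sv:
            raise ValueError("n_selected_sv > n_sv")
        if not (0.0 < self.min_freq_shift <= 0.96):
            raise ValueError("min_freq_shift must be in (0, 0.96]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @property
    def accessions(self) -> list[str]:
        return ([f"W{i + 1:02d}" for i in range(self.n_wild)]
                + [f"C{i + 1:02d}" for i in range(self.n_cult)])

    @property
    def groups(self) -> pd.Series:
        labels = ["wild"] * self.n_wild + ["cultivated"] * self.n_cult
        return pd.Series(labels, index=self.accessions, name="group")


@dataclass
class TruthSet:
    """Ground truth for everything the pipeline should recover."""

    svs: list[StructuralVariant]
    snp_sites: pd.DataFrame                     # id, chrom, pos (0-based), ref, alt
    sv_freqs: pd.DataFrame = field(default_factory=pd.DataFrame)   # freq_wild, freq_cult, selected
    snp_freqs: pd.DataFrame = field(default_factory=pd.DataFrame)
    sv_genotypes: pd.DataFrame = field(default_factory=pd.DataFrame)   # sv x accession dosage
    snp_genotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    groups: pd.Series = field(default_factory=pd.Series)
    selected_ids: list[str] = field(default_factory=list)


# ------------------------------------------------------------------ genomes

def _draw_sv_sizes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Two-component log-uniform size mixture: [min,99] w.p. frac_small else [100,max]."""
    small_hi = min(99, cfg.sv_size_max)
    large_lo = max(100, cfg.sv_size_min)
    is_small = rng.random(cfg.n_sv) < cfg.frac_small
    if cfg.sv_size_max < 100:
        is_small[:] = True
    if cfg.sv_size_min > 99:
        is_small[:] = False
    sizes = np.empty(cfg.n_sv, dtype=np.int64)
    for mask, lo, hi in ((is_small, cfg.sv_size_min, small_hi),
                         (~is_small, large_lo, cfg.sv_size_max)):
        n = int(mask.sum())
        if n:
            u = rng.uniform(math.log(lo), math.log(hi + 1), n)
            sizes[mask] = np.minimum(np.floor(np.exp(u)).astype(np.int64), hi)
    return np.maximum(sizes, cfg.sv_size_min)


def generate_genome_pair(cfg: SimConfig):
    """Build genome A, apply planted indels + SNPs to obtain genome B.

    Returns ``(genome_a, genome_b, truth, blocks)`` where the genomes are
    dicts of chromosome-name -> ASCII uint8 arrays, ``truth`` carries the SV
    and SNP records with coordinates in both assemblies, and ``blocks`` is
    the exact whole-genome alignment implied by the edits (one PAF block per
    chromosome, plus-strand, cg CIGAR of M/I/D runs).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_place, rng_snp = (np.random.default_rng(s) for s in ss.spawn(3))

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    genome_a = {c: _CODE2ASCII[rng_genome.integers(0, 4, cfg.chrom_len)] for c in chrom_names}

    sizes = _draw_sv_sizes(rng_place, cfg)
    is_ins = rng_place.random(cfg.n_sv) < 0.5
    # allocate SVs to chromosomes uniformly, then place with enforced spacing
    chrom_of = rng_place.integers(0, cfg.n_chrom, cfg.n_sv)
    spacing = 2 * cfg.read_len + cfg.insert_size   # no fragment spans two SVs
    margin = cfg.insert_size + cfg.read_len

    svs: list[StructuralVariant] = []
    genome_b: dict[str, np.ndarray] = {}
    blocks: list[AlignmentBlock] = []
    snp_rows: list[dict] = []
    sv_counter = 0

    for ci, chrom in enumerate(chrom_names):
        idx = np.flatnonzero(chrom_of == ci)
        sz = sizes[idx]
        ins = is_ins[idx]
        ref_spans = np.where(ins, 0, sz)
        needed = int(ref_spans.sum()) + spacing * len(idx)
        slack = cfg.chrom_len - 2 * margin - needed
        if slack < 0:
            raise CapacityError(
                f"{len(idx)} SVs (total ref span {int(ref_spans.sum())} bp) do not fit in "
                f"{chrom} ({cfg.chrom_len} bp) at spacing {spacing} bp"
            )
        extra = rng_place.multinomial(slack, np.full(len(idx) + 1, 1.0 / (len(idx) + 1)))
        pos = margin
        chrom_svs = []
        for k in range(len(idx)):
            pos += extra[k] + spacing // 2
            size = int(sz[k])
            if ins[k]:
                alt = _CODE2ASCII[rng_place.integers(0, 4, size)]
                sv = StructuralVariant(
                    id=f"sv{sv_counter:05d}", ref_name=chrom,
                    ref_start=pos, ref_end=pos, size=size, type=SvType.INSERTION,
                    query_name=chrom, alt_seq=alt.tobytes().decode("ascii"),
                )
            else:
                sv = StructuralVariant(
                    id=f"sv{sv_counter:05d}", ref_name=chrom,
                    ref_start=pos, ref_end=pos + size, size=size, type=SvType.DELETION,
                    query_name=chrom,
                )
            chrom_svs.append(sv)
            sv_counter += 1
            pos += int(ref_spans[k]) + spacing - spacing // 2

        # SNPs: uniform per-bp rate, outside SV loci (+/- 5 bp buffer)
        forbidden = np.zeros(cfg.chrom_len, dtype=bool)
        for sv in chrom_svs:
            forbidden[max(0, sv.ref_start - 5): min(cfg.chrom_len, sv.ref_end + 5)] = True
        snp_mask = (rng_snp.random(cfg.chrom_len) < cfg.snp_rate) & ~forbidden
        snp_pos = np.flatnonzero(snp_mask)
        ref_codes = _ASCII2CODE[genome_a[chrom][snp_pos]]
        alt_codes = (ref_codes + rng_snp.integers(1, 4, len(snp_pos))) % 4

        # genome B + both-coordinate breakpoints + CIGAR, in one walk
        a = genome_a[chrom]
        b_with_subs = a.copy()
        b_with_subs[snp_pos] = _CODE2ASCII[alt_codes]
        segments: list[np.ndarray] = []
        cigar_parts: list[str] = []
        cursor = 0
        offset = 0  # B pos - A pos for positions after the edits so far
        for sv in chrom_svs:
            mlen = sv.ref_start - cursor
            if mlen:
                segments.append(b_with_subs[cursor:sv.ref_start])
                cigar_parts.append(f"{mlen}M")
            b_pos = sv.ref_start + offset
            if sv.type == SvType.INSERTION:
                segments.append(svio.str_to_seq(sv.alt_seq))
                cigar_parts.append(f"{sv.size}I")
                sv.query_start, sv.query_end = b_pos, b_pos + sv.size
                offset += sv.size
                cursor = sv.ref_start
            else:
                cigar_parts.append(f"{sv.size}D")
                sv.query_start = sv.query_end = b_pos
                offset -= sv.size
                cursor = sv.ref_end
        if cursor < cfg.chrom_len:
            segments.append(b_with_subs[cursor:])
            cigar_parts.append(f"{cfg.chrom_len - cursor}M")
        genome_b[chrom] = (np.concatenate(segments) if segments
                           else np.empty(0, dtype=np.uint8))
        blocks.append(AlignmentBlock(
            ref_name=chrom, ref_start=0, ref_end=cfg.chrom_len,
            query_name=chrom, query_start=0, query_end=len(genome_b[chrom]),
            strand="+", cigar="".join(cigar_parts) or f"{cfg.chrom_len}M",
        ))
        svs.extend(chrom_svs)
        for p, rc, ac in zip(snp_pos, ref_codes, alt_codes):
            snp_rows.append({
                "id": f"snp_{chrom}_{int(p)}", "chrom": chrom, "pos": int(p),
                "ref": "ACGT"[rc], "alt": "ACGT"[ac],
            })

    snp_sites = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    truth = TruthSet(svs=svs, snp_sites=snp_sites)
    return genome_a, genome_b, truth, blocks


# ------------------------------------------------------------------ population

def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, fst: float,
                     size: tuple | int) -> np.ndarray:
    alpha = p_anc * (1 - fst) / fst
    beta = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(alpha, beta, size=size)


def simulate_population(truth: TruthSet, cfg: SimConfig) -> TruthSet:
    """Fill per-group allele frequencies and diploid genotypes into the truth.

    Background SVs and SNPs get independent wild/cultivated frequencies drawn
    from Beta(p(1-F)/F, (1-p)(1-F)/F) around a uniform ancestral frequency
    (Balding-Nichols with F = ``fst_background``); ``n_selected_sv`` randomly
    chosen SVs instead get a wild-vs-cultivated shift >= ``min_freq_shift``.
    Genotypes are Binomial(2, group frequency) per accession.
    """
    if cfg.n_wild < 1 or cfg.n_cult < 1:
        raise ValueError("both groups must be non-empty")
    ss = np.random.SeedSequence(cfg.seed + 1_000_003)
    rng = np.random.default_rng(ss)

    sv_ids = [sv.id for sv in truth.svs]
    n_sv = len(sv_ids)
    p_anc = rng.uniform(0.1, 0.9, n_sv)
    fw = _balding_nichols(rng, p_anc, cfg.fst_background, n_sv)
    fc = _balding_nichols(rng, p_anc, cfg.fst_background, n_sv)

    selected_idx = rng.choice(n_sv, size=min(cfg.n_selected_sv, n_sv), replace=False)
    for i in selected_idx:
        low = rng.uniform(0.02, max(0.021, 0.98 - cfg.min_freq_shift))
        hi = low + cfg.min_freq_shift
        if rng.random() < 0.5:
            fw[i], fc[i] = low, hi
        else:
            fw[i], fc[i] = hi, low
    selected_ids = [sv_ids[i] for i in sorted(selected_idx)]

    groups = cfg.groups
    geno = np.empty((n_sv, len(groups)), dtype=np.int8)
    wild_cols = np.asarray(groups.values == "wild")
    geno[:, wild_cols] = rng.binomial(2, fw[:, None], (n_sv, int(wild_cols.sum())))
    geno[:, ~wild_cols] = rng.binomial(2, fc[:, None], (n_sv, int((~wild_cols).sum())))

    truth.sv_freqs = pd.DataFrame(
        {"freq_wild": fw, "freq_cult": fc,
         "selected": np.isin(np.arange(n_sv), selected_idx)},
        index=pd.Index(sv_ids, name="sv_id"))
    truth.sv_genotypes = pd.DataFrame(geno, index=sv_ids, columns=groups.index, dtype=float)
    truth.groups = groups
    truth.selected_ids = selected_ids

    n_snp = len(truth.snp_sites)
    if n_snp:
        p_anc_s = rng.uniform(0.05, 0.95, n_snp)
        fws = _balding_nichols(rng, p_anc_s, cfg.fst_background, n_snp)
        fcs = _balding_nichols(rng, p_anc_s, cfg.fst_background, n_snp)
        geno_s = np.empty((n_snp, len(groups)), dtype=np.int8)
        geno_s[:, wild_cols] = rng.binomial(2, fws[:, None], (n_snp, int(wild_cols.sum())))
        geno_s[:, ~wild_cols] = rng.binomial(2, fcs[:, None], (n_snp, int((~wild_cols).sum())))
        snp_ids = truth.snp_sites["id"].tolist()
        truth.snp_freqs = pd.DataFrame({"freq_wild": fws, "freq_cult": fcs},
                                       index=pd.Index(snp_ids, name="snp_id"))
        truth.snp_genotypes = pd.DataFrame(geno_s, index=snp_ids,
                                           columns=groups.index, dtype=float)
    return truth


# ------------------------------------------------------------------ haplotype <-> reference maps

class HapRefMap:
    """Match-block alignment between a haplotype and one reference chromosome.

    ``indels`` are (ref_pos, kind, length) with kind 'ins' (haplotype-only
    sequence) or 'del' (reference-only sequence), sorted by ref_pos.
    Projects haplotype intervals to reference POS/CIGAR/NM-segments.
    """

    def __init__(self, ref_len: int, indels: list[tuple[int, str, int]]):
        hap_starts, ref_starts, lens = [], [], []
        ref_cursor = hap_cursor = 0
        for pos, kind, length in indels:
            mlen = pos - ref_cursor
            if mlen > 0:
                hap_starts.append(hap_cursor)
                ref_starts.append(ref_cursor)
                lens.append(mlen)
            hap_cursor += mlen
            ref_cursor += mlen
            if kind == "ins":
                hap_cursor += length
            else:
                ref_cursor += length
        if ref_cursor < ref_len:
            hap_starts.append(hap_cursor)
            ref_starts.append(ref_cursor)
            lens.append(ref_len - ref_cursor)
            hap_cursor += ref_len - ref_cursor
        self.hap_starts = np.asarray(hap_starts, dtype=np.int64)
        self.ref_starts = np.asarray(ref_starts, dtype=np.int64)
        self.lens = np.asarray(lens, dtype=np.int64)
        self.hap_len = hap_cursor
        self.hap_ends = self.hap_starts + self.lens

    def simple_block(self, starts: np.ndarray, read_len: int):
        """Vectorized fast path: for reads fully inside one match block return
        (is_simple mask, ref positions)."""
        idx = np.searchsorted(self.hap_starts, starts, side="right") - 1
        idx_c = np.clip(idx, 0, len(self.hap_starts) - 1)
        ok = (idx >= 0) & (starts + read_len <= self.hap_ends[idx_c])
        pos = self.ref_starts[idx_c] + (starts - self.hap_starts[idx_c])
        return ok, np.where(ok, pos, -1)

    def project(self, s: int, e: int):
        """Project haplotype interval [s, e) onto the reference.

        Returns None if no base maps (read entirely within hap-only sequence),
        else (pos, cigar, segments, n_indel_bases) with segments =
        [(read_offset, ref_pos, length)] for each M run; soft clips cover
        read bases falling in hap-only gaps at either end.
        """
        k = int(np.searchsorted(self.hap_ends, s, side="right"))
        if k >= len(self.hap_starts) or self.hap_starts[k] >= e:
            return None
        lead = int(max(0, self.hap_starts[k] - s))
        cig: list[tuple[int, str]] = []
        if lead:
            cig.append((lead, "S"))
        segments = []
        n_indel = 0
        pos = int(self.ref_starts[k] + max(s, self.hap_starts[k]) - self.hap_starts[k])
        prev_hap_end = prev_ref_end = None
        first = k
        while k < len(self.hap_starts) and self.hap_starts[k] < e:
            hs, rs, ln = int(self.hap_starts[k]), int(self.ref_starts[k]), int(self.lens[k])
            if k > first:
                hap_gap = hs - prev_hap_end
                ref_gap = rs - prev_ref_end
                if hap_gap:
                    cig.append((hap_gap, "I"))
                    n_indel += hap_gap
                if ref_gap:
                    cig.append((ref_gap, "D"))
                    n_indel += ref_gap
            m_s, m_e = max(s, hs), min(e, hs + ln)
            segments.append((m_s - s, rs + (m_s - hs), m_e - m_s))
            cig.append((m_e - m_s, "M"))
            prev_hap_end, prev_ref_end = hs + ln, rs + ln
            k += 1
        trail = int(e - min(e, prev_hap_end))
        if trail:
            cig.append((trail, "S"))
        cigar = "".join(f"{n}{op}" for n, op in cig if n > 0)
        return pos, cigar, segments, n_indel


def _hap_indels_vs_a(svs_b_allele: list[StructuralVariant]) -> list[tuple[int, str, int]]:
    out = []
    for sv in svs_b_allele:
        if sv.type == SvType.INSERTION:
            out.append((sv.ref_start, "ins", sv.size))
        else:
            out.append((sv.ref_start, "del", sv.size))
    return sorted(out)


def _hap_indels_vs_b(svs_a_allele: list[StructuralVariant]) -> list[tuple[int, str, int]]:
    out = []
    for sv in svs_a_allele:
        if sv.type == SvType.INSERTION:   # B carries extra seq; this hap lacks it
            out.append((sv.query_start, "del", sv.size))
        else:                              # B lacks the segment; this hap carries it
            out.append((sv.query_start, "ins", sv.size))
    return sorted(out)


# ------------------------------------------------------------------ reads

def _sam_header(lens: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, ln in lens.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{ln}")
    return "\n".join(lines) + "\n"


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def simulate_reads(truth: TruthSet, genome_a: dict, genome_b: dict,
                   cfg: SimConfig, out_dir: str | Path,
                   depth_per_accession: Optional[dict[str, float]] = None) -> dict:
    """Write paired FASTQ plus exact truth SAMs against both assemblies.

    Per accession: two haplotypes are assembled from the truth genotypes,
    fragments of ``insert_size`` are drawn uniformly, per-base substitution
    errors injected at ``error_rate``, and each mate is emitted with its exact
    placement (POS/CIGAR/NM) against genome A and genome B; reads entirely
    within haplotype-only sequence relative to a given reference are flagged
    unmapped there.
    """
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    (out / "sam_A").mkdir(exist_ok=True)
    (out / "sam_B").mkdir(exist_ok=True)

    rl, ins = cfg.read_len, cfg.insert_size
    qual = "I" * rl
    a_codes = {c: _ASCII2CODE[arr] for c, arr in genome_a.items()}
    b_codes = {c: _ASCII2CODE[arr] for c, arr in genome_b.items()}
    lens_a = {c: len(v) for c, v in genome_a.items()}
    lens_b = {c: len(v) for c, v in genome_b.items()}
    chroms = list(genome_a)
    svs_by_chrom: dict[str, list[StructuralVariant]] = {c: [] for c in chroms}
    for sv in truth.svs:
        svs_by_chrom[sv.ref_name].append(sv)
    snp_by_chrom = {c: truth.snp_sites[truth.snp_sites["chrom"] == c] for c in chroms}

    ss = np.random.SeedSequence(cfg.seed + 7_777_777)
    acc_seeds = ss.spawn(len(truth.groups.index))
    manifest = {"fastq": {}, "sam_a": {}, "sam_b": {}, "n_pairs": {}}
    genome_len = sum(lens_a.values())

    sv_ids = list(truth.sv_genotypes.index)
    snp_ids = list(truth.snp_genotypes.index) if len(truth.snp_genotypes) else []

    for acc, acc_ss in zip(truth.groups.index, acc_seeds):
        rng = np.random.default_rng(acc_ss)
        depth = (depth_per_accession or {}).get(acc, cfg.depth)
        n_pairs = int(round(depth * genome_len / (2 * rl)))

        sv_dos = truth.sv_genotypes.loc[sv_ids, acc].to_numpy() if sv_ids else np.empty(0)
        coin = rng.integers(0, 2, len(sv_ids))
        hap_sv = [(sv_dos == 2) | ((sv_dos == 1) & (coin == h)) for h in (0, 1)]
        if snp_ids:
            snp_dos = truth.snp_genotypes.loc[snp_ids, acc].to_numpy()
            coin_s = rng.integers(0, 2, len(snp_ids))
            hap_snp = [(snp_dos == 2) | ((snp_dos == 1) & (coin_s == h)) for h in (0, 1)]
        else:
            hap_snp = [np.empty(0, dtype=bool)] * 2

        # build each haplotype chromosome + its maps to A and B
        haps: list[dict[str, np.ndarray]] = [{}, {}]
        maps_a: list[dict[str, HapRefMap]] = [{}, {}]
        maps_b: list[dict[str, HapRefMap]] = [{}, {}]
        sv_index = {sid: i for i, sid in enumerate(sv_ids)}
        snp_index = {sid: i for i, sid in enumerate(snp_ids)}
        for h in (0, 1):
            for chrom in chroms:
                chrom_svs = svs_by_chrom[chrom]
                with_b = [sv for sv in chrom_svs if hap_sv[h][sv_index[sv.id]]]
                with_a = [sv for sv in chrom_svs if not hap_sv[h][sv_index[sv.id]]]
                seq = a_codes[chrom].copy()
                sdf = snp_by_chrom[chrom]
                if len(sdf):
                    which = np.array([snp_index[i] for i in sdf["id"]])
                    alt_on = hap_snp[h][which]
                    pos_alt = sdf["pos"].to_numpy()[alt_on]
                    alt_codes = np.array([_ASCII2CODE[ord(x)] for x in sdf["alt"]])[alt_on]
                    seq[pos_alt] = alt_codes
                indels_a = _hap_indels_vs_a(with_b)
                # apply indels to build hap sequence
                segs = []
                cursor = 0
                for pos, kind, length in indels_a:
                    segs.append(seq[cursor:pos])
                    if kind == "ins":
                        sv = next(s for s in with_b if s.ref_start == pos
                                  and s.type == SvType.INSERTION)
                        segs.append(_ASCII2CODE[svio.str_to_seq(sv.alt_seq)])
                        cursor = pos
                    else:
                        cursor = pos + length
                segs.append(seq[cursor:])
                haps[h][chrom] = np.concatenate(segs) if segs else seq
                maps_a[h][chrom] = HapRefMap(lens_a[chrom], indels_a)
                maps_b[h][chrom] = HapRefMap(lens_b[chrom], _hap_indels_vs_b(with_a))

        # allocate pairs over (hap, chrom) cells by haplotype length
        cells = [(h, c) for h in (0, 1) for c in chroms]
        weights = np.array([len(haps[h][c]) for h, c in cells], dtype=float)
        counts = rng.multinomial(n_pairs, weights / weights.sum())

        fq1 = open(out / "reads" / f"{acc}_R1.fastq", "w")
        fq2 = open(out / "reads" / f"{acc}_R2.fastq", "w")
        sam_a = open(out / "sam_A" / f"{acc}.sam", "w")
        sam_b = open(out / "sam_B" / f"{acc}.sam", "w")
        sam_a.write(_sam_header(lens_a))
        sam_b.write(_sam_header(lens_b))
        pair_no = 0
        ar = np.arange(rl)
        for (h, chrom), n in zip(cells, counts):
            if n == 0:
                continue
            hap = haps[h][chrom]
            if len(hap) < ins:
                continue
            starts = rng.integers(0, len(hap) - ins + 1, n)
            starts.sort()
            m1 = hap[starts[:, None] + ar].copy()
            m2 = hap[(starts + ins - rl)[:, None] + ar].copy()
            for m in (m1, m2):
                err = rng.random(m.shape) < cfg.error_rate
                m[err] = (m[err] + rng.integers(1, 4, int(err.sum()))) % 4
            for ref_tag, refmap, ref_seq, fh in (
                    ("A", maps_a[h][chrom], a_codes[chrom], sam_a),
                    ("B", maps_b[h][chrom], b_codes[chrom], sam_b)):
                _write_sam_cell(fh, acc, chrom, pair_no, starts, m1, m2, refmap,
                                ref_seq, rl, ins, qual, ar)
            for i in range(n):
                name = f"{acc}:p{pair_no + i}"
                s1 = _CODE2ASCII[m1[i]].tobytes().decode()
                s2 = _CODE2ASCII[_revcomp_codes(m2[i])].tobytes().decode()
                fq1.write(f"@{name}/1\n{s1}\n+\n{qual}\n")
                fq2.write(f"@{name}/2\n{s2}\n+\n{qual}\n")
            pair_no += int(n)
        for fh in (fq1, fq2, sam_a, sam_b):
            fh.close()
        manifest["fastq"][acc] = [str(out / "reads" / f"{acc}_R1.fastq"),
                                  str(out / "reads" / f"{acc}_R2.fastq")]
        manifest["sam_a"][acc] = str(out / "sam_A" / f"{acc}.sam")
        manifest["sam_b"][acc] = str(out / "sam_B" / f"{acc}.sam")
        manifest["n_pairs"][acc] = pair_no
    return manifest


def _write_sam_cell(fh, acc, chrom, pair_no, starts, m1, m2, refmap, ref_seq,
                    rl, ins, qual, ar):
    """Emit one (haplotype, chromosome) batch of read pairs against one reference."""
    n = len(starts)
    s2_starts = starts + ins - rl
    ok1, pos1 = refmap.simple_block(starts, rl)
    ok2, pos2 = refmap.simple_block(s2_starts, rl)
    # batched NM for simple (single match block) reads
    nm1 = np.zeros(n, dtype=np.int64)
    nm2 = np.zeros(n, dtype=np.int64)
    for ok, pos, m, nm in ((ok1, pos1, m1, nm1), (ok2, pos2, m2, nm2)):
        if ok.any():
            p = pos[ok]
            nm[ok] = (m[ok] != ref_seq[p[:, None] + ar]).sum(axis=1)
    full_m = f"{rl}M"
    lines = []
    for i in range(n):
        name = f"{acc}:p{pair_no + i}"
        recs = []
        for mate, (okk, poss, nms, m, s_hap) in enumerate((
                (ok1[i], pos1[i], nm1[i], m1[i], int(starts[i])),
                (ok2[i], pos2[i], nm2[i], m2[i], int(s2_starts[i])))):
            if okk:
                recs.append((int(poss), full_m, int(nms)))
            else:
                proj = refmap.project(s_hap, s_hap + rl)
                if proj is None:
                    recs.append(None)
                    continue
                pos, cigar, segments, n_indel = proj
                nm = n_indel
                for roff, rpos, ln in segments:
                    if ln:
                        nm += int((m[roff:roff + ln] != ref_seq[rpos:rpos + ln]).sum())
                recs.append((pos, cigar, nm))
        seqs = (_CODE2ASCII[m1[i]].tobytes().decode(), _CODE2ASCII[m2[i]].tobytes().decode())
        for mate in (0, 1):
            rec = recs[mate]
            other = recs[1 - mate]
            first_bit = 0x40 if mate == 0 else 0x80
            if rec is None:
                flag = 0x1 | 0x4 | first_bit
                lines.append(f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seqs[mate]}\t{qual}")
                continue
            pos, cigar, nm = rec
            flag = 0x1 | first_bit | (0x10 if mate == 1 else 0x20)
            if other is None:
                flag |= 0x8
                rnext, pnext = "*", 0
            else:
                flag |= 0x2
                rnext, pnext = "=", other[0] + 1
            lines.append(
                f"{name}\t{flag}\t{chrom}\t{pos + 1}\t60\t{cigar}\t{rnext}\t{pnext}\t0\t"
                f"{seqs[mate]}\t{qual}\tNM:i:{nm}")
    fh.write("\n".join(lines) + "\n")


# ------------------------------------------------------------------ gene models

def generate_gene_models(chrom_lens: dict[str, int], n_genes: int,
                         seed: int = 0, mean_gene_len: int = 3000) -> list[GeneModel]:
    """Random non-overlapping gene models with 1-5 exons, for annotation tests."""
    rng = np.random.default_rng(np.random.SeedSequence(seed + 424_243))
    genes: list[GeneModel] = []
    gid = 0
    for chrom, length in chrom_lens.items():
        n_c = max(1, int(round(n_genes * length / sum(chrom_lens.values()))))
        slot = length // n_c
        for k in range(n_c):
            glen = int(np.clip(rng.normal(mean_gene_len, mean_gene_len / 3),
                               300, max(400, slot - 200)))
            lo = k * slot
            hi = min((k + 1) * slot, length) - glen
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 6))
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2,
                                      replace=False)) if n_exons > 1 else np.empty(0, int)
            bounds = np.concatenate([[0], cuts, [glen]])
            exons = [(start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
                     for i in range(n_exons)]
            exons = [(a, b) for a, b in exons if b > a]
            genes.append(GeneModel(gene_id=f"gene{gid:04d}", chrom=chrom,
                                   start=start, end=end, strand=strand, exons=exons))
            gid += 1
    return genes


# ------------------------------------------------------------------ one-call dataset

def simulate_dataset(cfg: SimConfig, out_dir: str | Path,
                     with_reads: bool = True, n_genes: int = 40) -> dict:
    """Generate and write the full synthetic dataset; returns a path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome_a, genome_b, truth, blocks = generate_genome_pair(cfg)
    truth = simulate_population(truth, cfg)

    lens_a = {c: len(v) for c, v in genome_a.items()}
    lens_b = {c: len(v) for c, v in genome_b.items()}
    svio.write_fasta(genome_a, out / "genomeA.fa")
    svio.write_fasta(genome_b, out / "genomeB.fa")
    svio.write_paf(blocks, out / "truth.paf", query_lens=lens_b, ref_lens=lens_a)
    svio.write_sv_truth_tsv(truth.svs, out / "truth_svs.tsv")
    svio.write_groups_tsv(truth.groups, out / "groups.tsv")
    truth.sv_genotypes.rename_axis("sv_id").to_csv(out / "truth_sv_genotypes.tsv", sep="\t")
    truth.sv_freqs.to_csv(out / "truth_sv_freqs.tsv", sep="\t")
    if len(truth.snp_sites):
        svio.write_snp_vcf(truth.snp_sites, truth.snp_genotypes, lens_a,
                           out / "truth_snps.vcf")
    genes = generate_gene_models(lens_a, n_genes, seed=cfg.seed)
    svio.write_gff3(genes, out / "genes.gff3")
    manifest = {
        "genome_a": str(out / "genomeA.fa"), "genome_b": str(out / "genomeB.fa"),
        "paf": str(out / "truth.paf"), "sv_truth": str(out / "truth_svs.tsv"),
        "groups": str(out / "groups.tsv"), "gff3": str(out / "genes.gff3"),
        "snp_vcf": str(out / "truth_snps.vcf") if len(truth.snp_sites) else None,
    }
    if with_reads:
        manifest.update(simulate_reads(truth, genome_a, genome_b, cfg, out))
    return manifest
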