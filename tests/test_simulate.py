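"""Simulator contracts: determinism, edit conservation, size mixture, read truth."""

import numpy as np
import pysam
import pytest

from svscan import io as svio
from svscan.models import SvType
from svscan.simulate import (
    CapacityError,
    HapRefMap,
    SimConfig,
    generate_genome_pair,
    simulate_population,
    simulate_reads,
)


def _apply_edits_oracle(genome_a, truth):
    """Independent splice: apply planted SNPs then indels to rebuild genome B."""
    out = {}
    for chrom, arr in genome_a.items():
        seq = arr.copy()
        snps = truth.snp_sites[truth.snp_sites["chrom"] == chrom]
        for _, s in snps.iterrows():
            assert chr(seq[s["pos"]]) == s["ref"]
            seq[s["pos"]] = ord(s["alt"])
        parts, cursor = [], 0
        for sv in sorted((s for s in truth.svs if s.ref_name == chrom),
                         key=lambda s: s.ref_start):
            parts.append(seq[cursor:sv.ref_start])
            if sv.type == SvType.INSERTION:
                parts.append(svio.str_to_seq(sv.alt_seq))
                cursor = sv.ref_start
            else:
                cursor = sv.ref_end
        parts.append(seq[cursor:])
        out[chrom] = np.concatenate(parts)
    return out


class TestGenomePair:
    def test_same_seed_identical_bytes(self, tmp_path):
        paths = []
        for rep in range(2):
            cfg = SimConfig(seed=42, n_chrom=2, chrom_len=60_000, n_sv=20)
            ga, gb, truth, blocks = generate_genome_pair(cfg)
            pa, pb, pp = (tmp_path / f"a{rep}.fa", tmp_path / f"b{rep}.fa",
                          tmp_path / f"t{rep}.paf")
            svio.write_fasta(ga, pa)
            svio.write_fasta(gb, pb)
            svio.write_paf(blocks, pp, {c: len(v) for c, v in gb.items()},
                           {c: len(v) for c, v in ga.items()})
            paths.append((pa.read_bytes(), pb.read_bytes(), pp.read_bytes()))
        assert paths[0] == paths[1]

    def test_identity_case_no_edits(self):
        cfg = SimConfig(seed=1, n_chrom=2, chrom_len=20_000, n_sv=0, snp_rate=0.0,
                        n_selected_sv=0)
        ga, gb, truth, blocks = generate_genome_pair(cfg)
        for chrom in ga:
            assert np.array_equal(ga[chrom], gb[chrom])
        assert len(blocks) == 2
        for b in blocks:
            assert b.cigar == "20000M"

    def test_edit_conservation_roundtrip(self, small_dataset):
        cfg, ga, gb, truth, _ = small_dataset
        rebuilt = _apply_edits_oracle(ga, truth)
        for chrom in ga:
            assert np.array_equal(rebuilt[chrom], gb[chrom])

    def test_both_coordinate_breakpoints(self, small_dataset):
        _, ga, gb, truth, _ = small_dataset
        for sv in truth.svs:
            if sv.type == SvType.INSERTION:
                planted = gb[sv.query_name][sv.query_start:sv.query_end]
                assert planted.tobytes().decode() == sv.alt_seq
            else:
                # flanks around the fused junction in B match the A flanks
                left = gb[sv.query_name][sv.query_start - 20:sv.query_start]
                assert np.array_equal(left, ga[sv.ref_name][sv.ref_start - 20:sv.ref_start])

    def test_size_mixture_binomial(self):
        cfg = SimConfig(seed=9, n_chrom=5, chrom_len=500_000, n_sv=500)
        _, _, truth, _ = generate_genome_pair(cfg)
        sizes = np.array([sv.size for sv in truth.svs])
        assert sizes.min() >= 10 and sizes.max() <= 20_000
        frac = (sizes < 100).mean()
        # 3-sigma binomial band around 0.877 at n=500
        se = np.sqrt(0.877 * 0.123 / 500)
        assert abs(frac - 0.877) < 3 * se

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_genome_pair(SimConfig(seed=0, n_chrom=1, chrom_len=20_000, n_sv=50))

    @pytest.mark.parametrize("field,value", [
        ("fst_background", 0.0), ("fst_background", 1.0), ("sv_size_min", 0),
        ("frac_small", 1.5), ("insert_size", 100),
    ])
    def test_config_validation(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})


class TestPopulation:
    def test_group_sizes_default_60(self, small_dataset):
        _, _, _, truth, _ = small_dataset
        cfg2 = SimConfig(seed=2, n_chrom=1, chrom_len=60_000, n_sv=10, n_selected_sv=2)
        _, _, t2, _ = generate_genome_pair(cfg2)
        t2 = simulate_population(t2, cfg2)
        assert t2.sv_genotypes.shape[1] == 60
        assert (t2.groups == "wild").sum() == 28
        assert (t2.groups == "cultivated").sum() == 32

    def test_selected_svs_have_configured_shift(self, small_dataset):
        cfg, _, _, truth, _ = small_dataset
        f = truth.sv_freqs
        for sid in truth.selected_ids:
            assert abs(f.loc[sid, "freq_wild"] - f.loc[sid, "freq_cult"]) \
                >= cfg.min_freq_shift - 1e-9

    def test_genotypes_consistent_with_group_freqs(self, small_dataset):
        _, _, _, truth, _ = small_dataset
        wild = truth.groups.index[truth.groups == "wild"]
        n_alleles = 2 * len(wild)
        for sid in truth.sv_freqs.index[:30]:
            p = truth.sv_freqs.loc[sid, "freq_wild"]
            k = truth.sv_genotypes.loc[sid, wild].sum()
            se = np.sqrt(max(p * (1 - p) * n_alleles, 1e-9))
            assert abs(k - p * n_alleles) < 5 * se + 1  # binomial 5-sigma band

    def test_empty_group_rejected(self):
        cfg = SimConfig(seed=0, n_chrom=1, chrom_len=30_000, n_sv=5, n_wild=0,
                        n_selected_sv=0)
        _, _, truth, _ = generate_genome_pair(cfg)
        with pytest.raises(ValueError):
            simulate_population(truth, cfg)


class TestHapRefMap:
    def test_projection_over_insertion_and_deletion(self):
        # hap = ref[0:100] + 10 inserted + ref[100:150] ; ref[150:170) deleted
        hmap = HapRefMap(200, [(100, "ins", 10), (150, "del", 20)])
        assert hmap.hap_len == 200 - 20 + 10
        pos, cigar, segs, n_indel = hmap.project(90, 140)
        assert pos == 90 and cigar == "10M10I30M" and n_indel == 10
        pos, cigar, segs, n_indel = hmap.project(150, 170)
        # hap 150..170 = ref 140..160 with the 20 bp deletion at ref 150
        assert pos == 140 and cigar == "10M20D10M" and n_indel == 20

    def test_read_inside_insertion_is_unmapped_or_clipped(self):
        hmap = HapRefMap(1000, [(500, "ins", 300)])
        assert hmap.project(550, 700) is None          # wholly inside the insertion
        pos, cigar, _, _ = hmap.project(480, 560)
        assert pos == 480 and cigar == "20M60S"        # runs into the insertion


class TestReads:
    def test_pair_count_matches_coverage(self, read_dataset):
        cfg, _, _, truth, manifest = read_dataset
        expected = cfg.depth * cfg.chrom_len / (2 * cfg.read_len)
        for acc, n in manifest["n_pairs"].items():
            assert abs(n - expected) / expected < 0.01

    def test_error_free_reads_have_nm_zero(self, tmp_path):
        cfg = SimConfig(seed=8, n_chrom=1, chrom_len=30_000, n_sv=8, snp_rate=0.0,
                        error_rate=0.0, depth=8, n_wild=2, n_cult=2, n_selected_sv=1)
        ga, gb, truth, _ = generate_genome_pair(cfg)
        truth = simulate_population(truth, cfg)
        manifest = simulate_reads(truth, ga, gb, cfg, tmp_path)
        acc = truth.groups.index[0]
        nms = []
        for path in (manifest["sam_a"][acc], manifest["sam_b"][acc]):
            with pysam.AlignmentFile(path, check_sq=False) as sam:
                for rec in sam:
                    if rec.is_unmapped:
                        continue
                    # NM counts substitutions plus indel bases the read spans
                    indel = sum(l for op, l in rec.cigartuples if op in (1, 2))
                    nms.append(rec.get_tag("NM") - indel)
        assert nms and max(nms) == 0

    def test_mean_mismatches_match_error_rate(self, tmp_path):
        cfg = SimConfig(seed=8, n_chrom=1, chrom_len=100_000, n_sv=0, snp_rate=0.0,
                        error_rate=0.01, depth=30, n_wild=1, n_cult=1, n_selected_sv=0)
        ga, gb, truth, _ = generate_genome_pair(cfg)
        truth = simulate_population(truth, cfg)
        manifest = simulate_reads(truth, ga, gb, cfg, tmp_path)
        acc = truth.groups.index[0]
        nms = []
        with pysam.AlignmentFile(manifest["sam_a"][acc], check_sq=False) as sam:
            nms = [rec.get_tag("NM") for rec in sam if not rec.is_unmapped]
        assert len(nms) >= 10_000
        mean = np.mean(nms)
        # binomial(150, 0.01) mean 1.5; 3/4 of errors change the base vs ref always
        assert abs(mean - 1.5) < 0.1

    def test_truth_sam_placement_exact(self, read_dataset):
        """Read sequence with zero NM equals the reference slice it claims."""
        cfg, ga, gb, truth, manifest = read_dataset
        acc = truth.groups.index[0]
        checked = 0
        with pysam.AlignmentFile(manifest["sam_a"][acc], check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.get_tag("NM") != 0 or "S" in rec.cigarstring:
                    continue
                if any(op in (1, 2) for op, _ in rec.cigartuples):
                    continue
                ref = ga[rec.reference_name][rec.reference_start:rec.reference_end]
                assert ref.tobytes().decode() == rec.query_sequence
                checked += 1
                if checked > 200:
                    break
        assert checked > 50

    def test_reads_deterministic(self, tmp_path):
        cfg = SimConfig(seed=4, n_chrom=1, chrom_len=30_000, n_sv=5, depth=5,
                        n_wild=2, n_cult=2, n_selected_sv=1)
        ga, gb, truth, _ = generate_genome_pair(cfg)
        truth = simulate_population(truth, cfg)
        outs = []
        for rep in range(2):
            d = tmp_path / f"r{rep}"
            man = simulate_reads(truth, ga, gb, cfg, d)
            acc = truth.groups.index[0]
            outs.append((open(man["fastq"][acc][0], "rb").read(),
                         open(man["sam_a"][acc], "rb").read()))
        assert outs[0] == outs[1]
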