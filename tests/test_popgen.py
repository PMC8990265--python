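"""Window pi vs exhaustive pairwise enumeration, Weir-Cockerham F_ST vs an
independent formula oracle and parameter recovery, LD null level, outlier
quantile logic, and PCA group separation."""

import numpy as np
import pandas as pd
import pytest

from svscan.popgen import (
    SnpPanel,
    genome_fst,
    genotype_pca,
    ld_decay,
    top_fraction_outliers,
    window_fst,
    window_pi,
    window_stats,
    weir_cockerham_components,
)


def _panel(dosages, positions, groups, chrom="chr1"):
    sites = pd.DataFrame({"id": [f"s{i}" for i in range(len(positions))],
                          "chrom": chrom, "pos": positions})
    dos = pd.DataFrame(np.asarray(dosages, float).T, index=groups.index,
                       columns=sites["id"])
    return SnpPanel(sites=sites, dosages=dos, groups=groups)


def _groups(n1, n2):
    accs = [f"w{i}" for i in range(n1)] + [f"c{i}" for i in range(n2)]
    return pd.Series(["wild"] * n1 + ["cultivated"] * n2, index=accs)


def pi_pairwise_oracle(dosage_col):
    """Mean pairwise allele difference: k(n-k)/C(n,2) per site (exhaustive)."""
    d = np.asarray(dosage_col, float)
    d = d[~np.isnan(d)]
    n = 2 * len(d)
    k = int(d.sum())
    if n < 2:
        return np.nan
    return k * (n - k) / (n * (n - 1) / 2)


class TestWindowPi:
    def test_two_two_split_in_100bp_window(self):
        groups = _groups(2, 0)
        panel = _panel([[2.0, 0.0]], [50], groups)
        pi = window_pi(panel, "wild", 100)["pi"].iloc[0]
        assert pi == pytest.approx((4 / 3 * 0.5) / 100)   # 0.006667

    def test_three_het_sites_give_003(self):
        # single diploid: 3 heterozygous sites in 100 bp -> mean pairwise
        # difference 3 between its two haplotypes -> pi = 0.03
        groups = pd.Series({"a": "wild"})
        panel = _panel([[1.0], [1.0], [1.0]], [10, 40, 70], groups)
        assert window_pi(panel, "wild", 100)["pi"].iloc[0] == pytest.approx(0.03)

    def test_monomorphic_window_zero(self):
        panel = _panel([[2.0, 2.0, 2.0]], [50], _groups(3, 0))
        assert window_pi(panel, "wild", 100)["pi"].iloc[0] == 0.0

    def test_all_missing_window_is_nan_not_zero(self):
        panel = _panel([[np.nan, np.nan]], [50], _groups(2, 0))
        assert np.isnan(window_pi(panel, "wild", 100)["pi"].iloc[0])

    def test_exhaustive_pairwise_oracle_8_haplotypes(self):
        rng = np.random.default_rng(4)
        dosages = rng.integers(0, 3, (12, 4)).astype(float)
        dosages[rng.random(dosages.shape) < 0.1] = np.nan
        panel = _panel(dosages, (np.arange(12) * 7 + 3).tolist(), _groups(4, 0))
        got = window_pi(panel, "wild", 100)["pi"].iloc[0]
        expected = np.nansum([pi_pairwise_oracle(dosages[i]) for i in range(12)]) / 100
        assert got == pytest.approx(expected)


def wc_fst_oracle(genos1, genos2):
    """Independent scalar Weir-Cockerham (1984) theta for one site, two pops."""
    g1, g2 = np.asarray(genos1, float), np.asarray(genos2, float)
    n1, n2 = len(g1), len(g2)
    p1, p2 = g1.sum() / (2 * n1), g2.sum() / (2 * n2)
    h1, h2 = (g1 == 1).mean(), (g2 == 1).mean()
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


class TestFst:
    def test_fixed_difference_is_one(self):
        panel = _panel([[2.0] * 10 + [0.0] * 10], [50], _groups(10, 10))
        assert window_fst(panel, 100)["fst"].iloc[0] == pytest.approx(1.0)

    def test_pooled_panel_near_zero(self):
        rng = np.random.default_rng(8)
        dosages = rng.binomial(2, 0.4, (200, 60)).astype(float)
        panel = _panel(dosages, (np.arange(200) * 10).tolist(), _groups(28, 32))
        assert abs(genome_fst(panel)) < 0.02

    def test_against_independent_formula_oracle(self):
        g1 = [0] * 8 + [1] * 2          # pop1: 8 AA, 2 Aa (dosage of alt a)
        g2 = [2] * 8 + [1] * 2          # pop2: 8 aa, 2 Aa
        panel = _panel([g1 + g2], [50], _groups(10, 10))
        got = window_fst(panel, 100)["fst"].iloc[0]
        assert got == pytest.approx(wc_fst_oracle(g1, g2), rel=1e-12)
        # vectorized components equal the scalar oracle on random sites
        rng = np.random.default_rng(5)
        for _ in range(25):
            x1 = rng.integers(0, 3, 15)
            x2 = rng.integers(0, 3, 20)
            if len(set(x1)) + len(set(x2)) == 2 and x1[0] == x2[0]:
                continue
            a, b, c = weir_cockerham_components(
                15, x1.sum() / 30, (x1 == 1).mean(), 20, x2.sum() / 40, (x2 == 1).mean())
            denom = a + b + c
            if denom == 0:
                continue
            assert a / denom == pytest.approx(wc_fst_oracle(x1, x2), rel=1e-9)

    @pytest.mark.parametrize("F", [0.05, 0.15, 0.3])
    def test_balding_nichols_parameter_recovery(self, F):
        rng = np.random.default_rng(int(F * 1000))
        n_snp = 5000
        p = rng.uniform(0.1, 0.9, n_snp)
        fw = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        fc = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        g = np.empty((n_snp, 60))
        g[:, :28] = rng.binomial(2, fw[:, None], (n_snp, 28))
        g[:, 28:] = rng.binomial(2, fc[:, None], (n_snp, 32))
        panel = _panel(g, (np.arange(n_snp) * 5).tolist(), _groups(28, 32))
        assert genome_fst(panel) == pytest.approx(F, abs=0.02)

    def test_monotone_in_frequency_difference(self):
        ests = []
        for p2 in (0.5, 0.3, 0.1):
            g1 = np.repeat([0, 1, 2], [5, 10, 5])      # p1 = 0.5, HWE-ish
            n_bb = int(round(p2 * p2 * 20))
            n_ab = int(round(2 * p2 * (1 - p2) * 20))
            g2 = np.repeat([2, 1, 0], [n_bb, n_ab, 20 - n_bb - n_ab])
            ests.append(wc_fst_oracle(g1, g2))
        assert ests[0] < ests[1] < ests[2]


class TestOutliers:
    def test_exactly_five_of_hundred(self):
        stats = pd.DataFrame({"chrom": "chr1", "start": np.arange(100) * 15_000,
                              "end": (np.arange(100) + 1) * 15_000,
                              "fst": np.linspace(0, 0.9, 100),
                              "pi_ratio": np.linspace(1, 2, 100)})
        out = top_fraction_outliers(stats, 0.05)
        assert out["outlier_fst"].sum() == 5
        assert set(out.loc[out["outlier_fst"], "start"]) == set(np.arange(95, 100) * 15_000)

    def test_all_equal_metric_tie_rule(self):
        stats = pd.DataFrame({"fst": [0.2] * 40, "pi_ratio": [1.0] * 40})
        out = top_fraction_outliers(stats, 0.05)
        assert out["outlier_fst"].all()          # documented: ties at threshold all flag

    def test_few_windows_flags_only_maximum(self):
        stats = pd.DataFrame({"fst": [0.1, 0.5, 0.3], "pi_ratio": [1.0, 1.2, 3.0]})
        out = top_fraction_outliers(stats, 0.05)
        assert out["outlier_fst"].tolist() == [False, True, False]
        assert out["outlier_pi_ratio"].tolist() == [False, False, True]

    def test_planted_sweep_window_flagged(self, two_group_labels):
        rng = np.random.default_rng(21)
        n_snp, per_win = 600, 10
        p = rng.uniform(0.2, 0.8, n_snp)
        g = rng.binomial(2, p, (60, n_snp)).astype(float)
        sweep = slice(300, 310)                   # one 15 kb window span
        g[:28, sweep] = rng.binomial(2, 0.95, (28, 10))
        g[28:, sweep] = rng.binomial(2, 0.05, (32, 10))
        pos = (np.arange(n_snp) * (15_000 // per_win) + 100).tolist()
        panel = _panel(g.T.tolist(), pos, two_group_labels)
        stats = top_fraction_outliers(window_stats(panel, 15_000), 0.05)
        sweep_win = stats[(stats["start"] <= pos[300]) & (stats["end"] > pos[300])]
        assert bool(sweep_win["outlier_fst"].iloc[0])


class TestLd:
    def test_duplicated_column_r2_one(self):
        g = np.random.default_rng(0).binomial(2, 0.5, 30).astype(float)
        panel = _panel([g, g.copy()], [100, 200], _groups(30, 0))
        ld = ld_decay(panel, "wild", max_dist=1000, bin_bp=1000)
        assert ld["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_complement_invariance(self):
        g = np.random.default_rng(1).binomial(2, 0.5, 30).astype(float)
        panel = _panel([g, 2.0 - g], [100, 200], _groups(30, 0))
        assert ld_decay(panel, "wild", 1000, 1000)["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_sites_null_level(self):
        rng = np.random.default_rng(2)
        n = 60
        g = rng.binomial(2, 0.5, (n, 150)).astype(float)
        panel = _panel(g.T.tolist(), (np.arange(150) * 10).tolist(), _groups(28, 32))
        panel.groups[:] = "wild"
        ld = ld_decay(panel, "wild", max_dist=2000, bin_bp=2000)
        assert ld["mean_r2"].iloc[0] == pytest.approx(1 / (n - 1), rel=0.25)

    def test_zero_variance_pair_skipped(self):
        panel = _panel([[1.0] * 10, [0.0, 2.0] * 5], [100, 200], _groups(10, 0))
        ld = ld_decay(panel, "wild", 1000, 1000)
        assert ld["n_pairs"].iloc[0] == 0 and np.isnan(ld["mean_r2"].iloc[0])


class TestPca:
    def test_duplicated_accessions_identical_coordinates(self):
        rng = np.random.default_rng(6)
        d = pd.DataFrame(rng.binomial(2, 0.5, (5, 40)).astype(float),
                         index=list("abcde"))
        d.loc["e"] = d.loc["a"]
        coords, _ = genotype_pca(d, k=3)
        assert np.allclose(coords.loc["a"], coords.loc["e"])

    def test_two_groups_separate_on_pc1(self, two_group_labels):
        rng = np.random.default_rng(9)
        F = 0.2
        p = rng.uniform(0.2, 0.8, 400)
        fw = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        fc = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        g = np.empty((60, 400))
        g[:28] = rng.binomial(2, fw, (28, 400))
        g[28:] = rng.binomial(2, fc, (32, 400))
        coords, evr = genotype_pca(pd.DataFrame(g, index=two_group_labels.index), k=4)
        pc1 = coords["PC1"]
        between = abs(pc1[:28].mean() - pc1[28:].mean())
        within = pc1[:28].std() + pc1[28:].std()
        assert between > within
        assert evr[0] > evr[1] > 0

    def test_constant_matrix_zero_variance(self):
        d = pd.DataFrame(np.ones((6, 10)))
        coords, evr = genotype_pca(d, k=3)
        assert np.allclose(evr, 0) and np.allclose(coords.to_numpy(), 0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(10)
        d = pd.DataFrame(rng.binomial(2, 0.4, (8, 30)).astype(float))
        c1, _ = genotype_pca(d, k=2)
        c2, _ = genotype_pca(d.copy(), k=2)
        assert np.allclose(c1, c2)
        arr = c1.to_numpy()
        assert arr[np.argmax(np.abs(arr[:, 0])), 0] >= 0
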