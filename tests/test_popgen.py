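"""Diversity/differentiation estimators against brute-force oracles,
outlier calling, LD decay, distances, NJ and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cropgs as cg
from cropgs.popgen import hudson_fst_components


class TestSiteDiversity:
    def test_two_alleles_differing(self):
        assert cg.site_diversity(1, 2) == pytest.approx(1.0)

    def test_monomorphic(self):
        assert cg.site_diversity(0, 10) == 0.0

    def test_matches_pairwise_brute_force(self):
        # mean pairwise difference over all allele pairs, 6 alleles
        for alt in range(7):
            alleles = [1] * alt + [0] * (6 - alt)
            pairs = list(itertools.combinations(alleles, 2))
            brute = np.mean([a != b for a, b in pairs])
            assert cg.site_diversity(alt, 6) == pytest.approx(brute)


class TestWattersonTheta:
    def test_n2(self):
        assert cg.watterson_theta(5, 2, 1000) == pytest.approx(0.005)

    def test_n4(self):
        # a_3 = 1 + 1/2 + 1/3 = 11/6; S=11 over L=1 gives 6
        assert cg.watterson_theta(11, 4, 1) == pytest.approx(6.0)

    def test_zero_sites(self):
        assert cg.watterson_theta(0, 10, 100) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cg.watterson_theta(1, 1, 100)
        with pytest.raises(ValueError):
            cg.watterson_theta(1, 5, 0)


def _tajima_oracle(S, pi_sum, n):
    """Independent constant-by-constant transcription of Tajima (1989)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_sum - S / a1) / (e1 * S + e2 * S * (S - 1)) ** 0.5


class TestTajimaD:
    def test_zero_when_pi_equals_watterson(self):
        n = 10
        a1 = sum(1.0 / i for i in range(1, n))
        assert cg.tajima_d(7, 7 / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            S = int(rng.integers(1, 40))
            pi = float(rng.uniform(0.1, 30))
            assert cg.tajima_d(S, pi, n) == pytest.approx(
                _tajima_oracle(S, pi, n))

    def test_undefined_when_no_segregating_sites(self):
        assert np.isnan(cg.tajima_d(0, 0.0, 10))


class TestHudsonFst:
    def test_fixed_difference(self):
        assert cg.hudson_fst(1.0, 50, 0.0, 50) == pytest.approx(1.0)

    def test_equal_freqs_window_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 500)
        c1 = rng.binomial(100, p)
        c2 = rng.binomial(100, p)
        num, den = hudson_fst_components(c1 / 100, 100, c2 / 100, 100)
        assert abs(num.sum() / den.sum()) < 0.02

    def test_window_is_ratio_of_averages(self, wild_cult):
        stats = cg.window_scan(wild_cult, window=1_000_000)
        w = stats.iloc[0]
        sel = (wild_cult.pos >= w["start"]) & (wild_cult.pos <= w["end"])
        mw = wild_cult.population_labels == "wild"
        mc = wild_cult.population_labels == "cultivated"
        aw, tw = wild_cult.allele_counts(mw)
        ac, tc = wild_cult.allele_counts(mc)
        num, den = hudson_fst_components((ac / tc)[sel], tc[sel],
                                         (aw / tw)[sel], tw[sel])
        assert w["fst"] == pytest.approx(num.sum() / den.sum())


class TestNegLogRatio:
    def test_parity_is_zero(self):
        assert cg.neg_log_ratio(0.002, 0.002) == pytest.approx(0.0)

    def test_tenfold_is_one(self):
        assert cg.neg_log_ratio(0.0003, 0.003) == pytest.approx(1.0)

    def test_hundredfold_is_two(self):
        assert cg.neg_log_ratio(0.00002, 0.002) == pytest.approx(2.0)

    def test_zero_diversity_undefined(self):
        assert np.isnan(cg.neg_log_ratio(0.0, 0.01))
        assert np.isnan(cg.neg_log_ratio(0.01, 0.0))


class TestWindowScan:
    def test_boundary_variant_in_first_window(self):
        dosage = np.array([[0.0, 2], [2, 0], [1, 1], [0, 0]])
        vm = cg.VariantMatrix(
            sample_ids=list("abcd"), dosage=dosage,
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([100_000, 100_001]),
            ref=np.array(["A", "A"], dtype=object),
            alt=np.array(["G", "G"], dtype=object),
            population_labels=np.array(["wild", "wild", "cultivated",
                                        "cultivated"], dtype=object))
        stats = cg.window_scan(vm, window=100_000)
        assert stats.iloc[0]["n_sites"] == 1
        assert stats.iloc[1]["n_sites"] == 1

    def test_segregating_site_conservation(self, wild_cult):
        stats = cg.window_scan(wild_cult, window=100_000)
        mc = wild_cult.population_labels == "cultivated"
        ac, tc = wild_cult.allele_counts(mc)
        total_S = int(((ac > 0) & (ac < tc)).sum())
        assert stats["S_cult"].sum() == total_S

    def test_zero_effective_length_undefined(self, wild_cult):
        stats = cg.window_scan(wild_cult, window=100_000,
                               effective_lengths={("Pg1", 1): 0})
        assert np.isnan(stats.iloc[0]["theta_pi_cult"])

    def test_bad_window_rejected(self, wild_cult):
        with pytest.raises(ValueError):
            cg.window_scan(wild_cult, window=0)

    def test_tajima_d_near_zero_on_equilibrium_sfs(self):
        # neutral equilibrium: site frequencies with density ~ 1/x, under
        # which E[pi] = E[S]/a1 and D centres on zero
        rng = np.random.default_rng(12)
        n_loci, xmin = 4000, 1e-3
        p = xmin ** (1 - rng.uniform(size=n_loci))
        dosage = rng.binomial(2, p, size=(50, n_loci)).astype(float)
        pos = np.sort(rng.choice(np.arange(1, 2_000_001), n_loci,
                                 replace=False))
        vm = cg.VariantMatrix(
            sample_ids=[f"s{i}" for i in range(50)], dosage=dosage,
            chrom=np.array(["1"] * n_loci, dtype=object), pos=pos,
            ref=np.array(["A"] * n_loci, dtype=object),
            alt=np.array(["G"] * n_loci, dtype=object),
            population_labels=np.array(["wild"] * 25 + ["cultivated"] * 25,
                                       dtype=object))
        stats = cg.window_scan(vm, window=100_000)
        assert abs(np.nanmean(stats["tajima_d_wild"])) < 0.5

    def test_diversity_estimators_unbiased_under_drift(self):
        # 200 Balding-Nichols replicates: mean theta_pi per site tracks the
        # expected heterozygosity (1-F) * 2p(1-p) within 2 standard errors
        rng = np.random.default_rng(13)
        p0, F, n = 0.3, 0.1, 40
        ests = []
        for _ in range(200):
            pp = rng.beta(p0 * (1 - F) / F, (1 - p0) * (1 - F) / F)
            alt = rng.binomial(2 * n, pp)
            ests.append(cg.site_diversity(alt, 2 * n))
        expect = (1 - F) * 2 * p0 * (1 - p0)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - expect) < 2 * se + 1e-9


class TestCallOutliers:
    def test_null_joint_flag_rate(self):
        # independent uniform statistics: joint rate <= (1-q)^2 + slack
        rng = np.random.default_rng(4)
        n = 2000
        stats = pd.DataFrame({
            "chrom": "1",
            "start": np.arange(n) * 100_000 + 1,
            "end": (np.arange(n) + 1) * 100_000,
            "neg_log_ratio": rng.uniform(size=n),
            "fst": rng.uniform(size=n),
            "tajima_d_cult": 0.0,
        })
        flags, _ = cg.call_outliers(stats, q=0.95)
        assert flags.mean() <= 0.0035

    def test_planted_window_flagged_at_stringent_threshold(self):
        rng = np.random.default_rng(5)
        n = 300
        stats = pd.DataFrame({
            "chrom": "1",
            "start": np.arange(n) * 100_000 + 1,
            "end": (np.arange(n) + 1) * 100_000,
            "neg_log_ratio": rng.uniform(size=n),
            "fst": rng.uniform(size=n),
            "tajima_d_cult": 0.0,
        })
        stats.loc[42, ["neg_log_ratio", "fst"]] = 10.0, 10.0
        flags, regions = cg.call_outliers(stats, q=0.995)
        assert flags[42]
        assert ((regions["start"] <= stats.loc[42, "start"])
                & (regions["end"] >= stats.loc[42, "end"])).any()

    def test_sweep_recovery(self):
        sweeps = [(int(3e6 * i) + 1, int(3e6 * i) + 100_000)
                  for i in range(1, 11)]
        t = cg.SimTruth(seed=2, fst_target=0.08, sweep_windows=sweeps)
        vm = cg.simulate_populations(t, 100, 100, n_loci=12000,
                                     chrom_length=40_000_000)
        stats = cg.window_scan(vm, window=100_000)
        _, regions = cg.call_outliers(stats, q=0.95)
        hits = sum(((regions["start"] <= a) & (regions["end"] >= b)).any()
                   for a, b in sweeps)
        assert hits >= 8

    def test_too_few_windows_rejected(self):
        stats = pd.DataFrame({"chrom": "1", "start": [1], "end": [10],
                              "neg_log_ratio": [1.0], "fst": [0.5]})
        with pytest.raises(ValueError):
            cg.call_outliers(stats)


def _vm_from_haplotypes(H, positions, chrom="1"):
    """Inbred lines from 0/1 haplotypes (dosage = 2 * haplotype)."""
    p = H.shape[1]
    return cg.VariantMatrix(
        sample_ids=[f"s{i}" for i in range(H.shape[0])],
        dosage=2.0 * H, chrom=np.array([chrom] * p, dtype=object),
        pos=np.asarray(positions),
        ref=np.array(["A"] * p, dtype=object),
        alt=np.array(["G"] * p, dtype=object))


class TestLdDecay:
    def test_duplicated_snp_r2_one(self):
        rng = np.random.default_rng(6)
        h = rng.integers(0, 2, size=(50, 1))
        H = np.hstack([h, h])
        res = cg.ld_decay(_vm_from_haplotypes(H, [100, 5100]),
                          max_distance=10_000, maf_min=0.05)
        assert res.bins["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_snps_mean_r2(self):
        rng = np.random.default_rng(7)
        H = rng.integers(0, 2, size=(200, 300))
        pos = np.sort(rng.choice(np.arange(1, 200_000), 300, replace=False))
        res = cg.ld_decay(_vm_from_haplotypes(H, pos), max_distance=200_000,
                          maf_min=0.05)
        mean_r2 = np.average(res.bins["mean_r2"],
                             weights=res.bins["n_pairs"])
        assert mean_r2 == pytest.approx(1 / 200, abs=0.01)

    def test_copying_model_decay(self):
        # Markov haplotypes: corr(d) = exp(-d/L) so r2 crosses 0.2 at
        # d = L*ln(5)/2; binned means decrease and the estimate is
        # within a factor 2 of that truth.
        rng = np.random.default_rng(8)
        L = 10_000
        pos = np.sort(rng.choice(np.arange(1, 200_000), 400, replace=False))
        n = 300
        H = np.empty((n, 400), dtype=float)
        H[:, 0] = rng.integers(0, 2, n)
        for j in range(1, 400):
            r = np.exp(-(pos[j] - pos[j - 1]) / L)
            flip = rng.random(n) < (1 - r) / 2
            H[:, j] = np.where(flip, 1 - H[:, j - 1], H[:, j - 1])
        res = cg.ld_decay(_vm_from_haplotypes(H, pos), max_distance=100_000,
                          maf_min=0.05, n_bins=20)
        rho = sps.spearmanr(res.bins["center"], res.bins["mean_r2"])[0]
        assert rho < 0
        truth = L * np.log(5) / 2
        assert truth / 2 <= res.decay_distance <= truth * 2

    def test_no_pairs_in_range(self):
        rng = np.random.default_rng(9)
        H = rng.integers(0, 2, size=(50, 2))
        res = cg.ld_decay(_vm_from_haplotypes(H, [1, 900_000]),
                          max_distance=1000, maf_min=0.0)
        assert np.isnan(res.decay_distance) and res.bins.empty


class TestPDistance:
    def test_identical_and_hand_case(self):
        H = np.zeros((2, 100))
        H[1, :3] = 1.0  # 3 of 100 sites differ as 0 vs 2
        vm = _vm_from_haplotypes(H, np.arange(1, 101))
        D = cg.p_distance_matrix(vm)
        assert D.iloc[0, 0] == 0.0
        assert D.iloc[0, 1] == pytest.approx(0.03)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        X = rng.choice([0.0, 1, 2, np.nan], size=(5, 20),
                       p=[0.3, 0.2, 0.3, 0.2])
        X[:, 0] = [0, 1, 2, 0, 1]  # ensure shared sites
        vm = cg.VariantMatrix(
            sample_ids=list("abcde"), dosage=X,
            chrom=np.array(["1"] * 20, dtype=object), pos=np.arange(1, 21),
            ref=np.array(["A"] * 20, dtype=object),
            alt=np.array(["G"] * 20, dtype=object))
        D = cg.p_distance_matrix(vm)
        for i in range(5):
            for j in range(5):
                num = cnt = 0
                for k in range(20):
                    if not np.isnan(X[i, k]) and not np.isnan(X[j, k]):
                        num += abs(X[i, k] - X[j, k]) / 2
                        cnt += 1
                assert D.iloc[i, j] == pytest.approx(num / cnt)

    def test_no_shared_sites_raises(self):
        X = np.array([[0.0, np.nan], [np.nan, 2.0]])
        vm = cg.VariantMatrix(
            sample_ids=["a", "b"], dosage=X,
            chrom=np.array(["1", "1"], dtype=object), pos=np.array([1, 2]),
            ref=np.array(["A", "A"], dtype=object),
            alt=np.array(["G", "G"], dtype=object))
        with pytest.raises(ValueError, match="a.*b"):
            cg.p_distance_matrix(vm)


class TestNjTree:
    def test_additive_four_taxon_recovery(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4)) are additive
        import skbio
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0.0]],
            index=list("ABCD"), columns=list("ABCD"))
        newick = cg.nj_tree(D)
        tree = skbio.TreeNode.read([newick])
        paths = tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for b in list("ABCD")[i + 1:]:
                assert paths[a, b] == pytest.approx(D.loc[a, b], abs=1e-9)

    def test_population_monophyly(self, wild_cult):
        import skbio
        sub = wild_cult.take_samples(np.r_[0:15, 100:115])
        newick = cg.nj_tree(cg.p_distance_matrix(sub))
        tree = skbio.TreeNode.read([newick])
        wild = {s for s in sub.sample_ids if s.startswith("WILD")}
        tips = {t.name for t in tree.tips()}
        assert tips == set(sub.sample_ids)
        clades = {frozenset(t.name for t in node.tips())
                  for node in tree.non_tips(include_self=True)}
        bipartitions = clades | {frozenset(tips - c) for c in clades}
        assert frozenset(wild) in bipartitions

    def test_star_distances_total_length(self):
        D = pd.DataFrame(2.0 * (1 - np.eye(4)), index=list("ABCD"),
                         columns=list("ABCD"))
        import skbio
        tree = skbio.TreeNode.read([cg.nj_tree(D)])
        total = sum(n.length or 0 for n in tree.traverse())
        assert total == pytest.approx(4.0)

    def test_too_few_taxa(self):
        D = pd.DataFrame([[0, 1], [1, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            cg.nj_tree(D)


class TestPca:
    def test_population_separation(self, wild_cult):
        coords, _ = cg.pca(wild_cult, n_components=2)
        w = coords.iloc[:100, 0]
        c = coords.iloc[100:, 0]
        assert w.max() < c.min() or c.max() < w.min()

    def test_centering_and_explained(self, wild_cult):
        coords, explained = cg.pca(wild_cult, n_components=5)
        assert np.allclose(coords.mean(axis=0), 0, atol=1e-8)
        assert (np.diff(explained) <= 1e-12).all()
        assert explained.sum() <= 1.0

    def test_constant_matrix(self):
        vm = cg.VariantMatrix(
            sample_ids=["a", "b", "c"], dosage=np.full((3, 4), 2.0),
            chrom=np.array(["1"] * 4, dtype=object), pos=np.arange(1, 5),
            ref=np.array(["A"] * 4, dtype=object),
            alt=np.array(["G"] * 4, dtype=object))
        coords, explained = cg.pca(vm, n_components=2)
        assert np.allclose(coords, 0) and np.allclose(explained, 0)
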