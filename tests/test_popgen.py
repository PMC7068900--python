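import itertools

import numpy as np
import pytest

from conftest import build_panel
from linkinv.intervals import GenomicInterval
from linkinv.popgen import (AIM, Haplotype, aim_ancestry_fraction,
                            cluster_founder_haplotypes, detect_roh,
                            select_aims, site_fst, window_diversity,
                            windowed_fst)


def random_panel(seed=0, n_sites=60, n_samples=4, chrom="1", span=1_000_000):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, span), n_sites, replace=False))
    rows = [(chrom, int(p), "A", "C") for p in pos]
    g = rng.integers(0, 2, size=(n_sites, n_samples, 2)).astype(np.int8)
    samples = [f"s{i}" for i in range(n_samples)]
    half = n_samples // 2
    colony_of = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
    return build_panel(rows, g, samples, colony_of)


class TestWindowDiversity:
    def test_monomorphic_panel_has_zero_pi(self):
        rows = [("1", p, "A", "C") for p in (10, 500, 900)]
        g = np.zeros((3, 3, 2), dtype=np.int8)
        panel = build_panel(rows, g, ["s0", "s1", "s2"],
                            {f"s{i}": "A" for i in range(3)})
        df = window_diversity(panel, "A", {"1": 1_000_000})
        assert (df["value"] == 0).all()

    def test_single_site_closed_form(self):
        # p = 0.5 over n = 4 chromosomes in a 1-Mb window
        rows = [("1", 100, "A", "C")]
        g = np.array([[[0, 1], [1, 0]]], dtype=np.int8)
        panel = build_panel(rows, g, ["s0", "s1"], {"s0": "A", "s1": "A"})
        df = window_diversity(panel, "A", {"1": 1_000_000})
        expected = 2 * 0.25 * (4 / 3) / 1e6
        assert df["value"][0] == pytest.approx(expected, rel=1e-12)

    def test_matches_pairwise_difference_oracle(self):
        panel = random_panel(seed=3, n_sites=80)
        df = window_diversity(panel, "A", {"1": 1_000_000})
        # oracle: mean pairwise mismatch count over all chromosome pairs
        g = panel.genotypes[:, :2, :].reshape(80, 4)
        total = 0.0
        for i, j in itertools.combinations(range(4), 2):
            total += np.sum(g[:, i] != g[:, j])
        oracle = total / 6 / 1e6
        assert df["value"].sum() == pytest.approx(oracle, rel=1e-12)

    def test_sample_permutation_invariance(self):
        panel = random_panel(seed=4)
        a = window_diversity(panel, "A", {"1": 1_000_000})
        perm = panel.subset_sites(np.arange(panel.n_sites))
        perm.samples = panel.samples[::-1]
        perm.genotypes = panel.genotypes[:, ::-1, :]
        b = window_diversity(perm, "A", {"1": 1_000_000})
        np.testing.assert_allclose(a["value"], b["value"])

    def test_roh_masking_never_increases_pi(self):
        panel = random_panel(seed=5, n_sites=200)
        base = window_diversity(panel, "A", {"1": 1_000_000})
        masked = window_diversity(panel, "A", {"1": 1_000_000},
                                  roh_mask=[GenomicInterval("1", 0, 400_000)])
        assert (masked["value"] <= base["value"] + 1e-15).all()


class TestRoh:
    def _sample_panel(self, het_pos, hom_pos, length=4_000_000):
        pos = sorted(set(het_pos) | set(hom_pos))
        rows = [("1", p, "A", "C") for p in pos]
        g = np.zeros((len(pos), 1, 2), dtype=np.int8)
        for i, p in enumerate(pos):
            if p in het_pos:
                g[i] = [0, 1]
        return build_panel(rows, g, ["s0"], {"s0": "A"}), length

    def test_homozygous_stretch_flanked_by_het_clusters(self):
        het = list(range(1, 900_000, 10_000)) + \
              list(range(3_100_000, 4_000_000, 10_000))
        hom = list(range(1_000_001, 3_000_000, 50_000))
        panel, length = self._sample_panel(het, hom)
        rohs = detect_roh(panel, "s0", "1", chrom_length=length)
        assert len(rohs) == 1
        stretch = GenomicInterval("1", 1_000_000, 3_000_000)
        assert rohs[0].intersection_length(stretch) > 0.9 * stretch.length

    def test_uniformly_heterozygous_sample_has_no_roh(self):
        het = list(range(1, 4_000_000, 20_000))  # 50 het/Mb everywhere
        panel, length = self._sample_panel(het, [])
        assert detect_roh(panel, "s0", "1", chrom_length=length) == []

    def test_density_exactly_at_threshold_included(self):
        # 5 het calls in a 1-Mb chromosome: density == 5/Mb -> ROH ("<=")
        het = [100_000, 300_000, 500_000, 700_000, 900_000]
        panel, _ = self._sample_panel(het, [50_000], length=1_000_000)
        rohs = detect_roh(panel, "s0", "1", chrom_length=1_000_000)
        assert len(rohs) == 1


class TestFst:
    def test_fixed_difference_is_one(self):
        rows = [("1", 100, "A", "C")]
        g = np.array([[[0, 0], [0, 0], [1, 1], [1, 1]]], dtype=np.int8)
        panel = build_panel(rows, g, ["a1", "a2", "b1", "b2"],
                            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        theta = site_fst(panel, ["a1", "a2"], ["b1", "b2"])
        assert theta[0] == pytest.approx(1.0)

    def test_identical_pools_show_no_positive_differentiation(self):
        # the unbiased estimator scatters at or below zero when the pools
        # are identical (its expectation under no differentiation is zero)
        rows = [("1", 100, "A", "C")]
        g = np.array([[[0, 1], [1, 1], [0, 1], [1, 1]]], dtype=np.int8)
        panel = build_panel(rows, g, ["a1", "a2", "b1", "b2"],
                            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        theta = site_fst(panel, ["a1", "a2"], ["b1", "b2"])
        assert theta[0] <= 0.0

    def test_large_identical_hwe_pools_near_zero(self):
        rng = np.random.default_rng(12)
        n = 500
        hap = rng.integers(0, 2, size=(1, n, 2)).astype(np.int8)
        g = np.concatenate([hap, hap], axis=1)
        rows = [("1", 100, "A", "C")]
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        colony_of = {s: s[0].upper() for s in samples}
        panel = build_panel(rows, g, samples, colony_of)
        theta = site_fst(panel, samples[:n], samples[n:])
        assert theta[0] == pytest.approx(0.0, abs=2e-3)

    def test_monomorphic_site_reported_missing(self):
        rows = [("1", 100, "A", "C")]
        g = np.zeros((1, 4, 2), dtype=np.int8)
        panel = build_panel(rows, g, ["a1", "a2", "b1", "b2"],
                            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert np.isnan(site_fst(panel, ["a1", "a2"], ["b1", "b2"])[0])

    def test_components_match_hand_formula(self):
        # pools {0/0, 0/1} vs {0/1, 1/1}
        rows = [("1", 100, "A", "C")]
        g = np.array([[[0, 0], [0, 1], [0, 1], [1, 1]]], dtype=np.int8)
        panel = build_panel(rows, g, ["a1", "a2", "b1", "b2"],
                            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        theta = site_fst(panel, ["a1", "a2"], ["b1", "b2"])

        # independent scalar evaluation of the 1984 variance components
        r, n1, n2 = 2, 2.0, 2.0
        p1, p2 = 0.25, 0.75
        h1, h2 = 0.5, 0.5
        n_bar = (n1 + n2) / 2
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar)**2 + n2 * (p2 - p_bar)**2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = n_bar / n_c * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                 - h_bar / 4) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                   - h_bar * (2 * n_bar - 1) / (4 * n_bar))
        c = h_bar / 2
        assert theta[0] == pytest.approx(a / (a + b + c), rel=1e-12)

    def test_windowed_fst_pool_permutation_invariance(self):
        panel = random_panel(seed=8, n_sites=100)
        a = windowed_fst(panel, ["s0", "s1"], ["s2", "s3"], {"1": 1_000_000})
        b = windowed_fst(panel, ["s1", "s0"], ["s3", "s2"], {"1": 1_000_000})
        np.testing.assert_allclose(a["value"], b["value"])


class TestAims:
    def _callsets(self, drop_from_conserved=False):
        rows = [("1", 100, "A", "C"), ("1", 200, "G", "T")]
        # site 1: fixed difference; site 2: no differentiation
        g = np.array([
            [[0, 0], [0, 0], [1, 1], [1, 1]],
            [[0, 1], [0, 1], [0, 1], [0, 1]],
        ], dtype=np.int8)
        samples = ["a1", "a2", "b1", "b2"]
        colony_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        colony = build_panel(rows, g, samples, colony_of)
        conserved_rows = rows[1:] if drop_from_conserved else rows
        conserved_g = g[1:] if drop_from_conserved else g
        conserved = build_panel(conserved_rows, conserved_g, samples, colony_of)
        return colony, conserved

    def test_fixed_difference_selected_with_distinct_alleles(self):
        colony, conserved = self._callsets()
        aims = select_aims(colony, conserved, ["A"], ["B"])
        assert [(a.pos, a.allele_a, a.allele_b) for a in aims] == [(100, 0, 1)]
        assert all(a.fst > 0.8 for a in aims)

    def test_site_absent_from_conserved_excluded(self):
        colony, conserved = self._callsets(drop_from_conserved=True)
        assert select_aims(colony, conserved, ["A"], ["B"]) == []

    def test_ancestry_fraction_counting(self):
        # 10 AIMs; donor (pool B) allele predominates at 4 of them
        rows = [("1", 100 * (i + 1), "A", "C") for i in range(10)]
        g = np.zeros((10, 2, 2), dtype=np.int8)
        g[:4] = 1  # donor alt allele fixed at the first four loci
        panel = build_panel(rows, g, ["k1", "k2"], {"k1": "K", "k2": "K"})
        aims = [AIM("1", 100 * (i + 1), 1.0, 0, 1) for i in range(10)]
        assert aim_ancestry_fraction(aims, panel, "K", donor_is_a=False) \
            == pytest.approx(0.4)
        # the colony's own (pool A) alleles predominate nowhere -> 0.6 donor_a
        assert aim_ancestry_fraction(aims, panel, "K", donor_is_a=True) \
            == pytest.approx(0.6)

    def test_no_callable_aims_is_an_error(self):
        rows = [("1", 100, "A", "C")]
        g = np.full((1, 1, 2), -1, dtype=np.int8)
        panel = build_panel(rows, g, ["k1"], {"k1": "K"})
        with pytest.raises(ValueError):
            aim_ancestry_fraction([AIM("1", 100, 1.0, 0, 1)], panel, "K", True)

    def test_aim_count_increases_with_subspecies_drift(self):
        """More subspecies drift -> more highly differentiated sites."""
        from linkinv.genomics_io import build_callsets
        from linkinv.simulate import SimConfig, ColonySpec, simulate_all

        counts = []
        for f in (0.05, 0.25, 0.5):
            cfg = SimConfig(
                seed=20, chrom_lengths={"1": 1_500_000},
                repeat_density=0.0, admixture=[], inversions=[],
                f_split={"Aaa": f, "Aaf": f, "sister": 0.45},
                colonies=[ColonySpec("U", "Aaa", 3, 6),
                          ColonySpec("V", "Aaf", 3, 6)])
            sim = simulate_all(cfg)
            colony, conserved = build_callsets(sim.panel, sim.outgroup_panels)
            aims = select_aims(colony, conserved, ["U"], ["V"])
            counts.append(len(aims))
        assert counts[0] < counts[1] < counts[2]


class TestFounderClustering:
    def _hap(self, sample, phase, alleles, start=0, end=10_000):
        positions = np.arange(1, len(alleles) + 1) * (end - start) \
            // (len(alleles) + 1) + start
        return Haplotype(sample, phase, GenomicInterval("1", start, end),
                         positions, np.asarray(alleles, dtype=np.int8))

    def test_identical_haplotypes_form_one_cluster(self):
        a = self._hap("s1", 0, [0, 1, 0, 1])
        b = self._hap("s2", 0, [0, 1, 0, 1])
        assignment, clusters = cluster_founder_haplotypes([a, b])
        assert len(clusters) == 1 and assignment == [0, 0]

    @pytest.mark.parametrize("n_diff, n_clusters", [
        (11, 2),   # 1.1 diffs/kb over 10 kb: novel (strict "more than 1")
        (10, 1),   # exactly 1.0/kb: same founder
    ])
    def test_difference_rate_boundary(self, n_diff, n_clusters):
        base = [0] * 50
        other = list(base)
        for i in range(n_diff):
            other[i] = 1
        a = self._hap("s1", 0, base)
        b = self._hap("s2", 0, other)
        _, clusters = cluster_founder_haplotypes([a, b])
        assert len(clusters) == n_clusters

    def test_insufficient_overlap_leaves_haplotype_unassigned(self):
        a = self._hap("s1", 0, [0, 1, 0, 1], 0, 10_000)
        b = self._hap("s2", 0, [0, 1], 50_000, 52_000)
        assignment, clusters = cluster_founder_haplotypes([a, b])
        assert assignment[1] == -1 and len(clusters) == 1
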