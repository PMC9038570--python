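"""Tajima's D, window scan, z-normalization and clade partitioning."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from dmbtkit import synthdata
from dmbtkit.selscan import (HaplotypeMatrix, DegenerateDistributionError,
                             NoStructureError, partition_clades,
                             read_phased_vcf, select_tag_snp,
                             tajima_constants, tajimas_d, window_scan,
                             znormalize)
from dmbtkit.io import write_phased_vcf


def oracle_tajimas_d(alleles: np.ndarray) -> float:
    """Independent exact-arithmetic reference for Tajima's D.

    Constants built with fractions; pi by brute-force pairwise Hamming sums.
    """
    n, L = alleles.shape
    counts = alleles.sum(axis=0)
    seg = [(int(c)) for c in counts if 0 < c < n]
    S = len(seg)
    if S == 0:
        return float("nan")
    diffs = [int(np.sum(alleles[i] != alleles[j]))
             for i, j in combinations(range(n), 2)]
    pi = Fraction(sum(diffs), len(diffs))
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(pi - S / a1) / math.sqrt(float(var))


class TestTajimasD:
    def test_ladder_matches_exact_oracle(self, ladder_matrix):
        w = tajimas_d(ladder_matrix)
        assert w.S == 3
        assert w.pi == pytest.approx(10 / 6, abs=1e-12)
        assert w.theta_w == pytest.approx(3 / (1 + 0.5 + 1 / 3), abs=1e-12)
        assert w.D == pytest.approx(oracle_tajimas_d(ladder_matrix.alleles),
                                    abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        L = int(rng.integers(2, 30))
        alleles = rng.integers(0, 2, size=(n, L)).astype(np.uint8)
        mat = HaplotypeMatrix("c", np.arange(1, L + 1), alleles)
        got = tajimas_d(mat).D
        want = oracle_tajimas_d(alleles)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_tskit_on_msprime_genealogies(self, seed):
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(samples=10, ploidy=1, population_size=0.5,
                                  random_seed=seed)
        ts = msprime.sim_mutations(ts, rate=2.5, random_seed=seed,
                                   model="binary", discrete_genome=False)
        G = ts.genotype_matrix().T
        if G.shape[1] == 0:
            pytest.skip("no mutations at this seed")
        mat = HaplotypeMatrix("c", np.arange(1, G.shape[1] + 1),
                              G.astype(np.uint8))
        assert tajimas_d(mat).D == pytest.approx(float(ts.Tajimas_D()),
                                                 abs=1e-9)

    def test_monomorphic_matrix_has_undefined_d(self):
        mat = HaplotypeMatrix("c", [5, 6], np.zeros((4, 2), dtype=np.uint8))
        w = tajimas_d(mat)
        assert w.S == 0 and math.isnan(w.D) and not w.d_defined

    def test_sign_of_d_matches_pi_vs_theta_w(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            alleles = rng.integers(0, 2, size=(8, 15)).astype(np.uint8)
            w = tajimas_d(HaplotypeMatrix("c", np.arange(1, 16), alleles))
            if w.S and w.pi != pytest.approx(w.theta_w):
                assert math.copysign(1, w.D) == math.copysign(1, w.pi - w.theta_w)

    def test_haplotype_permutation_leaves_d_unchanged(self, ladder_matrix):
        rng = np.random.default_rng(1)
        perm = rng.permutation(ladder_matrix.n_hap)
        permuted = HaplotypeMatrix("chrT", ladder_matrix.positions,
                                   ladder_matrix.alleles[perm])
        assert tajimas_d(permuted).D == pytest.approx(
            tajimas_d(ladder_matrix).D, abs=1e-15)

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            HaplotypeMatrix("c", [1], np.array([[1]]))


class TestWindowScan:
    def test_boundary_positions_fall_in_adjacent_windows(self):
        mat = HaplotypeMatrix("c", [9999, 10001],
                              np.array([[0, 1], [1, 0]], dtype=np.uint8))
        windows = window_scan(mat, window_bp=10_000)
        assert [(w.start, w.end) for w in windows] == [(0, 10_000),
                                                       (10_000, 20_000)]
        assert [w.S for w in windows] == [1, 1]

    def test_single_window_equals_whole_matrix_statistic(self, ladder_matrix):
        windows = window_scan(ladder_matrix, window_bp=10_000)
        assert len(windows) == 1
        assert windows[0].D == pytest.approx(tajimas_d(ladder_matrix).D)

    def test_scan_matches_manual_chunking(self):
        mat = synthdata.simulate_neutral_window(10, 8.0, seed=5,
                                                window_bp=30_000)
        whole = window_scan(mat, window_bp=10_000)
        chunks = [tajimas_d(mat.slice_window(k * 10_000, (k + 1) * 10_000),
                            start=k * 10_000, end=(k + 1) * 10_000)
                  for k in range(3)
                  if mat.slice_window(k * 10_000, (k + 1) * 10_000).n_sites]
        assert [(w.start, w.S, w.D) for w in whole] == [
            (w.start, w.S, w.D) for w in chunks]

    def test_simulated_windows_consistent_with_watterson_expectation(self):
        theta, n, reps = 5.0, 10, 200
        a1 = tajima_constants(n)["a1"]
        S = [window_scan(synthdata.simulate_neutral_window(n, theta, s))[0].S
             for s in range(reps)
             if synthdata.simulate_neutral_window(n, theta, s).n_sites]
        var_s = theta * a1 + theta**2 * tajima_constants(n)["a2"]
        se = math.sqrt(var_s / len(S))
        assert abs(np.mean(S) - theta * a1) < 3 * se

    def test_invalid_window_size(self, ladder_matrix):
        with pytest.raises(ValueError):
            window_scan(ladder_matrix, window_bp=0)


class TestZNormalize:
    def _genome(self):
        mk = lambda D, S: type("W", (), {"D": D, "S": S, "d_defined": True})()
        from dmbtkit.selscan import WindowStat
        return [WindowStat("c", i * 10, i * 10 + 10, 5, 1.0, 1.0, d, 10)
                for i, d in enumerate([-1.0, 0.0, 1.0])]

    def test_target_at_genome_mean_scores_zero(self):
        from dmbtkit.selscan import WindowStat
        genome = self._genome()
        target = WindowStat("c", 0, 10, 5, 1.0, 1.0, 0.0, 10)
        assert znormalize(target, genome).z == pytest.approx(0.0)

    def test_unit_sd_genome_returns_d_as_z(self):
        from dmbtkit.selscan import WindowStat
        genome = self._genome()   # sample sd of {-1, 0, 1} is exactly 1
        target = WindowStat("c", 0, 10, 5, 1.0, 1.0, 2.67, 10)
        assert znormalize(target, genome).z == pytest.approx(2.67)

    def test_sparse_target_excluded_with_reason(self):
        from dmbtkit.selscan import WindowStat
        genome = self._genome()
        target = WindowStat("c", 0, 10, 2, 0.5, 0.5, 1.0, 10)
        zs = znormalize(target, genome, min_variable_sites=3)
        assert zs.excluded and "fewer than 3 variable sites" in zs.reason
        assert math.isnan(zs.z)

    def test_degenerate_genome_distribution_raises(self):
        from dmbtkit.selscan import WindowStat
        genome = [WindowStat("c", 0, 10, 5, 1.0, 1.0, 0.5, 10)] * 3
        target = WindowStat("c", 0, 10, 5, 1.0, 1.0, 1.0, 10)
        with pytest.raises(DegenerateDistributionError):
            znormalize(target, genome)


def brute_force_bipartition(alleles: np.ndarray) -> np.ndarray:
    """Bipartition maximizing between/within divergence ratio, by enumeration."""
    n = alleles.shape[0]
    best, best_ratio = None, -1.0
    for mask in range(1, 2 ** (n - 1)):
        labels = np.array([(mask >> i) & 1 for i in range(n)])
        between, within = [], []
        for i, j in combinations(range(n), 2):
            d = int(np.sum(alleles[i] != alleles[j]))
            (within if labels[i] == labels[j] else between).append(d)
        b = np.mean(between)
        w = np.mean(within) if within else 0.0
        ratio = b / w if w > 0 else (math.inf if b > 0 else 0.0)
        if ratio > best_ratio:
            best, best_ratio = labels, ratio
    return best


class TestCladePartition:
    def test_perfect_two_block_structure(self, two_block_matrix):
        part = partition_clades(two_block_matrix)
        assert set(np.unique(part.assignment)) == {0, 1}
        assert list(part.assignment) == [0, 0, 0, 1, 1, 1]
        assert part.between_divergence == pytest.approx(5.0)
        assert part.within_divergence == pytest.approx(0.0)
        assert part.concordant_sites.size == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_max_ratio_bipartition_on_small_structured_data(self, seed):
        mat, _ = synthdata.simulate_balanced_region(
            8, 0.5, clade_divergence=4, theta_within=0.5, seed=seed)
        part = partition_clades(mat)
        want = brute_force_bipartition(mat.alleles)
        agree = np.mean(part.assignment == want)
        assert agree in (0.0, 1.0)   # equal up to clade relabeling

    def test_recovers_truth_labels_without_within_clade_noise(self):
        mat, truth = synthdata.simulate_balanced_region(
            20, 0.4, clade_divergence=5, theta_within=0.0, seed=11)
        part = partition_clades(mat)
        truth01 = (truth.clade_labels == truth.clade_labels[0]).astype(int)
        agree = np.mean(part.assignment == (1 - truth01))
        assert agree in (0.0, 1.0)

    def test_permuting_haplotypes_relabels_only(self):
        mat, _ = synthdata.simulate_balanced_region(
            10, 0.5, clade_divergence=5, theta_within=1.0, seed=3)
        part = partition_clades(mat)
        rng = np.random.default_rng(4)
        perm = rng.permutation(mat.n_hap)
        permuted = HaplotypeMatrix(mat.chrom, mat.positions, mat.alleles[perm])
        part2 = partition_clades(permuted)
        agree = np.mean(part2.assignment == part.assignment[perm])
        assert agree in (0.0, 1.0)

    def test_identical_haplotypes_raise_no_structure(self):
        mat = HaplotypeMatrix("c", [1, 2], np.ones((4, 2), dtype=np.uint8))
        with pytest.raises((NoStructureError, ValueError)):
            partition_clades(mat)


class TestTagSnp:
    def test_perfectly_concordant_site_chosen(self, two_block_matrix):
        part = partition_clades(two_block_matrix)
        tag = select_tag_snp(part, two_block_matrix)
        assert tag.concordance == pytest.approx(1.0)
        assert tag.reliable

    def test_tie_breaks_to_leftmost_position(self):
        alleles = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.uint8)
        mat = HaplotypeMatrix("c", [100, 200], alleles)
        tag = select_tag_snp(partition_clades(mat), mat)
        assert tag.position == 100

    def test_planted_fixed_difference_recovered_amid_noise(self):
        mat, truth = synthdata.simulate_balanced_region(
            30, 0.5, clade_divergence=10, theta_within=1.0, seed=9)
        part = partition_clades(mat)
        tag = select_tag_snp(part, mat)
        # planted sites are exactly those fixed between the truth clades
        short = mat.alleles[truth.clade_labels == "short"]
        long_ = mat.alleles[truth.clade_labels == "long"]
        fixed = ((short == short[0]).all(axis=0)
                 & (long_ == long_[0]).all(axis=0)
                 & (short[0] != long_[0]))
        assert fixed[tag.site_index]
        assert tag.concordance == pytest.approx(1.0)


class TestVcfRoundTrip:
    def test_writer_reader_inverse(self, tmp_path):
        mat = synthdata.simulate_neutral_window(8, 4.0, seed=2)
        path = tmp_path / "x.vcf"
        write_phased_vcf(mat, path)
        back = read_phased_vcf(str(path))
        assert np.array_equal(back.alleles, mat.alleles)
        assert np.array_equal(back.positions, mat.positions)

    def test_unphased_and_multiallelic_records_skipped(self, tmp_path):
        path = tmp_path / "y.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\n"
            "chr1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"
            "chr1\t300\t.\tA\tC,G\t.\tPASS\t.\tGT\t0|1\n")
        mat = read_phased_vcf(str(path))
        assert mat.n_sites == 1 and mat.positions[0] == 100
        assert np.array_equal(mat.alleles[:, 0], [0, 1])
        assert mat.meta["n_skipped_unphased"] == 1
        assert mat.meta["n_skipped_multiallelic"] == 1

    def test_region_query_on_plain_vcf(self, tmp_path):
        mat = synthdata.simulate_neutral_window(6, 5.0, seed=1, start=5001)
        path = tmp_path / "r.vcf"
        write_phased_vcf(mat, path)
        lo, hi = 5001, int(mat.positions[mat.n_sites // 2])
        sub = read_phased_vcf(str(path), region=f"chrSim:{lo}-{hi}")
        keep = (mat.positions >= lo) & (mat.positions <= hi)
        assert np.array_equal(sub.positions, mat.positions[keep])
        assert np.array_equal(sub.alleles, mat.alleles[:, keep])

    def test_missing_sample_reported(self, tmp_path):
        mat = synthdata.simulate_neutral_window(4, 4.0, seed=2)
        path = tmp_path / "z.vcf"
        write_phased_vcf(mat, path)
        with pytest.raises(ValueError, match="absent"):
            read_phased_vcf(str(path), samples=["nope"])
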