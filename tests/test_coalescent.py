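import math

import msprime
import numpy as np
import pytest
from scipy import stats

from coaldrop.coalescent import (
    ChromosomeSpec,
    HaplotypePanel,
    LocalTree,
    MsParseError,
    read_ms_panel,
    simulate_panel,
    write_ms_panel,
)
from coaldrop.demography import NeTrajectory


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


def pairwise_tmrca(tree: LocalTree, a: int, b: int) -> float:
    ancestors = {}
    v = a
    while v != -1:
        ancestors[v] = tree.time[v]
        v = int(tree.parent[v])
    v = b
    while v not in ancestors:
        v = int(tree.parent[v])
    return float(tree.time[v])


class TestChromosomeSpec:
    def test_recombination_rate_derivation(self):
        chrom = ChromosomeSpec(1, 100.0, 100_000_000, 2.5e-8)
        assert chrom.recombination_rate_per_bp == pytest.approx(1e-8)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ChromosomeSpec(1, 0.0, 100, 1e-8)
        with pytest.raises(ValueError):
            ChromosomeSpec(1, 1.0, 0, 1e-8)


class TestLocalTree:
    def test_ultrametric_and_increasing_times(self, const_ne_100, rng):
        tree = LocalTree.simulate(8, const_ne_100, rng)
        assert np.all(tree.time[:8] == 0)
        for v in range(tree.parent.size):
            p = int(tree.parent[v])
            if p != -1:
                assert tree.time[p] > tree.time[v]

    def test_tmrca_n2_matches_exponential_2ne(self, const_ne_100):
        rng = np.random.default_rng(0)
        heights = np.array(
            [LocalTree.simulate(2, const_ne_100, rng).height() for _ in range(10_000)]
        )
        res = stats.kstest(heights, stats.expon(scale=200.0).cdf)
        assert res.pvalue > 1e-3

    def test_pairwise_tmrca_n12_matches_exponential_2ne(self, const_ne_100):
        rng = np.random.default_rng(1)
        draws = np.array(
            [
                pairwise_tmrca(LocalTree.simulate(12, const_ne_100, rng), 0, 1)
                for _ in range(10_000)
            ]
        )
        res = stats.kstest(draws, stats.expon(scale=200.0).cdf)
        assert res.pvalue > 1e-3


class TestSimulatePanel:
    def test_rejects_small_samples(self, const_ne_100, rng):
        chrom = ChromosomeSpec(1, 1.0, 1000, 1e-8)
        with pytest.raises(ValueError):
            simulate_panel(1, chrom, const_ne_100, rng)

    def test_zero_mutation_rate_gives_empty_panel(self, const_ne_100, rng):
        chrom = ChromosomeSpec(1, 1.0, 10_000, 0.0)
        panel = simulate_panel(4, chrom, const_ne_100, rng)
        assert panel.n_sites == 0

    def test_watterson_n2_no_recombination(self, const_ne_100):
        # E[S] = 4 Ne mu L = 10 for Ne=100, mu=2.5e-8, L=1e6
        rng = np.random.default_rng(2)
        chrom = ChromosomeSpec(1, 1e-9, 1_000_000, 2.5e-8)
        S = np.array(
            [simulate_panel(2, chrom, const_ne_100, rng).n_sites for _ in range(500)]
        )
        se = S.std() / math.sqrt(S.size)
        assert abs(S.mean() - 10.0) < 3 * se

    def test_expected_sites_invariant_to_recombination(self, const_ne_1000):
        rng = np.random.default_rng(3)
        with_r = ChromosomeSpec(1, 1.0, 1_000_000, 1e-8)
        no_r = ChromosomeSpec(1, 1e-9, 1_000_000, 1e-8)
        expected = 4 * 1000 * 1e-8 * 1e6 * harmonic(10)
        s_r = np.array(
            [simulate_panel(10, with_r, const_ne_1000, rng).n_sites for _ in range(200)]
        )
        s_n = np.array(
            [simulate_panel(10, no_r, const_ne_1000, rng).n_sites for _ in range(200)]
        )
        for s in (s_r, s_n):
            se = s.std() / math.sqrt(s.size)
            assert abs(s.mean() - expected) < 3 * se

    def test_site_frequency_spectrum_n10(self, const_ne_1000):
        # E[# sites with derived count i] = theta L / i
        rng = np.random.default_rng(4)
        chrom = ChromosomeSpec(1, 1.0, 300_000, 1e-7)
        counts = np.zeros(10)
        reps = 1000
        per_rep = []
        for _ in range(reps):
            panel = simulate_panel(10, chrom, const_ne_1000, rng)
            freq = panel.alleles.sum(axis=0)
            c = np.bincount(freq, minlength=10)
            counts += c
            per_rep.append(c)
        theta_l = 4 * 1000 * 1e-7 * 300_000
        per_rep = np.array(per_rep)
        for i in range(1, 10):
            se = per_rep[:, i].std() / math.sqrt(reps)
            assert abs(per_rep[:, i].mean() - theta_l / i) < 3 * se + 1e-9

    def test_panel_invariants(self, const_ne_1000, rng):
        chrom = ChromosomeSpec(1, 1.0, 100_000, 1e-6)
        panel = simulate_panel(12, chrom, const_ne_1000, rng)
        panel.validate()
        assert panel.n_sites > 0
        sums = panel.alleles.sum(axis=0)
        assert np.all((sums > 0) & (sums < 12))
        assert np.all(np.diff(panel.positions) > 0)

    def test_smc_variant_runs_and_matches_expectation(self, const_ne_1000):
        rng = np.random.default_rng(5)
        chrom = ChromosomeSpec(1, 1.0, 1_000_000, 1e-8)
        expected = 4 * 1000 * 1e-8 * 1e6 * harmonic(6)
        s = np.array(
            [
                simulate_panel(6, chrom, const_ne_1000, rng, smc_prime=False).n_sites
                for _ in range(200)
            ]
        )
        se = s.std() / math.sqrt(s.size)
        assert abs(s.mean() - expected) < 3 * se


class TestAgainstHudsonOracle:
    """Distributional agreement with a full-ARG (Hudson) simulator on
    small instances with a handful of recombination breakpoints."""

    N = 6
    NE = 1000.0
    L = 50_000
    R = 1e-8  # ~2 breakpoints per replicate at these branch lengths
    REPS = 1200

    def _mine(self, stat):
        traj = NeTrajectory((0.0,), (self.NE,))
        chrom = ChromosomeSpec(1, self.R * self.L * 100, self.L, 0.0)
        rng = np.random.default_rng(6)
        out = []
        for _ in range(self.REPS):
            tree = LocalTree.simulate(self.N, traj, rng)
            x = 0.0
            while True:
                total = tree.total_branch_length()
                x += rng.exponential(1.0 / (self.R * total))
                if x >= self.L:
                    break
                tree.recombination_event(traj, rng, smc_prime=True)
            out.append(stat(tree))
        return np.array(out)

    def _msprime(self, stat):
        out = []
        for seed in range(1, self.REPS + 1):
            # ploidy=2 so the per-pair rate is 1/(2 Ne), matching our scaling
            ts = msprime.sim_ancestry(
                samples=self.N // 2, ploidy=2, population_size=self.NE,
                sequence_length=self.L, recombination_rate=self.R,
                random_seed=seed, model="hudson",
            )
            tree = ts.last()
            out.append(stat(tree))
        return np.array(out)

    def test_final_tree_height_distribution(self):
        mine = self._mine(lambda t: t.height())
        ref = self._msprime(lambda t: max(t.time(r) for r in t.roots))
        res = stats.ks_2samp(mine, ref)
        assert res.pvalue > 1e-3

    def test_final_tree_length_distribution(self):
        mine = self._mine(lambda t: t.total_branch_length())
        ref = self._msprime(lambda t: t.total_branch_length)
        res = stats.ks_2samp(mine, ref)
        assert res.pvalue > 1e-3


class TestMsIO:
    def test_direct_mapping_example(self):
        chrom = ChromosomeSpec(1, 1.0, 100, 1e-8)
        text = "segsites: 2\npositions: 0.25 0.75\n01\n10\n"
        panel = read_ms_panel(text, chrom)
        assert panel.positions.tolist() == [25, 75]
        assert panel.alleles.tolist() == [[0, 1], [1, 0]]

    def test_empty_replicate(self):
        chrom = ChromosomeSpec(1, 1.0, 100, 1e-8)
        panel = read_ms_panel("segsites: 0\n", chrom)
        assert panel.n_sites == 0

    def test_single_site_write(self):
        chrom = ChromosomeSpec(1, 1.0, 100, 1e-8)
        panel = HaplotypePanel(
            chrom,
            np.array([50], dtype=np.int64),
            np.array([[1], [0]], dtype=np.uint8),
        )
        text = write_ms_panel(panel)
        assert "segsites: 1" in text
        assert len(text.splitlines()[2].split(":")[1].split()) == 1

    def test_empty_panel_write(self):
        chrom = ChromosomeSpec(1, 1.0, 100, 1e-8)
        panel = HaplotypePanel(
            chrom, np.zeros(0, dtype=np.int64), np.zeros((2, 0), dtype=np.uint8)
        )
        assert "segsites: 0" in write_ms_panel(panel)

    def test_round_trip_simulated_panel(self, const_ne_1000, rng):
        chrom = ChromosomeSpec(1, 1.0, 1_000_000, 1e-7)
        panel = simulate_panel(8, chrom, const_ne_1000, rng)
        back = read_ms_panel(write_ms_panel(panel), chrom)
        assert np.array_equal(back.positions, panel.positions)
        assert np.array_equal(back.alleles, panel.alleles)

    def test_position_tie_breaking(self):
        chrom = ChromosomeSpec(1, 1.0, 100, 1e-8)
        text = "segsites: 2\npositions: 0.25 0.25\n01\n10\n"
        panel = read_ms_panel(text, chrom)
        assert panel.positions.tolist() == [25, 26]

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("segsites: 2\npositions: 0.1 0.2\n01\n1\n", "length 1"),
            ("segsites: 2\npositions: 0.1 0.2\n0x\n10\n", "non-binary"),
            ("segsites: 2\npositions: 0.1\n01\n10\n", "1 positions"),
            ("positions: 0.1\n01\n", "segsites"),
        ],
    )
    def test_parse_errors_name_lines(self, text, fragment):
        chrom = ChromosomeSpec(1, 1.0, 100, 1e-8)
        with pytest.raises(MsParseError, match=fragment):
            read_ms_panel(text, chrom)
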