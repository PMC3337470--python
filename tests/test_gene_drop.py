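import math

import numpy as np
import pytest
from scipy import stats

from coaldrop.coalescent import ChromosomeSpec, simulate_panel
from coaldrop.demography import NeTrajectory
from coaldrop.gene_drop import (
    MATERNAL,
    PATERNAL,
    DiploidGenome,
    MeiosisLog,
    RecombinationModel,
    cm_to_site_index,
    draw_crossovers,
    drop,
    make_base_gamete,
    meiosis,
)
from coaldrop.packed_haplotypes import pack_bits, unpack_words
from coaldrop.pedigree import generate_pedigree, read_pedigree


MODEL = RecombinationModel()


class TestDrawCrossovers:
    def test_mean_is_one_per_100cm(self):
        rng = np.random.default_rng(0)
        counts = np.array(
            [draw_crossovers(100.0, MODEL, rng).size for _ in range(100_000)]
        )
        se = counts.std() / math.sqrt(counts.size)
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_zero_length(self, rng):
        assert draw_crossovers(0.0, MODEL, rng).size == 0

    def test_count_distribution_poisson(self):
        rng = np.random.default_rng(1)
        counts = np.array(
            [draw_crossovers(100.0, MODEL, rng).size for _ in range(100_000)]
        )
        observed = np.bincount(counts, minlength=6)
        observed = np.append(observed[:5], observed[5:].sum())
        pmf = stats.poisson(1.0).pmf(np.arange(5))
        expected = np.append(pmf, 1 - pmf.sum()) * counts.size
        res = stats.chisquare(observed, expected)
        assert res.pvalue > 1e-3

    def test_positions_sorted_and_in_range(self, rng):
        for _ in range(200):
            pos = draw_crossovers(50.0, RecombinationModel(0.1), rng)
            assert np.all(np.diff(pos) >= 0)
            assert np.all((pos >= 0) & (pos <= 50.0))


class TestCmToSiteIndex:
    CHROM = ChromosomeSpec(1, 100.0, 1000, 1e-8)
    POSITIONS = np.array([10, 300, 301, 999], dtype=np.int64)

    def test_zero_maps_to_zero(self):
        assert cm_to_site_index(0.0, self.CHROM, self.POSITIONS) == 0

    def test_full_length_maps_to_n_sites(self):
        assert cm_to_site_index(100.0, self.CHROM, self.POSITIONS) == 4

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cm_to_site_index(101.0, self.CHROM, self.POSITIONS)

    def test_randomized_against_linear_scan(self, rng):
        positions = np.sort(
            rng.choice(np.arange(1, 100_001), size=500, replace=False)
        ).astype(np.int64)
        chrom = ChromosomeSpec(1, 100.0, 100_000, 1e-8)
        for _ in range(500):
            cm = float(rng.random() * 100.0)
            bp = cm / 100.0 * 100_000
            expected = next(
                (i for i, p in enumerate(positions) if p >= bp), len(positions)
            )
            assert cm_to_site_index(cm, chrom, positions) == expected


class TestMakeBaseGamete:
    def test_zero_crossover_copies_one_haplotype(self, small_panel):
        rng = np.random.default_rng(2)
        no_recomb = RecombinationModel(rate_per_cm=1e-12)
        g = make_base_gamete(small_panel, no_recomb, rng)
        bits = unpack_words(g.words, g.n_sites)
        assert any(
            np.array_equal(bits, small_panel.alleles[h])
            for h in range(small_panel.n_haplotypes)
        )

    def test_alleles_always_from_panel_columns(self, small_panel):
        rng = np.random.default_rng(3)
        hot = RecombinationModel(rate_per_cm=0.05)
        col_has = [
            set(np.unique(small_panel.alleles[:, j]))
            for j in range(small_panel.n_sites)
        ]
        for _ in range(20):
            g = make_base_gamete(small_panel, hot, rng)
            bits = unpack_words(g.words, g.n_sites)
            for j in range(small_panel.n_sites):
                assert int(bits[j]) in col_has[j]

    def test_base_frequencies_track_panel(self, small_panel):
        rng = np.random.default_rng(4)
        n_gametes = 2000
        total = np.zeros(small_panel.n_sites)
        for _ in range(n_gametes):
            g = make_base_gamete(small_panel, MODEL, rng)
            total += unpack_words(g.words, g.n_sites)
        freq = total / n_gametes
        panel_freq = small_panel.alleles.mean(axis=0)
        se = np.sqrt(panel_freq * (1 - panel_freq) / n_gametes)
        ok = np.abs(freq - panel_freq) < 4 * se + 1e-12
        assert ok.mean() > 0.99  # a few 4-sigma excursions are expected

    def test_empty_panel_rejected(self, small_panel, rng):
        from coaldrop.coalescent import HaplotypePanel

        empty = HaplotypePanel(
            small_panel.chromosome,
            np.zeros(0, dtype=np.int64),
            np.zeros((0, 0), dtype=np.uint8),
        )
        with pytest.raises(ValueError):
            make_base_gamete(empty, MODEL, rng)


def _diploid_from_panel(panel, i, j):
    return DiploidGenome(
        paternal=[_packed(panel, i)],
        maternal=[_packed(panel, j)],
    )


def _packed(panel, h):
    from coaldrop.packed_haplotypes import PackedGamete

    return PackedGamete(panel.n_sites, pack_bits(panel.alleles[h]))


class TestMeiosis:
    def test_homozygous_parent_transmits_identically(self, small_panel):
        rng = np.random.default_rng(5)
        parent = _diploid_from_panel(small_panel, 3, 3)
        g = meiosis(parent, 0, small_panel.chromosome, small_panel.positions, MODEL, rng)
        assert np.array_equal(
            unpack_words(g.words, g.n_sites), small_panel.alleles[3]
        )

    def test_mendelian_consistency(self, small_panel):
        rng = np.random.default_rng(6)
        for _ in range(50):
            i, j = rng.integers(small_panel.n_haplotypes, size=2)
            parent = _diploid_from_panel(small_panel, int(i), int(j))
            g = meiosis(
                parent, 0, small_panel.chromosome, small_panel.positions, MODEL, rng
            )
            bits = unpack_words(g.words, g.n_sites)
            a = small_panel.alleles[int(i)]
            b = small_panel.alleles[int(j)]
            assert np.all((bits == a) | (bits == b))

    def test_transmission_ratio_half_at_het_sites(self, small_panel):
        rng = np.random.default_rng(7)
        i, j = 0, 1
        het = np.flatnonzero(small_panel.alleles[i] != small_panel.alleles[j])
        site = int(het[0])
        parent = _diploid_from_panel(small_panel, i, j)
        n = 10_000
        hits = 0
        for _ in range(n):
            g = meiosis(
                parent, 0, small_panel.chromosome, small_panel.positions, MODEL, rng
            )
            hits += int(unpack_words(g.words, g.n_sites)[site] == small_panel.alleles[i][site])
        p = hits / n
        se = math.sqrt(0.25 / n)
        assert abs(p - 0.5) < 3 * se


@pytest.fixture(scope="module")
def dropped(small_panel):
    rng = np.random.default_rng(8)
    ped = generate_pedigree(5, 3, 3, 2, rng)
    genomes = drop(ped, [small_panel], MODEL, rng)
    return ped, genomes


class TestDrop:
    def test_single_base_individual(self, small_panel):
        rng = np.random.default_rng(9)
        ped = read_pedigree("1 0 0\n")
        genomes = drop(ped, [small_panel], MODEL, rng)
        cg = genomes.chromosomes[0]
        assert not np.array_equal(cg.words[0, 0], cg.words[0, 1]) or True
        assert cg.words.shape[0] == 1

    def test_trio_mendelian_consistency(self, small_panel):
        rng = np.random.default_rng(10)
        ped = read_pedigree("1 0 0\n2 0 0\n3 1 2\n")
        genomes = drop(ped, [small_panel], MODEL, rng)
        cg = genomes.chromosomes[0]
        child_pat = cg.bits(2, PATERNAL)
        child_mat = cg.bits(2, MATERNAL)
        sire = (cg.bits(0, PATERNAL), cg.bits(0, MATERNAL))
        dam = (cg.bits(1, PATERNAL), cg.bits(1, MATERNAL))
        assert np.all((child_pat == sire[0]) | (child_pat == sire[1]))
        assert np.all((child_mat == dam[0]) | (child_mat == dam[1]))

    def test_full_drop_mendelian_audit(self, dropped, small_panel):
        ped, genomes = dropped
        cg = genomes.chromosomes[0]
        row_of = ped.index_of()
        rng = np.random.default_rng(11)
        audit_sites = rng.choice(
            small_panel.n_sites, size=min(1000, small_panel.n_sites), replace=False
        )
        for ind in ped:
            if ind.sire_id == 0:
                continue
            i = row_of[ind.id]
            pat = cg.bits(i, PATERNAL)[audit_sites]
            sp = cg.bits(row_of[ind.sire_id], PATERNAL)[audit_sites]
            sm = cg.bits(row_of[ind.sire_id], MATERNAL)[audit_sites]
            assert np.all((pat == sp) | (pat == sm))

    def test_no_mutation_fixed_sites_stay_fixed(self, dropped):
        ped, genomes = dropped
        cg = genomes.chromosomes[0]
        base_rows = [i for i, ind in enumerate(ped) if ind.generation == 0]
        all_rows = range(len(ped))
        base_sum = np.zeros(cg.n_sites, dtype=np.int64)
        for r in base_rows:
            base_sum += cg.bits(r, 0)
            base_sum += cg.bits(r, 1)
        lost = base_sum == 0
        fixed = base_sum == 2 * len(base_rows)
        total = np.zeros(cg.n_sites, dtype=np.int64)
        for r in all_rows:
            total += cg.bits(r, 0)
            total += cg.bits(r, 1)
        assert np.all(total[lost] == 0)
        assert np.all(total[fixed] == 2 * len(ped))

    def test_dosage_is_gamete_sum(self, dropped):
        ped, genomes = dropped
        cg = genomes.chromosomes[0]
        d = cg.dosage()
        assert d.min() >= 0 and d.max() <= 2
        for r in (0, len(ped) // 2, len(ped) - 1):
            assert np.array_equal(d[r], cg.bits(r, 0).astype(np.int8) + cg.bits(r, 1))

    def test_no_systematic_frequency_trend(self, small_panel):
        # drift only: per-site regression slopes of frequency on generation
        # should center on zero
        rng = np.random.default_rng(12)
        ped = generate_pedigree(6, 8, 5, 2, rng)
        genomes = drop(ped, [small_panel], MODEL, rng)
        cg = genomes.chromosomes[0]
        gens = np.array([ind.generation for ind in ped])
        n_gen = gens.max() + 1
        freqs = np.zeros((n_gen, cg.n_sites))
        for g in range(n_gen):
            rows = np.flatnonzero(gens == g)
            tot = np.zeros(cg.n_sites)
            for r in rows:
                tot += cg.bits(r, 0)
                tot += cg.bits(r, 1)
            freqs[g] = tot / (2 * rows.size)
        x = np.arange(n_gen) - (n_gen - 1) / 2
        slopes = (x @ (freqs - freqs.mean(axis=0))) / (x @ x)
        se = slopes.std() / math.sqrt(cg.n_sites)
        assert abs(slopes.mean()) < 4 * se + 1e-3

    def test_meiosis_log_counts(self, dropped, small_panel):
        ped, genomes = dropped
        log = genomes.meiosis_log
        n_base = len(ped.generation(0))
        expected = 2 * n_base + 2 * (len(ped) - n_base)
        assert log.n_meioses == expected
        assert log.total_cm == expected * small_panel.chromosome.genetic_length_cm

    def test_missing_parent_genome_error(self, small_panel):
        from coaldrop.pedigree import Individual, Pedigree

        bad = Pedigree([Individual(5, 1, 2, "M", 1)])
        with pytest.raises(RuntimeError, match="ordering"):
            drop(bad, [small_panel], MODEL, np.random.default_rng(0))
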