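"""Gene drop: base-gamete construction and Mendelian transmission.

Base individuals assemble each gamete from the coalescent panel: crossover
positions are Poisson on the genetic map and each inter-breakpoint segment
is copied from an independently (with replacement) chosen panel haplotype.
Every later individual receives one recombined gamete from each parent —
Mendelian inheritance with Poisson crossovers, no interference and no
mutation.  Gametes are stored bit-packed throughout; crossovers operate on
packed words via :mod:`coaldrop.packed_haplotypes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import ChromosomeSpec, HaplotypePanel
from .packed_haplotypes import (
    PackedGamete,
    WORD_WIDTH,
    pack_bits,
    recombine_words,
    unpack_words,
)
from .pedigree import Pedigree

__all__ = [
    "RecombinationModel",
    "DiploidGenome",
    "ChromosomeGenomes",
    "PopulationGenomes",
    "MeiosisLog",
    "draw_crossovers",
    "cm_to_site_index",
    "make_base_gamete",
    "meiosis",
    "drop",
]

PATERNAL, MATERNAL = 0, 1


@dataclass(frozen=True)
class RecombinationModel:
    """Poisson crossover process: ``rate_per_cm`` events per cM, no
    interference (default 0.01/cM, i.e. one event per Morgan)."""

    rate_per_cm: float = 0.01

    def __post_init__(self) -> None:
        if self.rate_per_cm <= 0:
            raise ValueError("rate_per_cm must be positive")


@dataclass
class MeiosisLog:
    """Counters enabling post-hoc crossover-rate audits."""

    n_meioses: int = 0
    n_crossovers: int = 0
    total_cm: float = 0.0


@dataclass
class DiploidGenome:
    """One individual's two packed gametes per chromosome (paternal first)."""

    paternal: list[PackedGamete]
    maternal: list[PackedGamete]


@dataclass
class ChromosomeGenomes:
    """All gametes of the population for one chromosome.

    ``words`` has shape (n_individuals, 2, n_words); axis 1 is
    paternal/maternal.  Rows follow pedigree order.
    """

    chromosome: ChromosomeSpec
    positions: np.ndarray  # site bp positions (1-based), sorted
    n_sites: int
    words: np.ndarray

    def gamete(self, row: int, which: int) -> PackedGamete:
        return PackedGamete(self.n_sites, self.words[row, which])

    def bits(self, row: int, which: int) -> np.ndarray:
        return unpack_words(self.words[row, which], self.n_sites)

    def dosage(self, site_indices: np.ndarray | None = None) -> np.ndarray:
        """(n_individuals x n_sites-or-subset) matrix of 0/1/2 counts."""
        n_ind = self.words.shape[0]
        cols = self.n_sites if site_indices is None else len(site_indices)
        out = np.empty((n_ind, cols), dtype=np.int8)
        for i in range(n_ind):
            bits = (
                unpack_words(self.words[i, 0], self.n_sites).astype(np.int8)
                + unpack_words(self.words[i, 1], self.n_sites)
            )
            out[i] = bits if site_indices is None else bits[site_indices]
        return out


@dataclass
class PopulationGenomes:
    """Per-chromosome packed gametes for every pedigree member."""

    pedigree: Pedigree
    chromosomes: list[ChromosomeGenomes]
    meiosis_log: MeiosisLog = field(default_factory=MeiosisLog)

    @property
    def n_individuals(self) -> int:
        return len(self.pedigree)

    def genome_of(self, row: int) -> DiploidGenome:
        return DiploidGenome(
            paternal=[c.gamete(row, PATERNAL) for c in self.chromosomes],
            maternal=[c.gamete(row, MATERNAL) for c in self.chromosomes],
        )


def draw_crossovers(
    genetic_length_cm: float, model: RecombinationModel, rng: np.random.Generator
) -> np.ndarray:
    """Sorted crossover positions (cM): Poisson count, uniform placement."""
    if genetic_length_cm < 0:
        raise ValueError("genetic length must be non-negative")
    if genetic_length_cm == 0:
        return np.zeros(0, dtype=np.float64)
    count = rng.poisson(model.rate_per_cm * genetic_length_cm)
    if count == 0:
        return np.zeros(0, dtype=np.float64)
    return np.sort(rng.random(count) * genetic_length_cm)


def cm_to_site_index(
    pos_cm: float, chrom: ChromosomeSpec, panel_positions: np.ndarray
) -> int:
    """Map a genetic position to the first segregating site at/after the
    corresponding bp coordinate (uniform cM<->bp map).  May return
    ``n_sites`` (a no-op breakpoint, dropped by callers)."""
    if not (0 <= pos_cm <= chrom.genetic_length_cm):
        raise ValueError(f"position {pos_cm} outside [0, {chrom.genetic_length_cm}] cM")
    bp = pos_cm / chrom.genetic_length_cm * chrom.physical_length_bp
    return int(np.searchsorted(panel_positions, bp, side="left"))


def _crossover_site_breakpoints(
    chrom: ChromosomeSpec,
    positions: np.ndarray,
    n_sites: int,
    model: RecombinationModel,
    rng: np.random.Generator,
    log: MeiosisLog | None,
) -> np.ndarray:
    cm = draw_crossovers(chrom.genetic_length_cm, model, rng)
    if log is not None:
        log.n_meioses += 1
        log.n_crossovers += cm.size
        log.total_cm += chrom.genetic_length_cm
    if cm.size == 0 or n_sites == 0:
        return np.zeros(0, dtype=np.int64)
    bp = cm / chrom.genetic_length_cm * chrom.physical_length_bp
    idx = np.searchsorted(positions, bp, side="left")
    idx = np.unique(idx[(idx > 0) & (idx < n_sites)])
    return idx


def make_base_gamete(
    panel: HaplotypePanel,
    model: RecombinationModel,
    rng: np.random.Generator,
    log: MeiosisLog | None = None,
) -> PackedGamete:
    """Assemble a founder gamete as a crossover mosaic of panel haplotypes."""
    if panel.n_haplotypes == 0:
        raise ValueError("empty haplotype panel")
    breaks = _crossover_site_breakpoints(
        panel.chromosome, panel.positions, panel.n_sites, model, rng, log
    )
    n_seg = breaks.size + 1
    sources = rng.integers(panel.n_haplotypes, size=n_seg)
    bits = np.empty(panel.n_sites, dtype=np.uint8)
    bounds = [0, *breaks.tolist(), panel.n_sites]
    for k in range(n_seg):
        lo, hi = bounds[k], bounds[k + 1]
        bits[lo:hi] = panel.alleles[sources[k], lo:hi]
    return PackedGamete(panel.n_sites, pack_bits(bits))


def meiosis(
    parent: DiploidGenome,
    chrom_index: int,
    chrom: ChromosomeSpec,
    positions: np.ndarray,
    model: RecombinationModel,
    rng: np.random.Generator,
    log: MeiosisLog | None = None,
) -> PackedGamete:
    """One meiosis on one chromosome: recombine the parent's two gametes
    with a fair-coin starting strand."""
    pat = parent.paternal[chrom_index]
    mat = parent.maternal[chrom_index]
    out = np.zeros_like(pat.words)
    _meiosis_words(
        pat.words, mat.words, pat.n_sites, chrom, positions, model, rng, out, log
    )
    return PackedGamete(pat.n_sites, out)


def _meiosis_words(
    wa: np.ndarray,
    wb: np.ndarray,
    n_sites: int,
    chrom: ChromosomeSpec,
    positions: np.ndarray,
    model: RecombinationModel,
    rng: np.random.Generator,
    out: np.ndarray,
    log: MeiosisLog | None,
) -> None:
    breaks = _crossover_site_breakpoints(chrom, positions, n_sites, model, rng, log)
    start = int(rng.integers(2))
    if breaks.size == 0:
        np.copyto(out, wa if start == 0 else wb)
        return
    recombine_words(wa, wb, n_sites, breaks.tolist(), start, out=out)


def drop(
    pedigree: Pedigree,
    panels: list[HaplotypePanel],
    model: RecombinationModel,
    rng: np.random.Generator,
) -> PopulationGenomes:
    """Drop panel haplotypes through the pedigree.

    Base individuals get two independent founder gametes per chromosome;
    everyone else gets one meiosis product from each parent (paternal
    gamete from the sire, maternal from the dam), in pedigree order.
    """
    row_of = pedigree.index_of()
    log = MeiosisLog()
    chroms: list[ChromosomeGenomes] = []
    n_ind = len(pedigree)
    for panel in panels:
        n_words = -(-panel.n_sites // WORD_WIDTH)
        words = np.zeros((n_ind, 2, max(n_words, 1)), dtype=np.uint64)
        if n_words == 0:
            words = np.zeros((n_ind, 2, 0), dtype=np.uint64)
        chroms.append(
            ChromosomeGenomes(
                chromosome=panel.chromosome,
                positions=panel.positions,
                n_sites=panel.n_sites,
                words=words,
            )
        )
    for i, ind in enumerate(pedigree):
        if ind.sire_id == 0 and ind.dam_id == 0:
            for c, panel in enumerate(panels):
                for which in (PATERNAL, MATERNAL):
                    g = make_base_gamete(panel, model, rng, log=log)
                    chroms[c].words[i, which] = g.words
        else:
            if ind.sire_id not in row_of or ind.dam_id not in row_of:
                raise RuntimeError(
                    f"individual {ind.id}: parent genome missing (ordering violation)"
                )
            sire_row = row_of[ind.sire_id]
            dam_row = row_of[ind.dam_id]
            for c, panel in enumerate(panels):
                cg = chroms[c]
                for which, prow in ((PATERNAL, sire_row), (MATERNAL, dam_row)):
                    _meiosis_words(
                        cg.words[prow, 0],
                        cg.words[prow, 1],
                        cg.n_sites,
                        cg.chromosome,
                        cg.positions,
                        model,
                        rng,
                        cg.words[i, which],
                        log,
                    )
    return PopulationGenomes(pedigree=pedigree, chromosomes=chroms, meiosis_log=log)
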