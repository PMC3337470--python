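"""Sampling of SNP-chip site sets and candidate-QTL site sets.

Chips are uniform samples (without replacement) of segregating sites at a
configured total density, allocated across chromosomes proportionally to
their site counts.  Candidate QTL come in two flavours: an unrestricted
uniform sample, and a sample restricted to sites whose base-generation
minor allele frequency does not exceed a threshold.  No exclusivity
between chips and QTL sets is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_drop import PopulationGenomes

__all__ = [
    "SitePanelIndex",
    "ChipSpec",
    "QTLSet",
    "maf",
    "build_site_index",
    "sample_chips",
    "sample_candidate_qtl",
    "genotype_dosage",
]


@dataclass(frozen=True)
class ChipSpec:
    name: str
    density: int  # total SNP count across the genome

    def __post_init__(self) -> None:
        if self.density < 1:
            raise ValueError("chip density must be >= 1")


@dataclass
class SitePanelIndex:
    """Global index over every segregating site of the genome.

    Global site ids number sites 0..total-1 in (chromosome, position)
    order.  ``frequency`` is the derived-allele frequency among the base
    generation's gametes (the population the variance scaling sees).
    """

    chrom_index: np.ndarray  # per site, 1-based chromosome number
    positions: np.ndarray  # per site, 1-based bp
    frequency: np.ndarray  # per site, derived-allele frequency in base generation
    sites_per_chrom: np.ndarray  # site count per chromosome

    @property
    def n_sites(self) -> int:
        return self.positions.size

    def chrom_slice(self, c: int) -> slice:
        """Global-id slice of chromosome c (0-based position in the genome list)."""
        offsets = np.concatenate([[0], np.cumsum(self.sites_per_chrom)])
        return slice(int(offsets[c]), int(offsets[c + 1]))


@dataclass
class QTLSet:
    site_ids: np.ndarray  # global ids, sorted
    maf_threshold: float | None

    @property
    def n_sites(self) -> int:
        return self.site_ids.size


def maf(freq):
    """Minor allele frequency: min(f, 1 - f); scalar or array."""
    arr = np.asarray(freq, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("allele frequency must lie in [0, 1]")
    out = np.minimum(arr, 1.0 - arr)
    return float(out) if np.isscalar(freq) or arr.ndim == 0 else out


def build_site_index(genomes: PopulationGenomes) -> SitePanelIndex:
    """Index all sites with base-generation allele frequencies."""
    base_rows = [
        i for i, ind in enumerate(genomes.pedigree) if ind.generation == 0
    ]
    chrom_idx, positions, freqs, counts = [], [], [], []
    for cg in genomes.chromosomes:
        counts.append(cg.n_sites)
        chrom_idx.append(np.full(cg.n_sites, cg.chromosome.index, dtype=np.int64))
        positions.append(cg.positions)
        if cg.n_sites == 0:
            freqs.append(np.zeros(0))
            continue
        total = np.zeros(cg.n_sites, dtype=np.int64)
        for row in base_rows:
            total += cg.bits(row, 0)
            total += cg.bits(row, 1)
        freqs.append(total / (2.0 * len(base_rows)))
    return SitePanelIndex(
        chrom_index=np.concatenate(chrom_idx) if chrom_idx else np.zeros(0, np.int64),
        positions=np.concatenate(positions) if positions else np.zeros(0, np.int64),
        frequency=np.concatenate(freqs) if freqs else np.zeros(0),
        sites_per_chrom=np.array(counts, dtype=np.int64),
    )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    quotas = total * weights / weights.sum()
    alloc = np.floor(quotas).astype(np.int64)
    short = total - int(alloc.sum())
    if short:
        order = np.argsort(-(quotas - alloc), kind="stable")  # ties: lower index first
        alloc[order[:short]] += 1
    return alloc


def sample_chips(
    index: SitePanelIndex,
    chips: list[ChipSpec],
    rng: np.random.Generator,
    nested: bool = False,
) -> dict[str, np.ndarray]:
    """Sample each chip's global site ids (sorted by genome position).

    Chips are independent uniform samples without replacement unless
    ``nested`` is set, in which case each chip is a subsample of the next
    denser one.
    """
    for chip in chips:
        if chip.density > index.n_sites:
            raise ValueError(
                f"chip {chip.name!r} density {chip.density} exceeds "
                f"{index.n_sites} available segregating sites"
            )
    out: dict[str, np.ndarray] = {}
    if nested:
        ordered = sorted(chips, key=lambda c: -c.density)
        pool = _chip_sample(index, ordered[0].density, rng)
        out[ordered[0].name] = pool
        for chip in ordered[1:]:
            sub = rng.choice(pool, size=chip.density, replace=False)
            pool = np.sort(sub)
            out[chip.name] = pool
        return out
    for chip in chips:
        out[chip.name] = _chip_sample(index, chip.density, rng)
    return out


def _chip_sample(
    index: SitePanelIndex, density: int, rng: np.random.Generator
) -> np.ndarray:
    nonzero = index.sites_per_chrom > 0
    alloc = np.zeros_like(index.sites_per_chrom)
    alloc[nonzero] = _largest_remainder(
        density, index.sites_per_chrom[nonzero].astype(float)
    )
    over = alloc > index.sites_per_chrom
    if np.any(over):
        # proportional quota exceeded a chromosome's supply; clamp and
        # redistribute the shortfall among the others
        alloc = np.minimum(alloc, index.sites_per_chrom)
        deficit = density - int(alloc.sum())
        while deficit > 0:
            room = index.sites_per_chrom - alloc
            open_ = room > 0
            add = _largest_remainder(
                min(deficit, int(room.sum())), room[open_].astype(float)
            )
            alloc[open_] += np.minimum(add, room[open_])
            deficit = density - int(alloc.sum())
    ids = []
    offset = 0
    for c, n_c in enumerate(index.sites_per_chrom):
        k = int(alloc[c])
        if k:
            picks = rng.choice(int(n_c), size=k, replace=False) + offset
            ids.append(np.sort(picks))
        offset += int(n_c)
    return np.concatenate(ids) if ids else np.zeros(0, dtype=np.int64)


def sample_candidate_qtl(
    index: SitePanelIndex,
    n: int,
    maf_threshold: float | None,
    rng: np.random.Generator,
) -> QTLSet:
    """Uniform sample of candidate-QTL sites, optionally MAF-restricted.

    The restriction is inclusive: sites with MAF <= threshold are eligible.
    """
    if maf_threshold is not None and not (0 < maf_threshold <= 0.5):
        raise ValueError("maf_threshold must lie in (0, 0.5]")
    if maf_threshold is None:
        eligible = np.arange(index.n_sites, dtype=np.int64)
    else:
        eligible = np.flatnonzero(maf(index.frequency) <= maf_threshold)
    if n > eligible.size:
        raise ValueError(
            f"requested {n} candidate QTL but only {eligible.size} eligible sites"
        )
    picks = rng.choice(eligible, size=n, replace=False)
    return QTLSet(site_ids=np.sort(picks), maf_threshold=maf_threshold)


def genotype_dosage(
    genomes: PopulationGenomes, index: SitePanelIndex, site_ids: np.ndarray
) -> np.ndarray:
    """Individuals x sites matrix of derived-allele counts (0/1/2)."""
    site_ids = np.asarray(site_ids, dtype=np.int64)
    if site_ids.size and (site_ids.min() < 0 or site_ids.max() >= index.n_sites):
        raise KeyError("unknown global site id")
    n_ind = genomes.n_individuals
    out = np.empty((n_ind, site_ids.size), dtype=np.int8)
    col = 0
    for c, cg in enumerate(genomes.chromosomes):
        sl = index.chrom_slice(c)
        mask = (site_ids >= sl.start) & (site_ids < sl.stop)
        if not np.any(mask):
            continue
        local = site_ids[mask] - sl.start
        sub = cg.dosage(local)
        out[:, np.flatnonzero(mask)] = sub
        col += local.size
    return out
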