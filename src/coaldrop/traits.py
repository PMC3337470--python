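"""Additive trait models: effects, breeding values, heritability scaling.

Four default traits span the {normal, gamma} x {unrestricted,
MAF-restricted} grid: PolyUnres, GammaUnres, PolyRes, GammaRes.  Normal
traits place a N(0, 1) allele-substitution effect at every candidate
locus; gamma traits draw |effect| ~ Gamma(shape, scale) at a uniform
subset of loci with a fair sign flip.  The residual standard deviation of
each trait is scaled against the base generation's genetic variance,
computed by the uncentered sum of squares a'a/(n-1), so the configured
heritability sigma_a^2 / (sigma_a^2 + sigma_e^2) holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gene_drop import PopulationGenomes
from .markers_qtl import QTLSet, SitePanelIndex, genotype_dosage

__all__ = [
    "TraitSpec",
    "TraitModel",
    "DEFAULT_TRAITS",
    "sample_effects",
    "breeding_values",
    "base_genetic_variance",
    "residual_sd",
    "phenotypes",
    "build_trait",
    "build_four_traits",
]


@dataclass(frozen=True)
class TraitSpec:
    """Configuration of one additive trait."""

    name: str
    qtl_source: str  # "unrestricted" | "restricted"
    effect_distribution: str  # "normal" | "gamma"
    n_effect_loci: int | None  # None = all candidate loci
    heritability: float
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66

    def __post_init__(self) -> None:
        if self.qtl_source not in ("unrestricted", "restricted"):
            raise ValueError(f"unknown qtl_source {self.qtl_source!r}")
        if self.effect_distribution not in ("normal", "gamma"):
            raise ValueError(f"unknown effect distribution {self.effect_distribution!r}")
        if not (0 < self.heritability < 1):
            raise ValueError("heritability must lie in (0, 1)")
        if self.n_effect_loci is not None and self.n_effect_loci < 1:
            raise ValueError("n_effect_loci must be >= 1")
        if self.effect_distribution == "gamma" and (
            self.gamma_shape <= 0 or self.gamma_scale <= 0
        ):
            raise ValueError("gamma shape and scale must be positive")


#: The default four-trait panel: h^2 = 0.25, gamma(0.4, 1.66), 900-locus
#: gamma subsets.  Fixed order — effect and residual draws consume the
#: trait RNG stream in this order, so runs are bit-reproducible.
DEFAULT_TRAITS = (
    TraitSpec("PolyUnres", "unrestricted", "normal", None, 0.25),
    TraitSpec("GammaUnres", "unrestricted", "gamma", 900, 0.25),
    TraitSpec("PolyRes", "restricted", "normal", None, 0.25),
    TraitSpec("GammaRes", "restricted", "gamma", 900, 0.25),
)


@dataclass
class TraitModel:
    """A realized trait: loci, effects and the fitted noise scale."""

    spec: TraitSpec
    loci: np.ndarray  # global site ids carrying nonzero effects, sorted
    effects: np.ndarray  # allele-substitution effect per locus
    base_genetic_variance: float
    residual_sd: float

    @property
    def configured_h2(self) -> float:
        va = self.base_genetic_variance
        return va / (va + self.residual_sd**2)


def sample_effects(
    spec: TraitSpec, qtl: QTLSet, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw effect loci and allele-substitution effects for one trait.

    Normal traits use every candidate locus; gamma traits use a uniform
    subset of ``n_effect_loci`` loci (loci outside the subset carry no
    effect and are not listed).
    """
    if spec.effect_distribution == "normal":
        loci = qtl.site_ids.copy()
        effects = rng.normal(0.0, 1.0, size=loci.size)
        return loci, effects
    n = spec.n_effect_loci if spec.n_effect_loci is not None else qtl.n_sites
    if n > qtl.n_sites:
        raise ValueError(
            f"trait {spec.name!r}: subset of {n} loci exceeds "
            f"candidate set of {qtl.n_sites}"
        )
    order = np.sort(rng.choice(qtl.n_sites, size=n, replace=False))
    loci = qtl.site_ids[order]
    magnitude = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=n)
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    return loci, magnitude * signs


def breeding_values(dosage: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """a_i = sum_j dosage_ij * effect_j."""
    return np.asarray(dosage, dtype=np.float64) @ np.asarray(effects, dtype=np.float64)


def base_genetic_variance(a_base: np.ndarray) -> float:
    """Uncentered base-generation genetic variance a'a/(n-1)."""
    a = np.asarray(a_base, dtype=np.float64)
    if a.size < 2:
        raise ValueError("need at least 2 base individuals")
    return float(a @ a) / (a.size - 1)


def residual_sd(var_a: float, h2: float) -> float:
    """sigma_e making sigma_a^2/(sigma_a^2 + sigma_e^2) equal h^2 exactly."""
    if var_a <= 0:
        raise ValueError("no genetic variance to scale against")
    if not (0 < h2 < 1):
        raise ValueError("heritability must lie in (0, 1)")
    return math.sqrt(var_a * (1.0 - h2) / h2)


def phenotypes(
    a: np.ndarray, sigma_e: float, rng: np.random.Generator
) -> np.ndarray:
    """y_i = a_i + e_i with e_i ~ N(0, sigma_e^2)."""
    if sigma_e < 0:
        raise ValueError("residual sd must be non-negative")
    a = np.asarray(a, dtype=np.float64)
    return a + rng.normal(0.0, sigma_e, size=a.size) if sigma_e else a.copy()


def build_trait(
    spec: TraitSpec,
    qtl: QTLSet,
    genomes: PopulationGenomes,
    index: SitePanelIndex,
    base_rows: np.ndarray,
    rng: np.random.Generator,
) -> tuple[TraitModel, np.ndarray, np.ndarray]:
    """Realize one trait: model plus per-individual (a, y) in pedigree order."""
    loci, effects = sample_effects(spec, qtl, rng)
    dosage = genotype_dosage(genomes, index, loci)
    a = breeding_values(dosage, effects)
    var_a = base_genetic_variance(a[base_rows])
    sd_e = residual_sd(var_a, spec.heritability)
    y = phenotypes(a, sd_e, rng)
    model = TraitModel(
        spec=spec,
        loci=loci,
        effects=effects,
        base_genetic_variance=var_a,
        residual_sd=sd_e,
    )
    return model, a, y


def build_four_traits(
    unrestricted: QTLSet,
    restricted: QTLSet,
    genomes: PopulationGenomes,
    index: SitePanelIndex,
    rng: np.random.Generator,
    specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS,
) -> dict[str, tuple[TraitModel, np.ndarray, np.ndarray]]:
    """Build the full trait panel in its documented fixed order."""
    base_rows = np.array(
        [i for i, ind in enumerate(genomes.pedigree) if ind.generation == 0],
        dtype=np.int64,
    )
    sources = {"unrestricted": unrestricted, "restricted": restricted}
    out: dict[str, tuple[TraitModel, np.ndarray, np.ndarray]] = {}
    for spec in specs:
        out[spec.name] = build_trait(
            spec, sources[spec.qtl_source], genomes, index, base_rows, rng
        )
    return out
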