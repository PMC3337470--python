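"""Validation summary statistics, recomputable from output files alone."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent import HaplotypePanel

__all__ = [
    "count_segregating",
    "realized_heritability",
    "crossover_rate_estimate",
    "RunReport",
    "report_from_dir",
]


def count_segregating(panels: list[HaplotypePanel]) -> tuple[list[int], int]:
    """Per-chromosome and total segregating-site counts."""
    per = [p.n_sites for p in panels]
    return per, sum(per)


def realized_heritability(a: np.ndarray, y: np.ndarray) -> float:
    """Centered sample var(a)/var(y) — the audit counterpart of the
    uncentered scaling formula used to construct the traits."""
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    if a.size < 2 or y.size != a.size:
        raise ValueError("need >= 2 paired observations")
    vy = y.var(ddof=1)
    if vy == 0:
        return 0.0
    return float(a.var(ddof=1) / vy)


def crossover_rate_estimate(
    n_crossovers: int, total_cm: float
) -> float:
    """Crossover events per cM over all logged meioses."""
    if total_cm <= 0:
        raise ValueError("no meioses logged")
    return n_crossovers / total_cm


@dataclass
class RunReport:
    """Scenario audit figures, all recomputed from a run's output files."""

    sites_per_chrom: list[int] = field(default_factory=list)
    total_sites: int = 0
    chip_sizes: dict[str, int] = field(default_factory=dict)
    qtl_sizes: dict[str, int] = field(default_factory=dict)
    qtl_max_maf: dict[str, float] = field(default_factory=dict)
    configured_h2: dict[str, float] = field(default_factory=dict)
    base_genetic_variance: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)
    realized_h2_base: dict[str, float] = field(default_factory=dict)
    mean_crossovers_per_meiosis: float = 0.0
    split_sizes: dict[str, int] = field(default_factory=dict)
    pedigree_size: int = 0

    def to_text(self) -> str:
        lines = ["metric\tkey\tvalue"]
        lines.append(f"pedigree_size\t-\t{self.pedigree_size}")
        for c, s in enumerate(self.sites_per_chrom, start=1):
            lines.append(f"segregating_sites\tchr{c}\t{s}")
        lines.append(f"segregating_sites\ttotal\t{self.total_sites}")
        for name, v in self.chip_sizes.items():
            lines.append(f"chip_sites\t{name}\t{v}")
        for name, v in self.qtl_sizes.items():
            lines.append(f"qtl_sites\t{name}\t{v}")
        for name, v in self.qtl_max_maf.items():
            lines.append(f"qtl_max_maf\t{name}\t{v:.6f}")
        for name, v in self.configured_h2.items():
            lines.append(f"configured_h2\t{name}\t{v:.12f}")
        for name, v in self.base_genetic_variance.items():
            lines.append(f"base_genetic_variance\t{name}\t{v:.6f}")
        for name, v in self.residual_sd.items():
            lines.append(f"residual_sd\t{name}\t{v:.6f}")
        for name, v in self.realized_h2_base.items():
            lines.append(f"realized_h2_base\t{name}\t{v:.6f}")
        lines.append(
            f"mean_crossovers_per_meiosis\t-\t{self.mean_crossovers_per_meiosis:.6f}"
        )
        for name, v in self.split_sizes.items():
            lines.append(f"split_size\t{name}\t{v}")
        return "\n".join(lines) + "\n"


def report_from_dir(outdir: str | Path) -> RunReport:
    """Rebuild a :class:`RunReport` by reading a run's output files.

    No in-memory state from the run is used, so any output directory can
    be audited post hoc.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    rep = RunReport()

    ped_lines = (outdir / "pedigree.txt").read_text().splitlines()[1:]
    gen_of: dict[int, int] = {}
    base_ids = []
    for ln in ped_lines:
        parts = ln.split("\t")
        gen_of[int(parts[0])] = int(parts[4])
        if int(parts[4]) == 0:
            base_ids.append(int(parts[0]))
    rep.pedigree_size = len(ped_lines)

    sites = manifest.get("sites_per_chromosome", [])
    rep.sites_per_chrom = list(sites)
    rep.total_sites = int(sum(sites))

    for path in sorted(outdir.glob("chip_*.map")):
        name = path.stem[len("chip_"):]
        rep.chip_sizes[name] = len(path.read_text().splitlines()) - 1
    for path in sorted(outdir.glob("qtl_*.map")):
        name = path.stem[len("qtl_"):]
        rows = [ln.split("\t") for ln in path.read_text().splitlines()[1:]]
        rep.qtl_sizes[name] = len(rows)
        if rows:
            freqs = np.array([float(r[4]) for r in rows])
            rep.qtl_max_maf[name] = float(np.minimum(freqs, 1 - freqs).max())

    for path in sorted(outdir.glob("trait_*.txt")):
        name = path.stem[len("trait_"):]
        rows = [ln.split("\t") for ln in path.read_text().splitlines()[1:]]
        ids = np.array([int(r[0]) for r in rows])
        a = np.array([float(r[2]) for r in rows])
        y = np.array([float(r[3]) for r in rows])
        base_mask = np.array([gen_of[i] == 0 for i in ids])
        va = float(a[base_mask] @ a[base_mask]) / (base_mask.sum() - 1)
        sd_e = float(manifest["traits"][name]["residual_sd"])
        rep.base_genetic_variance[name] = va
        rep.residual_sd[name] = sd_e
        rep.configured_h2[name] = va / (va + sd_e**2)
        rep.realized_h2_base[name] = realized_heritability(a[base_mask], y[base_mask])

    log = manifest.get("meiosis_log", {})
    if log.get("n_meioses"):
        rep.mean_crossovers_per_meiosis = log["n_crossovers"] / log["n_meioses"]

    for path in sorted(outdir.glob("split_*.txt")):
        name = path.stem[len("split_"):]
        rep.split_sizes[name] = len(path.read_text().splitlines()) - 1
    return rep
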