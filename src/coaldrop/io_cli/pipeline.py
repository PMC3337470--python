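"""Pipeline orchestration and output writers.

``run`` executes demography -> coalescent (or ms read) -> pedigree ->
gene drop -> marker/QTL sampling -> traits -> split -> writers, and drops
a ``manifest.json`` recording the master seed plus row/column counts for
every file written.  All outputs are tab-delimited text with a header
line; coordinates are 1-based bp and dosages count the derived allele.

The ``scale`` knob shrinks every chromosome's physical length (and the
chip densities, proportionally) for desk-scale runs; pedigree, QTL count
and traits are untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .._rng import substream
from ..coalescent import ChromosomeSpec, HaplotypePanel, read_ms_panel, simulate_panel
from ..gene_drop import MATERNAL, PATERNAL, PopulationGenomes, RecombinationModel, drop
from ..markers_qtl import (
    ChipSpec,
    QTLSet,
    SitePanelIndex,
    build_site_index,
    genotype_dosage,
    maf,
    sample_candidate_qtl,
    sample_chips,
)
from ..pedigree import Pedigree, generate_pedigree, read_pedigree
from ..traits import build_four_traits
from .specfile import SimulationSpec, SplitConfig, format_spec

__all__ = ["run", "write_split", "export_vcf", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def write_split(
    pedigree: Pedigree,
    split: SplitConfig,
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    """Training/validation id lists per the split configuration.

    Training takes every individual of the training generations;
    each validation set is a uniform sample without replacement of the
    configured size from its generation.
    """
    out: dict[str, list[int]] = {}
    training: list[int] = []
    for g in split.training_generations:
        members = pedigree.generation(g)
        if not members:
            raise ValueError(f"training generation {g} is empty")
        training.extend(ind.id for ind in members)
    out["training"] = training
    for g, size in split.validation:
        members = [ind.id for ind in pedigree.generation(g)]
        if size > len(members):
            raise ValueError(
                f"validation sample of {size} exceeds generation {g} "
                f"size {len(members)}"
            )
        picks = rng.choice(len(members), size=size, replace=False)
        out[f"validation_gen{g}"] = sorted(members[i] for i in picks)
    return out


def _write_table(path: Path, header: list[str], rows) -> tuple[int, int]:
    n_rows = 0
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
            n_rows += 1
    return n_rows, len(header)


def _write_matrix_rows(path: Path, header: list[str], row_iter) -> tuple[int, int]:
    """Rows whose trailing field is a pre-joined numeric block."""
    n_rows = 0
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for prefix, block in row_iter:
            fh.write(prefix)
            fh.write(block)
            fh.write("\n")
            n_rows += 1
    return n_rows, len(header)


def _dosage_block(values: np.ndarray) -> str:
    return "\t".join(map(str, values.tolist()))


def export_vcf(
    genomes: PopulationGenomes,
    index: SitePanelIndex,
    site_ids: np.ndarray,
    path: Path,
    chromosomes: list[ChromosomeSpec],
) -> tuple[int, int]:
    """Phased VCF 4.2 export (REF=A / ALT=T placeholders, GT paternal|maternal)."""
    site_ids = np.asarray(site_ids, dtype=np.int64)
    ids = [ind.id for ind in genomes.pedigree]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coaldrop\n")
        for chrom in chromosomes:
            fh.write(
                f"##contig=<ID={chrom.index},length={chrom.physical_length_bp}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"ind{i}" for i in ids)
            + "\n"
        )
        n_ind = genomes.n_individuals
        written = 0
        for c, cg in enumerate(genomes.chromosomes):
            sl = index.chrom_slice(c)
            local = site_ids[(site_ids >= sl.start) & (site_ids < sl.stop)] - sl.start
            if local.size == 0:
                continue
            pat = np.empty((n_ind, local.size), dtype=np.uint8)
            mat = np.empty((n_ind, local.size), dtype=np.uint8)
            for i in range(n_ind):
                pat[i] = cg.bits(i, PATERNAL)[local]
                mat[i] = cg.bits(i, MATERNAL)[local]
            for j, s in enumerate(local):
                gts = "\t".join(
                    f"{pat[i, j]}|{mat[i, j]}" for i in range(n_ind)
                )
                fh.write(
                    f"{cg.chromosome.index}\t{cg.positions[s]}\t"
                    f"site{sl.start + s}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
                )
                written += 1
    return written, 9 + len(ids)


@_stage("coalescent")
def _make_panels(
    spec: SimulationSpec, chroms: list[ChromosomeSpec], base_dir: Path
) -> list[HaplotypePanel]:
    panels = []
    for chrom in chroms:
        if spec.haplotype_source == "internal":
            rng = substream(spec.seed, "coalescent", chrom.index)
            panels.append(simulate_panel(spec.n_haplotypes, chrom, spec.demography, rng))
        else:
            text = (base_dir / spec.ms_files[chrom.index - 1]).read_text()
            panels.append(read_ms_panel(text, chrom))
    return panels


@_stage("pedigree")
def _make_pedigree(spec: SimulationSpec, base_dir: Path) -> Pedigree:
    if spec.pedigree_source == "internal":
        rng = substream(spec.seed, "pedigree")
        return generate_pedigree(
            spec.n_generations, spec.n_sires, spec.dams_per_sire,
            spec.offspring_per_dam, rng,
        )
    return read_pedigree((base_dir / spec.pedigree_file).read_text())


def run(
    spec: SimulationSpec,
    outdir: str | Path,
    seed: int | None = None,
    base_dir: str | Path | None = None,
) -> Path:
    """Execute the full pipeline; returns the output directory.

    ``seed`` overrides the control file's master seed.  Identical
    spec + seed produce a byte-identical output tree.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_dir = Path(base_dir) if base_dir else Path.cwd()
    if seed is not None:
        spec = type(spec)(**{**spec.__dict__, "seed": seed})

    scaled_bp = max(1, int(round(spec.physical_length_bp * spec.scale)))
    chroms = [
        ChromosomeSpec(i, spec.genetic_length_cm, scaled_bp, spec.mutation_rate)
        for i in range(1, spec.n_chromosomes + 1)
    ]
    chip_specs = [
        ChipSpec(c.name, max(1, int(round(c.density * spec.scale))))
        for c in spec.chips
    ]

    manifest: dict = {"seed": spec.seed, "scale": spec.scale, "files": {}}
    files = manifest["files"]

    panels = _make_panels(spec, chroms, base_dir)
    manifest["sites_per_chromosome"] = [p.n_sites for p in panels]

    pedigree = _make_pedigree(spec, base_dir)

    try:
        genomes = drop(
            pedigree, panels, RecombinationModel(), substream(spec.seed, "gene_drop")
        )
    except Exception as exc:
        raise PipelineError(f"stage 'gene_drop' failed: {exc}") from exc

    try:
        index = build_site_index(genomes)
        chip_sites = sample_chips(
            index, chip_specs, substream(spec.seed, "chips"), nested=spec.nested_chips
        )
        qtl_unres = sample_candidate_qtl(
            index, spec.qtl_count, None, substream(spec.seed, "qtl", 0)
        )
        qtl_res = sample_candidate_qtl(
            index, spec.qtl_count, spec.qtl_maf_threshold, substream(spec.seed, "qtl", 1)
        )
    except Exception as exc:
        raise PipelineError(f"stage 'markers_qtl' failed: {exc}") from exc

    try:
        trait_results = build_four_traits(
            qtl_unres, qtl_res, genomes, index,
            substream(spec.seed, "traits"), specs=spec.traits,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'traits' failed: {exc}") from exc

    try:
        splits = write_split(pedigree, spec.split, substream(spec.seed, "split"))
    except Exception as exc:
        raise PipelineError(f"stage 'split' failed: {exc}") from exc

    # ---- writers -------------------------------------------------------
    (outdir / "spec.txt").write_text(format_spec(spec))
    files["spec.txt"] = {"rows": len(format_spec(spec).splitlines()), "cols": 1}

    files["pedigree.txt"] = dict(zip(("rows", "cols"), _write_table(
        outdir / "pedigree.txt",
        ["id", "sire", "dam", "sex", "generation"],
        ((i.id, i.sire_id, i.dam_id, i.sex, i.generation) for i in pedigree),
    )))

    for name, ids in chip_sites.items():
        path = outdir / f"chip_{name}.map"
        files[path.name] = dict(zip(("rows", "cols"), _write_table(
            path,
            ["chip", "chromosome", "bp", "site_id"],
            ((name, index.chrom_index[s], index.positions[s], s) for s in ids),
        )))

    for qname, qset in (("unrestricted", qtl_unres), ("restricted", qtl_res)):
        path = outdir / f"qtl_{qname}.map"
        files[path.name] = dict(zip(("rows", "cols"), _write_table(
            path,
            ["set", "chromosome", "bp", "site_id", "base_frequency"],
            (
                (qname, index.chrom_index[s], index.positions[s], s,
                 f"{index.frequency[s]:.8f}")
                for s in qset.site_ids
            ),
        )))

    row_ids = [ind.id for ind in pedigree]
    gens = [ind.generation for ind in pedigree]
    for name, ids in chip_sites.items():
        dosage = genotype_dosage(genomes, index, ids)
        path = outdir / f"genotypes_{name}.txt"
        files[path.name] = dict(zip(("rows", "cols"), _write_matrix_rows(
            path,
            ["id"] + [f"site{s}" for s in ids],
            ((f"{row_ids[i]}\t", _dosage_block(dosage[i])) for i in range(len(row_ids))),
        )))
        if spec.write_phased:
            path = outdir / f"phased_{name}.txt"
            files[path.name] = dict(zip(("rows", "cols"), _write_matrix_rows(
                path,
                ["id", "gamete"] + [f"site{s}" for s in ids],
                _phased_rows(genomes, index, ids, row_ids),
            )))

    if spec.write_sequence:
        all_ids = np.arange(index.n_sites, dtype=np.int64)
        path = outdir / "sequence.txt"
        files[path.name] = dict(zip(("rows", "cols"), _write_matrix_rows(
            path,
            ["id", "gamete"] + [f"site{s}" for s in all_ids],
            _phased_rows(genomes, index, all_ids, row_ids),
        )))

    if spec.write_vcf:
        for name, ids in chip_sites.items():
            path = outdir / f"{name}.vcf"
            rows, cols = export_vcf(genomes, index, ids, path, chroms)
            files[path.name] = {"rows": rows, "cols": cols}

    manifest["traits"] = {}
    for tname, (model, a, y) in trait_results.items():
        path = outdir / f"trait_{tname}.txt"
        files[path.name] = dict(zip(("rows", "cols"), _write_table(
            path,
            ["id", "generation", "breeding_value", "phenotype"],
            (
                (row_ids[i], gens[i], f"{a[i]:.8f}", f"{y[i]:.8f}")
                for i in range(len(row_ids))
            ),
        )))
        path = outdir / f"qtl_effects_{tname}.txt"
        files[path.name] = dict(zip(("rows", "cols"), _write_table(
            path,
            ["site_id", "chromosome", "bp", "effect"],
            (
                (s, index.chrom_index[s], index.positions[s], f"{e:.10f}")
                for s, e in zip(model.loci, model.effects)
            ),
        )))
        manifest["traits"][tname] = {
            "heritability": model.spec.heritability,
            "base_genetic_variance": model.base_genetic_variance,
            "residual_sd": model.residual_sd,
            "configured_h2": model.configured_h2,
            "n_effect_loci": int(model.loci.size),
        }

    for sname, ids in splits.items():
        path = outdir / f"split_{sname}.txt"
        files[path.name] = dict(zip(("rows", "cols"), _write_table(
            path,
            ["id", "generation"],
            ((i, pedigree[i].generation) for i in ids),
        )))

    log = genomes.meiosis_log
    manifest["meiosis_log"] = {
        "n_meioses": log.n_meioses,
        "n_crossovers": log.n_crossovers,
        "total_cm": log.total_cm,
    }
    manifest["qtl"] = {
        "unrestricted": int(qtl_unres.n_sites),
        "restricted": int(qtl_res.n_sites),
        "restricted_max_maf": float(np.max(maf(index.frequency[qtl_res.site_ids])))
        if qtl_res.n_sites else 0.0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def _phased_rows(genomes, index, site_ids, row_ids):
    site_ids = np.asarray(site_ids, dtype=np.int64)
    for i, ind_id in enumerate(row_ids):
        for which, label in ((PATERNAL, "P"), (MATERNAL, "M")):
            parts = []
            for c, cg in enumerate(genomes.chromosomes):
                sl = index.chrom_slice(c)
                local = site_ids[(site_ids >= sl.start) & (site_ids < sl.stop)] - sl.start
                if local.size:
                    parts.append(cg.bits(i, which)[local])
            bits = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
            yield f"{ind_id}\t{label}\t", _dosage_block(bits)
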