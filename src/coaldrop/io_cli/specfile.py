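"""The single plain-text control file driving a simulation run.

Grammar: ``[section]`` headers, one ``key = value`` pair per line, ``#``
comments.  Repeatable keys (``ne``, ``chip``, ``trait``, ``validation``)
accumulate.  ``parse_spec`` validates everything up front and reports the
offending key and line; ``format_spec`` emits a normalized form for which
parse -> emit -> parse is a fixpoint.

Example::

    [genome]
    chromosomes = 30
    genetic_length_cm = 100
    physical_length_bp = 100000000
    mutation_rate = 2.5e-8

    [demography]
    ne = 0 100
    ne = 1000 1256
    ne = 10000 4350
    ne = 100000 43500
    generation_interval = 1

    [haplotypes]
    source = internal
    n_haplotypes = 4000

    [pedigree]
    source = internal
    generations = 10
    sires_per_generation = 50
    dams_per_sire = 10
    offspring_per_dam = 2

    [chips]
    chip = SNP60k 60000
    chip = SNP300k 300000
    nested = false

    [qtl]
    count = 9000
    maf_threshold = 0.3

    [traits]
    trait = PolyUnres unrestricted normal all 0.25
    trait = GammaUnres unrestricted gamma:0.4:1.66 900 0.25
    trait = PolyRes restricted normal all 0.25
    trait = GammaRes restricted gamma:0.4:1.66 900 0.25

    [split]
    training_generations = 4 5
    validation = 6:500 8:500 10:500

    [run]
    seed = 1
    scale = 1.0
    write_sequence = false
    write_phased = false
    write_vcf = false
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

from ..demography import NeTrajectory
from ..markers_qtl import ChipSpec
from ..traits import TraitSpec

__all__ = ["SpecError", "SplitConfig", "SimulationSpec", "parse_spec", "format_spec"]


class SpecError(ValueError):
    """Control-file validation error; message names key and line."""


@dataclass(frozen=True)
class SplitConfig:
    training_generations: tuple[int, ...]
    validation: tuple[tuple[int, int], ...]  # (generation, sample size)


@dataclass
class SimulationSpec:
    # genome
    n_chromosomes: int
    genetic_length_cm: float
    physical_length_bp: int
    mutation_rate: float
    # demography
    demography: NeTrajectory
    generation_interval: float
    # haplotype source
    haplotype_source: str  # "internal" | "ms"
    n_haplotypes: int
    ms_files: tuple[str, ...] = ()
    # pedigree
    pedigree_source: str = "internal"  # "internal" | "file"
    n_generations: int = 10
    n_sires: int = 50
    dams_per_sire: int = 10
    offspring_per_dam: int = 2
    pedigree_file: str | None = None
    # chips & qtl
    chips: tuple[ChipSpec, ...] = ()
    nested_chips: bool = False
    qtl_count: int = 9000
    qtl_maf_threshold: float = 0.30
    # traits
    traits: tuple[TraitSpec, ...] = ()
    # split
    split: SplitConfig | None = None
    # run
    seed: int = 1
    scale: float = 1.0
    write_sequence: bool = False
    write_phased: bool = False
    write_vcf: bool = False


_REQUIRED = {
    "genome": ["chromosomes", "genetic_length_cm", "physical_length_bp", "mutation_rate"],
    "demography": ["ne"],
    "haplotypes": ["source"],
    "pedigree": ["source"],
    "chips": ["chip"],
    "qtl": ["count", "maf_threshold"],
    "traits": ["trait"],
    "split": ["training_generations", "validation"],
    "run": ["seed"],
}

_KNOWN_KEYS = {
    "genome": {"chromosomes", "genetic_length_cm", "physical_length_bp", "mutation_rate"},
    "demography": {"ne", "generation_interval"},
    "haplotypes": {"source", "n_haplotypes", "ms_files"},
    "pedigree": {
        "source", "generations", "sires_per_generation", "dams_per_sire",
        "offspring_per_dam", "file",
    },
    "chips": {"chip", "nested"},
    "qtl": {"count", "maf_threshold"},
    "traits": {"trait"},
    "split": {"training_generations", "validation"},
    "run": {"seed", "scale", "write_sequence", "write_phased", "write_vcf"},
}

_REPEATABLE = {("demography", "ne"), ("chips", "chip"), ("traits", "trait")}


def _tokenize(stream: TextIO | str):
    if isinstance(stream, str) and stream and "\n" not in stream:
        try:
            if Path(stream).is_file():
                stream = Path(stream).read_text()
        except OSError:
            pass
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    section = None
    entries: dict[str, list[tuple[str, str, int]]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in _KNOWN_KEYS:
                raise SpecError(f"line {lineno}: unknown section [{section}]")
            entries.setdefault(section, [])
            continue
        if section is None:
            raise SpecError(f"line {lineno}: key outside any [section]")
        if "=" not in line:
            raise SpecError(f"line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _KNOWN_KEYS[section]:
            raise SpecError(f"line {lineno}: unknown key {key!r} in [{section}]")
        if (section, key) not in _REPEATABLE and any(
            k == key for k, _, _ in entries[section]
        ):
            raise SpecError(f"line {lineno}: duplicate key {key!r} in [{section}]")
        entries[section].append((key, value, lineno))
    return entries


def _get(entries, section, key, default=None):
    for k, v, ln in entries.get(section, []):
        if k == key:
            return v, ln
    return default, None


def _get_all(entries, section, key):
    return [(v, ln) for k, v, ln in entries.get(section, []) if k == key]


def _num(value, ln, key, conv, check=None, what=""):
    try:
        out = conv(value)
    except ValueError:
        raise SpecError(f"line {ln}: key {key!r}: cannot parse {value!r}") from None
    if check is not None and not check(out):
        raise SpecError(f"line {ln}: key {key!r}: {value!r} {what}")
    return out


def _bool(value, ln, key):
    token = value.strip().lower()
    if token in ("true", "yes", "1"):
        return True
    if token in ("false", "no", "0"):
        return False
    raise SpecError(f"line {ln}: key {key!r}: expected true/false, got {value!r}")


def parse_spec(stream: TextIO | str, base_dir: str | Path | None = None) -> SimulationSpec:
    """Parse and fully validate a control file (text, stream or path)."""
    entries = _tokenize(stream)

    missing = []
    for section, keys in _REQUIRED.items():
        for key in keys:
            if _get(entries, section, key)[0] is None:
                missing.append(f"[{section}] {key}")
    if missing:
        raise SpecError("missing required key(s): " + ", ".join(missing))

    v, ln = _get(entries, "genome", "chromosomes")
    n_chrom = _num(v, ln, "chromosomes", int, lambda x: x >= 1, "must be >= 1")
    v, ln = _get(entries, "genome", "genetic_length_cm")
    glen = _num(v, ln, "genetic_length_cm", float, lambda x: x > 0, "must be > 0")
    v, ln = _get(entries, "genome", "physical_length_bp")
    plen = _num(v, ln, "physical_length_bp", lambda s: int(float(s)),
                lambda x: x >= 1, "must be >= 1")
    v, ln = _get(entries, "genome", "mutation_rate")
    mu = _num(v, ln, "mutation_rate", float, lambda x: x >= 0, "must be >= 0")

    anchors = []
    for v, ln in _get_all(entries, "demography", "ne"):
        parts = v.split()
        if len(parts) != 2:
            raise SpecError(f"line {ln}: key 'ne': expected 'time Ne', got {v!r}")
        t = _num(parts[0], ln, "ne", float, lambda x: x >= 0, "time must be >= 0")
        s = _num(parts[1], ln, "ne", float, lambda x: x > 0, "Ne must be > 0")
        anchors.append((t, s))
    v, ln = _get(entries, "demography", "generation_interval")
    gen_int = 1.0 if v is None else _num(
        v, ln, "generation_interval", float, lambda x: x > 0, "must be > 0"
    )
    try:
        traj = NeTrajectory.from_anchors(anchors, generation_interval=gen_int)
    except ValueError as exc:
        raise SpecError(f"[demography] ne anchors invalid: {exc}") from None

    v, ln = _get(entries, "haplotypes", "source")
    hap_source = v.strip().lower()
    if hap_source not in ("internal", "ms"):
        raise SpecError(f"line {ln}: key 'source': expected internal|ms, got {v!r}")
    ms_files: tuple[str, ...] = ()
    n_hap = 0
    if hap_source == "internal":
        v, ln = _get(entries, "haplotypes", "n_haplotypes")
        if v is None:
            raise SpecError("missing required key(s): [haplotypes] n_haplotypes")
        n_hap = _num(v, ln, "n_haplotypes", int, lambda x: x >= 2, "must be >= 2")
    else:
        v, ln = _get(entries, "haplotypes", "ms_files")
        if v is None:
            raise SpecError("missing required key(s): [haplotypes] ms_files")
        ms_files = tuple(v.split())
        if len(ms_files) != n_chrom:
            raise SpecError(
                f"line {ln}: key 'ms_files': {len(ms_files)} files for "
                f"{n_chrom} chromosomes"
            )
        root = Path(base_dir) if base_dir else Path.cwd()
        for f in ms_files:
            if not (root / f).exists():
                raise SpecError(f"line {ln}: key 'ms_files': file not found: {f}")

    v, ln = _get(entries, "pedigree", "source")
    ped_source = v.strip().lower()
    if ped_source not in ("internal", "file"):
        raise SpecError(f"line {ln}: key 'source': expected internal|file, got {v!r}")
    ped_file = None
    n_gen, n_sires, dps, opd = 10, 50, 10, 2
    if ped_source == "internal":
        for key, default in [
            ("generations", None), ("sires_per_generation", None),
            ("dams_per_sire", None), ("offspring_per_dam", None),
        ]:
            v, ln = _get(entries, "pedigree", key)
            if v is None:
                raise SpecError(f"missing required key(s): [pedigree] {key}")
        v, ln = _get(entries, "pedigree", "generations")
        n_gen = _num(v, ln, "generations", int, lambda x: x >= 1, "must be >= 1")
        v, ln = _get(entries, "pedigree", "sires_per_generation")
        n_sires = _num(v, ln, "sires_per_generation", int, lambda x: x >= 1, "must be >= 1")
        v, ln = _get(entries, "pedigree", "dams_per_sire")
        dps = _num(v, ln, "dams_per_sire", int, lambda x: x >= 1, "must be >= 1")
        v, ln = _get(entries, "pedigree", "offspring_per_dam")
        opd = _num(v, ln, "offspring_per_dam", int, lambda x: x >= 1, "must be >= 1")
    else:
        v, ln = _get(entries, "pedigree", "file")
        if v is None:
            raise SpecError("missing required key(s): [pedigree] file")
        ped_file = v.strip()
        root = Path(base_dir) if base_dir else Path.cwd()
        if not (root / ped_file).exists():
            raise SpecError(f"line {ln}: key 'file': file not found: {ped_file}")

    chips = []
    names = set()
    for v, ln in _get_all(entries, "chips", "chip"):
        parts = v.split()
        if len(parts) != 2:
            raise SpecError(f"line {ln}: key 'chip': expected 'name density', got {v!r}")
        density = _num(parts[1], ln, "chip", int, lambda x: x >= 1, "density must be >= 1")
        if parts[0] in names:
            raise SpecError(f"line {ln}: key 'chip': duplicate chip name {parts[0]!r}")
        names.add(parts[0])
        chips.append(ChipSpec(parts[0], density))
    v, ln = _get(entries, "chips", "nested")
    nested = False if v is None else _bool(v, ln, "nested")

    v, ln = _get(entries, "qtl", "count")
    qtl_count = _num(v, ln, "count", int, lambda x: x >= 1, "must be >= 1")
    v, ln = _get(entries, "qtl", "maf_threshold")
    qtl_maf = _num(
        v, ln, "maf_threshold", float, lambda x: 0 < x <= 0.5, "must lie in (0, 0.5]"
    )

    trait_specs = []
    tnames = set()
    for v, ln in _get_all(entries, "traits", "trait"):
        parts = v.split()
        if len(parts) != 5:
            raise SpecError(
                f"line {ln}: key 'trait': expected "
                f"'name source dist n_loci h2', got {v!r}"
            )
        name, source, dist_token, n_loci_token, h2_token = parts
        if name in tnames:
            raise SpecError(f"line {ln}: key 'trait': duplicate trait name {name!r}")
        tnames.add(name)
        if source not in ("unrestricted", "restricted"):
            raise SpecError(
                f"line {ln}: key 'trait': source must be unrestricted|restricted"
            )
        shape, scale_ = 0.4, 1.66
        if dist_token == "normal":
            dist = "normal"
        elif dist_token.startswith("gamma"):
            dist = "gamma"
            if ":" in dist_token:
                try:
                    _, shape_s, scale_s = dist_token.split(":")
                    shape, scale_ = float(shape_s), float(scale_s)
                except ValueError:
                    raise SpecError(
                        f"line {ln}: key 'trait': malformed gamma spec {dist_token!r}"
                    ) from None
        else:
            raise SpecError(
                f"line {ln}: key 'trait': distribution must be normal|gamma[:shape:scale]"
            )
        n_loci = None if n_loci_token == "all" else _num(
            n_loci_token, ln, "trait", int, lambda x: x >= 1, "n_loci must be >= 1"
        )
        h2 = _num(h2_token, ln, "trait", float, lambda x: 0 < x < 1,
                  "h2 must lie in (0, 1)")
        try:
            trait_specs.append(
                TraitSpec(name, source, dist, n_loci, h2, shape, scale_)
            )
        except ValueError as exc:
            raise SpecError(f"line {ln}: key 'trait': {exc}") from None
        if n_loci is not None and n_loci > qtl_count:
            raise SpecError(
                f"line {ln}: key 'trait': n_loci {n_loci} exceeds qtl count {qtl_count}"
            )

    v, ln = _get(entries, "split", "training_generations")
    try:
        train_gens = tuple(int(tok) for tok in v.split())
    except ValueError:
        raise SpecError(
            f"line {ln}: key 'training_generations': cannot parse {v!r}"
        ) from None
    v, ln = _get(entries, "split", "validation")
    validation = []
    for tok in v.split():
        if ":" not in tok:
            raise SpecError(
                f"line {ln}: key 'validation': expected gen:size, got {tok!r}"
            )
        g_s, s_s = tok.split(":", 1)
        g = _num(g_s, ln, "validation", int, lambda x: x >= 0, "generation must be >= 0")
        s = _num(s_s, ln, "validation", int, lambda x: x >= 1, "size must be >= 1")
        validation.append((g, s))
    split = SplitConfig(train_gens, tuple(validation))
    if ped_source == "internal":
        referenced = set(train_gens) | {g for g, _ in validation}
        bad = sorted(g for g in referenced if not (0 <= g < n_gen))
        if bad:
            raise SpecError(
                f"[split] references generation(s) {bad} outside 0..{n_gen - 1}"
            )

    v, ln = _get(entries, "run", "seed")
    seed = _num(v, ln, "seed", int, lambda x: x >= 0, "must be >= 0")
    v, ln = _get(entries, "run", "scale")
    scale = 1.0 if v is None else _num(
        v, ln, "scale", float, lambda x: 0 < x <= 1, "must lie in (0, 1]"
    )
    flags = {}
    for key in ("write_sequence", "write_phased", "write_vcf"):
        v, ln = _get(entries, "run", key)
        flags[key] = False if v is None else _bool(v, ln, key)

    return SimulationSpec(
        n_chromosomes=n_chrom,
        genetic_length_cm=glen,
        physical_length_bp=plen,
        mutation_rate=mu,
        demography=traj,
        generation_interval=gen_int,
        haplotype_source=hap_source,
        n_haplotypes=n_hap,
        ms_files=ms_files,
        pedigree_source=ped_source,
        n_generations=n_gen,
        n_sires=n_sires,
        dams_per_sire=dps,
        offspring_per_dam=opd,
        pedigree_file=ped_file,
        chips=tuple(chips),
        nested_chips=nested,
        qtl_count=qtl_count,
        qtl_maf_threshold=qtl_maf,
        traits=tuple(trait_specs),
        split=split,
        seed=seed,
        scale=scale,
        **flags,
    )


def format_spec(spec: SimulationSpec) -> str:
    """Normalized round-trippable control-file text."""
    out = io.StringIO()
    w = out.write
    w("[genome]\n")
    w(f"chromosomes = {spec.n_chromosomes}\n")
    w(f"genetic_length_cm = {spec.genetic_length_cm!r}\n")
    w(f"physical_length_bp = {spec.physical_length_bp}\n")
    w(f"mutation_rate = {spec.mutation_rate!r}\n\n")
    w("[demography]\n")
    for t, s in zip(spec.demography.times, spec.demography.sizes):
        w(f"ne = {t * spec.generation_interval!r} {s!r}\n")
    w(f"generation_interval = {spec.generation_interval!r}\n\n")
    w("[haplotypes]\n")
    w(f"source = {spec.haplotype_source}\n")
    if spec.haplotype_source == "internal":
        w(f"n_haplotypes = {spec.n_haplotypes}\n")
    else:
        w(f"ms_files = {' '.join(spec.ms_files)}\n")
    w("\n[pedigree]\n")
    w(f"source = {spec.pedigree_source}\n")
    if spec.pedigree_source == "internal":
        w(f"generations = {spec.n_generations}\n")
        w(f"sires_per_generation = {spec.n_sires}\n")
        w(f"dams_per_sire = {spec.dams_per_sire}\n")
        w(f"offspring_per_dam = {spec.offspring_per_dam}\n")
    else:
        w(f"file = {spec.pedigree_file}\n")
    w("\n[chips]\n")
    for chip in spec.chips:
        w(f"chip = {chip.name} {chip.density}\n")
    w(f"nested = {str(spec.nested_chips).lower()}\n\n")
    w("[qtl]\n")
    w(f"count = {spec.qtl_count}\n")
    w(f"maf_threshold = {spec.qtl_maf_threshold!r}\n\n")
    w("[traits]\n")
    for t in spec.traits:
        dist = "normal" if t.effect_distribution == "normal" else (
            f"gamma:{t.gamma_shape!r}:{t.gamma_scale!r}"
        )
        n_loci = "all" if t.n_effect_loci is None else str(t.n_effect_loci)
        w(f"trait = {t.name} {t.qtl_source} {dist} {n_loci} {t.heritability!r}\n")
    w("\n[split]\n")
    w(f"training_generations = {' '.join(str(g) for g in spec.split.training_generations)}\n")
    w(f"validation = {' '.join(f'{g}:{s}' for g, s in spec.split.validation)}\n\n")
    w("[run]\n")
    w(f"seed = {spec.seed}\n")
    w(f"scale = {spec.scale!r}\n")
    w(f"write_sequence = {str(spec.write_sequence).lower()}\n")
    w(f"write_phased = {str(spec.write_phased).lower()}\n")
    w(f"write_vcf = {str(spec.write_vcf).lower()}\n")
    return out.getvalue()


def default_scenario_text(seed: int = 1, scale: float = 1.0) -> str:
    """The shipped default scenario: 30 x 100 cM / 1e8 bp chromosomes,
    declining-Ne cattle demography, 4000 haplotypes, 50x10x2 pedigree for
    10 generations, 60k/300k chips, 9000 candidate QTL (MAF cap 0.30),
    four traits at h^2 = 0.25, training on generations 4-5 and validation
    on 500 each from generations 6, 8 and 10."""
    return f"""\
[genome]
chromosomes = 30
genetic_length_cm = 100
physical_length_bp = 100000000
mutation_rate = 2.5e-8

[demography]
ne = 0 100
ne = 1000 1256
ne = 10000 4350
ne = 100000 43500
generation_interval = 1

[haplotypes]
source = internal
n_haplotypes = 4000

[pedigree]
source = internal
generations = 10
sires_per_generation = 50
dams_per_sire = 10
offspring_per_dam = 2

[chips]
chip = SNP60k 60000
chip = SNP300k 300000
nested = false

[qtl]
count = 9000
maf_threshold = 0.3

[traits]
trait = PolyUnres unrestricted normal all 0.25
trait = GammaUnres unrestricted gamma:0.4:1.66 900 0.25
trait = PolyRes restricted normal all 0.25
trait = GammaRes restricted gamma:0.4:1.66 900 0.25

[split]
# generations are 0-based: cohorts 3,4 here are the 4th and 5th bred
# cohorts; validation draws from the 6th, 8th and 10th (labels 5, 7, 9)
training_generations = 3 4
validation = 5:500 7:500 9:500

[run]
seed = {seed}
scale = {scale!r}
write_sequence = false
write_phased = false
write_vcf = false
"""
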