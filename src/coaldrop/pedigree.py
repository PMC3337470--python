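"""Pedigree generation, reading and validation.

The internal generator produces a discrete-generation mammalian-style
design: a base generation of unrelated founders, then each later
generation draws sires and dams without replacement from the previous
generation, mates them disjointly (full-sib families) with no selection.
External pedigrees (id / sire / dam [+ sex], 0 = unknown) are supported
for everything else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "Individual",
    "Pedigree",
    "generate_pedigree",
    "read_pedigree",
    "write_pedigree",
    "validate_pedigree",
]

MALE = "M"
FEMALE = "F"
UNKNOWN_SEX = "U"  # permitted only for non-parents from external files

_SEX_TOKENS = {
    "m": MALE, "M": MALE, "1": MALE, "male": MALE,
    "f": FEMALE, "F": FEMALE, "2": FEMALE, "female": FEMALE,
    "u": UNKNOWN_SEX, "U": UNKNOWN_SEX, "0": UNKNOWN_SEX,
}


@dataclass
class Individual:
    id: int
    sire_id: int  # 0 = unknown / base
    dam_id: int
    sex: str
    generation: int


@dataclass
class Pedigree:
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {ind.id: ind for ind in self.individuals}
        if len(self._by_id) != len(self.individuals):
            raise ValueError("duplicate individual ids")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, ind_id: int) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: int) -> bool:
        return ind_id in self._by_id

    @property
    def n_generations(self) -> int:
        return 1 + max((ind.generation for ind in self.individuals), default=-1)

    def generation(self, g: int) -> list[Individual]:
        return [ind for ind in self.individuals if ind.generation == g]

    def index_of(self) -> dict[int, int]:
        """id -> position in pedigree order (genome-array row index)."""
        return {ind.id: i for i, ind in enumerate(self.individuals)}


def generate_pedigree(
    n_generations: int,
    n_sires: int,
    dams_per_sire: int,
    offspring_per_dam: int,
    rng: np.random.Generator,
) -> Pedigree:
    """Generate the internal discrete-generation pedigree.

    Generation 0 holds ``n_sires * dams_per_sire * offspring_per_dam``
    unrelated founders with alternating sexes.  Each later generation
    samples ``n_sires`` males and ``n_sires * dams_per_sire`` females
    without replacement from the previous generation; every dam is mated
    to exactly one sire and produces ``offspring_per_dam`` offspring with
    random sex (re-drawn if a generation would lack parents of either sex
    for the next one).
    """
    for name, v in [
        ("n_generations", n_generations), ("n_sires", n_sires),
        ("dams_per_sire", dams_per_sire), ("offspring_per_dam", offspring_per_dam),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    gen_size = n_sires * dams_per_sire * offspring_per_dam
    n_dams = n_sires * dams_per_sire
    need_next = n_sires + n_dams
    base_males = -(-gen_size // 2)
    base_females = gen_size // 2
    if n_generations > 1:
        if base_males < n_sires or base_females < n_dams:
            raise ValueError(
                f"base generation of {gen_size} ({base_males} M / {base_females} F) "
                f"cannot supply {n_sires} sires and {n_dams} dams"
            )

    individuals: list[Individual] = []
    next_id = 1
    prev: list[Individual] = []
    for i in range(gen_size):
        ind = Individual(next_id, 0, 0, MALE if i % 2 == 0 else FEMALE, 0)
        individuals.append(ind)
        prev.append(ind)
        next_id += 1

    for g in range(1, n_generations):
        males = [ind for ind in prev if ind.sex == MALE]
        females = [ind for ind in prev if ind.sex == FEMALE]
        if len(males) < n_sires or len(females) < n_dams:
            raise ValueError(
                f"generation {g - 1} has {len(males)} males / {len(females)} females; "
                f"need {n_sires} sires and {n_dams} dams"
            )
        sires = [males[i] for i in rng.choice(len(males), size=n_sires, replace=False)]
        dams = [females[i] for i in rng.choice(len(females), size=n_dams, replace=False)]
        need_parents = g + 1 < n_generations
        for _attempt in range(1000):
            sexes = np.where(rng.random(gen_size) < 0.5, MALE, FEMALE)
            if not need_parents:
                break
            if (sexes == MALE).sum() >= n_sires and (sexes == FEMALE).sum() >= n_dams:
                break
        else:  # pragma: no cover - astronomically unlikely for feasible designs
            raise ValueError(
                f"could not draw sexes for generation {g} supplying "
                f"{n_sires} males and {n_dams} females"
            )
        cur: list[Individual] = []
        i = 0
        for d, dam in enumerate(dams):
            sire = sires[d // dams_per_sire]
            for _ in range(offspring_per_dam):
                ind = Individual(next_id, sire.id, dam.id, str(sexes[i]), g)
                individuals.append(ind)
                cur.append(ind)
                next_id += 1
                i += 1
        prev = cur
    return Pedigree(individuals)


def read_pedigree(stream: TextIO | str) -> Pedigree:
    """Read a whitespace-delimited id / sire / dam [sex] pedigree file.

    Generations are inferred as 1 + max(parent generations); sexes are
    inferred from parental roles when no sex column is present.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows: list[tuple[int, int, int, str | None, int]] = []
    seen: dict[int, int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(f"line {lineno}: expected 3 or 4 columns, got {len(parts)}")
        try:
            ind_id, sire, dam = int(parts[0]), int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer id column") from exc
        if ind_id <= 0:
            raise ValueError(f"line {lineno}: ids must be positive")
        if ind_id in seen:
            raise ValueError(
                f"line {lineno}: duplicate id {ind_id} (first seen line {seen[ind_id]})"
            )
        sex = None
        if len(parts) == 4:
            if parts[3] not in _SEX_TOKENS:
                raise ValueError(f"line {lineno}: unrecognized sex token {parts[3]!r}")
            sex = _SEX_TOKENS[parts[3]]
        for role, pid in (("sire", sire), ("dam", dam)):
            if pid != 0 and pid not in seen:
                raise ValueError(
                    f"line {lineno}: {role} {pid} not defined on an earlier line"
                )
        seen[ind_id] = lineno
        rows.append((ind_id, sire, dam, sex, lineno))

    sires_seen = {r[1] for r in rows if r[1] != 0}
    dams_seen = {r[2] for r in rows if r[2] != 0}
    both = sires_seen & dams_seen
    if both:
        ids = sorted(both)[:5]
        lines = [seen[i] for i in ids]
        raise ValueError(
            f"individual(s) {ids} (line(s) {lines}) appear as both sire and dam"
        )

    generation: dict[int, int] = {}
    individuals = []
    for ind_id, sire, dam, sex, lineno in rows:
        gen = 0
        if sire or dam:
            gen = 1 + max(generation.get(sire, -1), generation.get(dam, -1))
        generation[ind_id] = gen
        if sex is None:
            sex = MALE if ind_id in sires_seen else (
                FEMALE if ind_id in dams_seen else UNKNOWN_SEX
            )
        individuals.append(Individual(ind_id, sire, dam, sex, gen))
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, stream: TextIO | None = None) -> str:
    """Write the 4-column text form (id sire dam sex)."""
    out = io.StringIO()
    for ind in ped:
        out.write(f"{ind.id} {ind.sire_id} {ind.dam_id} {ind.sex}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Return a list of invariant violations (empty iff the pedigree is valid)."""
    violations: list[str] = []
    position = {ind.id: i for i, ind in enumerate(ped.individuals)}
    for i, ind in enumerate(ped.individuals):
        for role, pid in (("sire", ind.sire_id), ("dam", ind.dam_id)):
            if pid == 0:
                continue
            if pid not in position:
                violations.append(f"{ind.id}: {role} {pid} not in pedigree")
                continue
            if position[pid] >= i:
                violations.append(f"{ind.id}: {role} {pid} does not precede it")
            parent = ped[pid]
            if role == "sire" and parent.sex == FEMALE:
                violations.append(f"{ind.id}: sire {pid} is female")
            if role == "dam" and parent.sex == MALE:
                violations.append(f"{ind.id}: dam {pid} is male")
            if parent.generation >= ind.generation:
                violations.append(
                    f"{ind.id}: parent {pid} generation {parent.generation} "
                    f">= own generation {ind.generation}"
                )
        if (ind.sire_id == 0) != (ind.dam_id == 0):
            violations.append(f"{ind.id}: exactly one parent unknown")
    return violations
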