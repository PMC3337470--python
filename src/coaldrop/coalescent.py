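"""Sequential Markovian coalescent with recombination and mutation.

Simulates per-chromosome ancestral haplotype panels: the leftmost marginal
genealogy is built by time-inhomogeneous coalescence under the demography
module, then the simulator walks left-to-right along the sequence.  The
distance to the next recombination breakpoint is exponential in the current
tree's total branch length times the per-bp recombination rate; at each
breakpoint one lineage is detached at a uniformly chosen point on the tree
and re-coalesces with the remaining branches (SMC' by default, so
back-coalescence onto the detached branch — leaving the tree unchanged —
is allowed; plain SMC forbids it).  Mutations are dropped on each marginal
tree over its non-recombining segment at the per-site rate, one segregating
site per mutation.  The full ancestral recombination graph is never
materialized: only the current marginal tree is held in memory.

Also reads and writes ms-dialect haplotype text (segsites / positions /
0-1 rows) so externally simulated panels can be dropped in.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .demography import (
    NeTrajectory,
    cumulative_inverse_ne,
    draw_waiting_time,
    time_for_integral,
)

__all__ = [
    "ChromosomeSpec",
    "HaplotypePanel",
    "simulate_panel",
    "read_ms_panel",
    "write_ms_panel",
    "MsParseError",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical and genetic layout of one chromosome."""

    index: int  # 1-based chromosome number
    genetic_length_cm: float
    physical_length_bp: int
    mutation_rate: float  # per site per generation

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("chromosome index is 1-based")
        if self.genetic_length_cm <= 0:
            raise ValueError("genetic length must be positive")
        if self.physical_length_bp <= 0:
            raise ValueError("physical length must be positive")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be non-negative")

    @property
    def recombination_rate_per_bp(self) -> float:
        """Morgans per base pair (uniform along the chromosome)."""
        return self.genetic_length_cm / 100.0 / self.physical_length_bp


@dataclass
class HaplotypePanel:
    """N phased haplotypes over S segregating sites on one chromosome.

    ``positions`` are strictly increasing 1-based bp coordinates;
    ``alleles`` is an N x S 0/1 matrix (0 = ancestral, 1 = derived) in
    which every column is segregating (0 < column sum < N).
    """

    chromosome: ChromosomeSpec
    positions: np.ndarray  # int64, 1-based bp
    alleles: np.ndarray  # uint8, shape (N, S)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def validate(self) -> None:
        if self.alleles.ndim != 2 or self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions/alleles shape mismatch")
        if self.n_sites:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.chromosome.physical_length_bp:
                raise ValueError("positions outside [1, physical_length]")
            sums = self.alleles.sum(axis=0)
            if np.any(sums <= 0) or np.any(sums >= self.n_haplotypes):
                raise ValueError("non-segregating column in panel")
        if self.alleles.size and (self.alleles.max() > 1 or self.alleles.min() < 0):
            raise ValueError("alleles must be 0/1")


_ROOT_LINEAGE = -2  # sentinel: re-coalescence with the lineage above the root


class LocalTree:
    """Mutable marginal genealogy over n leaves at one sequence position.

    Nodes 0..n-1 are leaves at time 0; slots n..2n-2 hold the n-1 internal
    nodes (slots are reused across SPR updates so the arrays never grow).
    """

    __slots__ = ("n", "parent", "children", "time", "root", "_lens", "_cum")

    def __init__(self, n: int) -> None:
        self.n = n
        size = 2 * n - 1
        self.parent = np.full(size, -1, dtype=np.int64)
        self.children = np.full((size, 2), -1, dtype=np.int64)
        self.time = np.zeros(size, dtype=np.float64)
        self.root = -1
        self._lens: np.ndarray | None = None  # cache, dropped on SPR updates
        self._cum: np.ndarray | None = None

    # -- queries ---------------------------------------------------------

    def edge_lengths(self) -> np.ndarray:
        """Branch length above each node (0 for the root); cached."""
        if self._lens is None:
            lens = np.zeros(self.parent.size, dtype=np.float64)
            has_parent = self.parent >= 0
            lens[has_parent] = (
                self.time[self.parent[has_parent]] - self.time[has_parent]
            )
            self._lens = lens
        return self._lens

    def _cum_lengths(self) -> np.ndarray:
        if self._cum is None:
            self._cum = np.cumsum(self.edge_lengths())
        return self._cum

    def _invalidate(self) -> None:
        self._lens = None
        self._cum = None

    def total_branch_length(self) -> float:
        return float(self._cum_lengths()[-1])

    def leaves_under(self, v: int) -> np.ndarray:
        if v < self.n:
            return np.array([v], dtype=np.int64)
        out = []
        stack = [v]
        children = self.children
        n = self.n
        while stack:
            w = stack.pop()
            if w < n:
                out.append(w)
            else:
                stack.append(int(children[w, 0]))
                stack.append(int(children[w, 1]))
        return np.array(out, dtype=np.int64)

    def height(self) -> float:
        return float(self.time[self.root])

    # -- construction ----------------------------------------------------

    @classmethod
    def simulate(
        cls, n: int, traj: NeTrajectory, rng: np.random.Generator
    ) -> "LocalTree":
        """Standard (single-position) coalescent under Ne(t)."""
        if n < 2:
            raise ValueError("need at least 2 lineages")
        tree = cls(n)
        active = list(range(n))
        t = 0.0
        nxt = n
        while len(active) > 1:
            k = len(active)
            t += draw_waiting_time(traj, t, k * (k - 1) / 2.0, rng)
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            if i < j:
                i, j = j, i
            a = active.pop(i)
            b = active.pop(j)
            tree.time[nxt] = t
            tree.children[nxt] = (a, b)
            tree.parent[a] = nxt
            tree.parent[b] = nxt
            active.append(nxt)
            nxt += 1
        tree.root = active[0]
        return tree

    # -- SPR update (one recombination event) ----------------------------

    def sample_branch_point(self, rng: np.random.Generator) -> tuple[int, float]:
        """Uniform point on the branches: (node below the point, time)."""
        lens = self.edge_lengths()
        cum = self._cum_lengths()
        u = rng.random() * cum[-1]
        v = int(np.searchsorted(cum, u, side="right"))
        t = float(self.time[v] + (u - (cum[v] - lens[v])))
        return v, t

    def _recoalescence(
        self,
        v_cut: int,
        t_r: float,
        traj: NeTrajectory,
        rng: np.random.Generator,
        smc_prime: bool,
    ) -> tuple[int, float]:
        """Time and partner lineage for the floating lineage detached at
        (v_cut, t_r).  Partner is a node id (the edge above it) or
        ``_ROOT_LINEAGE``."""
        n = self.n
        internal_times = np.sort(self.time[n:])
        t_cut_top = float(self.time[self.parent[v_cut]])
        target = rng.exponential()
        # interval boundaries above t_r: internal node times (k drops by one
        # at each), plus the top of the detached branch in plain-SMC mode
        j = int(np.searchsorted(internal_times, t_r, side="right"))
        bounds = np.concatenate(([t_r], internal_times[j:]))
        if not smc_prime and t_r < t_cut_top:
            bounds = np.sort(np.append(bounds, t_cut_top))
        k = n - np.searchsorted(internal_times, bounds[:-1], side="right")
        if not smc_prime:
            k = k - (bounds[:-1] < t_cut_top)
        integral = cumulative_inverse_ne(traj, bounds)
        caps = 0.5 * k * np.diff(integral)
        cum_caps = np.concatenate(([0.0], np.cumsum(caps)))
        if target >= cum_caps[-1]:
            # above the root: a single partner lineage remains
            t_c = time_for_integral(
                traj, float(bounds[-1]), 2.0 * (target - cum_caps[-1])
            )
        else:
            i = int(np.searchsorted(cum_caps, target, side="right")) - 1
            t_c = time_for_integral(
                traj, float(bounds[i]), 2.0 * (target - cum_caps[i]) / float(k[i])
            )
        # choose the partner edge uniformly among edges spanning t_c
        if t_c >= float(self.time[self.root]):
            return _ROOT_LINEAGE, t_c
        has_parent = self.parent >= 0
        spanning = (
            has_parent
            & (self.time <= t_c)
            & (self.time[np.where(has_parent, self.parent, 0)] > t_c)
        )
        if not smc_prime:
            spanning[v_cut] = False
        candidates = np.flatnonzero(spanning)
        partner = int(candidates[rng.integers(candidates.size)])
        return partner, t_c

    def apply_spr(self, v_cut: int, partner: int, t_c: float) -> bool:
        """Re-graft the lineage above ``v_cut`` at (partner, t_c).

        Returns False when the event is a back-coalescence onto the
        detached branch itself (tree unchanged), True otherwise.
        """
        u = v_cut
        p = int(self.parent[u])
        if partner == u:
            return False  # SMC' back-coalescence: marginal tree unchanged
        # splice out p
        s = int(self.children[p, 0]) if int(self.children[p, 1]) == u else int(
            self.children[p, 1]
        )
        g = int(self.parent[p])
        if g == -1:
            self.root = s
            self.parent[s] = -1
        else:
            side = 0 if int(self.children[g, 0]) == p else 1
            self.children[g, side] = s
            self.parent[s] = g
        if partner == p:
            partner = s
        if partner == _ROOT_LINEAGE:
            partner = self.root
        # re-insert node slot p at time t_c on the edge above partner
        h = int(self.parent[partner])
        self.time[p] = t_c
        self.children[p] = (partner, u)
        self.parent[partner] = p
        self.parent[u] = p
        if h == -1:
            self.parent[p] = -1
            self.root = p
        else:
            side = 0 if int(self.children[h, 0]) == partner else 1
            self.children[h, side] = p
            self.parent[p] = h
        self._invalidate()
        return True

    def recombination_event(
        self, traj: NeTrajectory, rng: np.random.Generator, smc_prime: bool = True
    ) -> bool:
        """One SMC(') step: detach at a uniform point, re-coalesce, re-graft."""
        v, t_r = self.sample_branch_point(rng)
        partner, t_c = self._recoalescence(v, t_r, traj, rng, smc_prime)
        return self.apply_spr(v, partner, t_c)


def _place_mutations(
    tree: LocalTree,
    seg_lo: float,
    seg_hi: float,
    mu: float,
    rng: np.random.Generator,
    used: set,
    sites: list,
) -> None:
    """Drop Poisson(mu * seg_len * total_branch_length) mutations on the
    current tree, each creating one segregating site at a uniform integer
    bp coordinate within [seg_lo, seg_hi); coordinate collisions redraw."""
    total = tree.total_branch_length()
    if total <= 0 or seg_hi <= seg_lo:
        return
    n_mut = rng.poisson(mu * (seg_hi - seg_lo) * total)
    if n_mut == 0:
        return
    cum = tree._cum_lengths()
    for _ in range(n_mut):
        v = int(np.searchsorted(cum, rng.random() * total, side="right"))
        pos = None
        for _attempt in range(100):
            cand = int(seg_lo + rng.random() * (seg_hi - seg_lo)) + 1
            if cand not in used:
                pos = cand
                break
        if pos is None:
            continue  # segment's integer coordinates exhausted (tiny chromosomes)
        used.add(pos)
        sites.append((pos, tree.leaves_under(v)))


def simulate_panel(
    n_haplotypes: int,
    chrom: ChromosomeSpec,
    traj: NeTrajectory,
    rng: np.random.Generator,
    smc_prime: bool = True,
) -> HaplotypePanel:
    """Simulate a haplotype panel for one chromosome.

    See the module docstring for the algorithm.  ``smc_prime=False``
    switches to plain SMC (no back-coalescence), used in tests.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    L = float(chrom.physical_length_bp)
    r_bp = chrom.recombination_rate_per_bp
    mu = chrom.mutation_rate
    tree = LocalTree.simulate(n_haplotypes, traj, rng)
    used: set = set()
    sites: list = []
    x = 0.0
    while x < L:
        total = tree.total_branch_length()
        rate = r_bp * total
        dist = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        seg_end = min(x + dist, L)
        _place_mutations(tree, x, seg_end, mu, rng, used, sites)
        if seg_end >= L:
            break
        tree.recombination_event(traj, rng, smc_prime=smc_prime)
        x = seg_end
    sites.sort(key=lambda item: item[0])
    positions = np.array([p for p, _ in sites], dtype=np.int64)
    alleles = np.zeros((n_haplotypes, len(sites)), dtype=np.uint8)
    for col, (_, leaves) in enumerate(sites):
        alleles[leaves, col] = 1
    panel = HaplotypePanel(chromosome=chrom, positions=positions, alleles=alleles)
    panel.validate()
    return panel


# ----------------------------------------------------------------------
# ms-dialect text I/O


class MsParseError(ValueError):
    """Raised on malformed ms-dialect input; message names the line."""


def read_ms_panel(stream: TextIO | str, chrom: ChromosomeSpec) -> HaplotypePanel:
    """Read one ms-style replicate (segsites / positions / 0-1 rows).

    Fractional positions are scaled to 1-based bp (fraction x physical
    length, rounded); coordinate ties are resolved by incrementing to the
    next free coordinate.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    idx = 0
    n_lines = len(lines)
    while idx < n_lines and not lines[idx].startswith("segsites:"):
        idx += 1
    if idx == n_lines:
        raise MsParseError("no 'segsites:' line found")
    seg_line = idx + 1
    try:
        segsites = int(lines[idx].split(":", 1)[1])
    except (IndexError, ValueError) as exc:
        raise MsParseError(f"line {seg_line}: malformed segsites line") from exc
    idx += 1
    if segsites == 0:
        haps = [ln for ln in lines[idx:] if ln.strip()]
        alleles = np.zeros((len(haps), 0), dtype=np.uint8)
        return HaplotypePanel(
            chromosome=chrom,
            positions=np.zeros(0, dtype=np.int64),
            alleles=alleles,
        )
    if idx >= n_lines or not lines[idx].startswith("positions:"):
        raise MsParseError(f"line {idx + 1}: expected 'positions:' line")
    try:
        fracs = [float(tok) for tok in lines[idx].split(":", 1)[1].split()]
    except ValueError as exc:
        raise MsParseError(f"line {idx + 1}: malformed positions line") from exc
    if len(fracs) != segsites:
        raise MsParseError(
            f"line {idx + 1}: {len(fracs)} positions but segsites: {segsites}"
        )
    if any(f < 0 or f > 1 for f in fracs):
        raise MsParseError(f"line {idx + 1}: positions must lie in [0, 1]")
    idx += 1
    L = chrom.physical_length_bp
    positions: list[int] = []
    taken: set[int] = set()
    for f in fracs:
        bp = max(1, int(round(f * L)))
        while bp in taken:
            bp += 1
        if bp > L:
            raise MsParseError("positions overflow the physical length after tie-breaking")
        taken.add(bp)
        positions.append(bp)
    rows = []
    for off, line in enumerate(lines[idx:]):
        if not line.strip():
            continue
        lineno = idx + off + 1
        if set(line) - {"0", "1"}:
            raise MsParseError(f"line {lineno}: non-binary haplotype characters")
        if len(line) != segsites:
            raise MsParseError(
                f"line {lineno}: haplotype length {len(line)} != segsites {segsites}"
            )
        rows.append(np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0"))
    if not rows:
        raise MsParseError("no haplotype rows found")
    order = np.argsort(positions, kind="stable")
    alleles = np.stack(rows)[:, order]
    pos_arr = np.array(positions, dtype=np.int64)[order]
    panel = HaplotypePanel(chromosome=chrom, positions=pos_arr, alleles=alleles)
    return panel


def write_ms_panel(panel: HaplotypePanel, stream: TextIO | None = None) -> str:
    """Write a panel as one ms-style replicate; inverse of read_ms_panel."""
    out = io.StringIO()
    out.write("//\n")
    out.write(f"segsites: {panel.n_sites}\n")
    if panel.n_sites:
        L = panel.chromosome.physical_length_bp
        fracs = " ".join(f"{p / L:.12f}" for p in panel.positions)
        out.write(f"positions: {fracs}\n")
        for row in panel.alleles:
            out.write((row + ord("0")).astype(np.uint8).tobytes().decode("ascii"))
            out.write("\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
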