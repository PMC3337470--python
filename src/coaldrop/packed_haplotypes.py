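"""Bit-packed gamete storage and recombination on packed words.

A gamete is a chromosome-length string of 0/1 alleles stored
little-position-first in 64-bit words.  Recombination copies whole words
between breakpoints and only bit-merges the (at most two per breakpoint)
words that a breakpoint straddles — gametes are never fully unpacked to
perform a crossover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["WORD_WIDTH", "PackedGamete", "pack", "unpack", "unpack_region", "recombine"]

WORD_WIDTH = 64
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class PackedGamete:
    """A fixed-width-word encoding of a binary allele string.

    ``words`` has ``ceil(n_sites / 64)`` entries; bits at positions
    >= ``n_sites`` are zero.
    """

    n_sites: int
    words: np.ndarray  # uint64, little-position-first within each word

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        expected = -(-self.n_sites // WORD_WIDTH)
        if self.words.dtype != np.uint64 or self.words.shape != (expected,):
            raise ValueError(
                f"words must be a uint64 array of length {expected}, "
                f"got {self.words.dtype} shape {self.words.shape}"
            )
        tail = self.n_sites % WORD_WIDTH
        if tail and self.n_sites and int(self.words[-1]) >> tail:
            raise ValueError("bits beyond n_sites must be zero")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PackedGamete):
            return NotImplemented
        return self.n_sites == other.n_sites and bool(
            np.array_equal(self.words, other.words)
        )


def _as_bit_array(alleles) -> np.ndarray:
    if isinstance(alleles, str):
        if alleles and set(alleles) - {"0", "1"}:
            bad = sorted(set(alleles) - {"0", "1"})
            raise ValueError(f"non-binary symbol(s) in allele string: {bad}")
        return np.frombuffer(alleles.encode("ascii"), dtype=np.uint8) - ord("0")
    arr = np.asarray(alleles, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("alleles must be one-dimensional")
    if arr.size and arr.max(initial=0) > 1:
        raise ValueError("alleles must be 0/1")
    return arr


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a 0/1 uint8 array into uint64 words (little-position-first)."""
    n = bits.size
    n_words = -(-n // WORD_WIDTH)
    packed = np.packbits(bits, bitorder="little")
    buf = np.zeros(n_words * 8, dtype=np.uint8)
    buf[: packed.size] = packed
    return buf.view("<u8").astype(np.uint64, copy=False)


def unpack_words(words: np.ndarray, n_sites: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`: return the 0/1 uint8 array."""
    as_bytes = np.ascontiguousarray(words, dtype="<u8").view(np.uint8)
    return np.unpackbits(as_bytes, bitorder="little")[:n_sites]


def pack(alleles) -> PackedGamete:
    """Encode a binary string (or 0/1 array) as a :class:`PackedGamete`."""
    bits = _as_bit_array(alleles)
    return PackedGamete(n_sites=bits.size, words=pack_bits(bits))


def unpack(g: PackedGamete) -> str:
    """Full decode back to a '0'/'1' string; ``unpack(pack(x)) == x``."""
    bits = unpack_words(g.words, g.n_sites)
    return (bits + ord("0")).astype(np.uint8).tobytes().decode("ascii")


def unpack_region(g: PackedGamete, lo: int, hi: int) -> str:
    """Decode only the half-open site range [lo, hi)."""
    if not (0 <= lo <= hi <= g.n_sites):
        raise IndexError(
            f"region [{lo}, {hi}) out of range for {g.n_sites} sites"
        )
    if lo == hi:
        return ""
    w_lo = lo // WORD_WIDTH
    w_hi = -(-hi // WORD_WIDTH)
    bits = unpack_words(g.words[w_lo:w_hi], w_hi * WORD_WIDTH - w_lo * WORD_WIDTH)
    sub = bits[lo - w_lo * WORD_WIDTH : hi - w_lo * WORD_WIDTH]
    return (sub + ord("0")).astype(np.uint8).tobytes().decode("ascii")


def _mask(lo_bit: int, hi_bit: int) -> np.uint64:
    # bits [lo_bit, hi_bit) set
    width = hi_bit - lo_bit
    if width >= WORD_WIDTH:
        return _FULL
    return np.uint64(((1 << width) - 1) << lo_bit)


def recombine_words(
    wa: np.ndarray,
    wb: np.ndarray,
    n_sites: int,
    breakpoints: Sequence[int],
    start_with: int,
    out: np.ndarray | None = None,
    stats: dict | None = None,
) -> np.ndarray:
    """Mosaic of two packed gametes switching source at each breakpoint.

    Word-level core of :func:`recombine`.  Segment boundaries at word
    boundaries (including 0 and n_sites) are pure word copies; only words
    genuinely straddled by a breakpoint are bit-merged.  ``stats`` (if
    given) accumulates the number of bit-merged words under key
    ``"merged_words"``.
    """
    sources = (wa, wb)
    if out is None:
        out = np.zeros_like(wa)
    merged = 0
    bounds = list(breakpoints) + [n_sites]
    cur = start_with
    lo = 0
    for hi in bounds:
        src = sources[cur]
        if lo < hi:
            w0, r0 = divmod(lo, WORD_WIDTH)
            w1, r1 = divmod(hi, WORD_WIDTH)
            if hi == n_sites and r1:
                # trailing bits are zero in both sources: whole-word copy is safe
                w1, r1 = w1 + 1, 0
            if w0 == w1:
                m = _mask(r0, r1)
                out[w0] = (out[w0] & ~m) | (src[w0] & m)
                merged += 1
            else:
                if r0:
                    m = _mask(r0, WORD_WIDTH)
                    out[w0] = (out[w0] & ~m) | (src[w0] & m)
                    merged += 1
                    w0 += 1
                out[w0:w1] = src[w0:w1]
                if r1:
                    m = _mask(0, r1)
                    out[w1] = (out[w1] & ~m) | (src[w1] & m)
                    merged += 1
        lo = hi
        cur ^= 1
    if stats is not None:
        stats["merged_words"] = stats.get("merged_words", 0) + merged
    return out


def recombine(
    a: PackedGamete,
    b: PackedGamete,
    breakpoints: Sequence[int],
    start_with: int = 0,
    stats: dict | None = None,
) -> PackedGamete:
    """Recombine two packed gametes at the given site-index breakpoints.

    Breakpoint ``k`` (0-based, strictly increasing, in (0, n_sites)) means
    sites >= k switch to the other source; ``start_with`` selects the
    source (0 = a, 1 = b) for sites before the first breakpoint.  The
    result equals the naive site-by-site mosaic but touches, at bit level,
    at most two words per breakpoint.
    """
    if a.n_sites != b.n_sites:
        raise ValueError(f"length mismatch: {a.n_sites} != {b.n_sites}")
    if start_with not in (0, 1):
        raise ValueError("start_with must be 0 or 1")
    bps = list(breakpoints)
    if any(y <= x for x, y in zip(bps, bps[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if bps and not (0 < bps[0] and bps[-1] < a.n_sites):
        raise ValueError("breakpoints must lie strictly inside (0, n_sites)")
    words = recombine_words(
        a.words, b.words, a.n_sites, bps, start_with, stats=stats
    )
    return PackedGamete(n_sites=a.n_sites, words=words)
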