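"""Seed-derivation scheme: one master seed, per-stage/per-index substreams.

Every stochastic stage of the pipeline pulls an independent generator via
``substream(master_seed, stage, index)`` so that any stage (e.g. the
coalescent for chromosome 7) can be regenerated in isolation and runs are
bit-reproducible regardless of execution order.
"""

from __future__ import annotations

import numpy as np

#: Fixed stage identifiers.  Do not renumber: output reproducibility
#: depends on this table.
STAGES = {
    "coalescent": 0,
    "pedigree": 1,
    "gene_drop": 2,
    "chips": 3,
    "qtl": 4,
    "traits": 5,
    "split": 6,
}


def substream(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return an independent PCG64 generator for (stage, index)."""
    if stage not in STAGES:
        raise KeyError(f"unknown RNG stage {stage!r}")
    seq = np.random.SeedSequence(master_seed, spawn_key=(STAGES[stage], index))
    return np.random.Generator(np.random.PCG64(seq))
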