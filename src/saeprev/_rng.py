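"""Seed-handling helpers.

Every stochastic entry point in the package takes an integer seed and builds
its generator here, so that whole pipelines are reproducible from one master
seed and individual sub-tasks (e.g. one imputation out of M) can be re-run
in isolation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from_seed", "spawn_seed"]


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; pass through an existing one unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(master_seed: int, counter: int) -> int:
    """Derive a reproducible 31-bit sub-seed from a master seed and a counter.

    Uses a fixed SeedSequence spawn-key scheme so sub-seed ``k`` of master
    ``s`` is always the same integer, independent of how many siblings exist.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(counter),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
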