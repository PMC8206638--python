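"""Deterministic seed derivation.

Every stochastic stage (surrogate construction, graph rewiring, Louvain runs,
synthetic-data generation) receives its own child seed derived from a single
master seed plus a tuple of string/integer keys (stage name, subject id,
timepoint, draw index ...).  The scheme is a plain ``numpy.random.SeedSequence``
with a ``spawn_key`` built from CRC-32 hashes of the keys, so any subject or
stage can be recomputed in isolation with results identical to a full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_ints(keys: tuple) -> tuple[int, ...]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            if k < 0:
                raise ValueError("seed keys must be non-negative integers or strings")
            out.append(int(k))
        else:
            out.append(zlib.crc32(str(k).encode("utf-8")))
    return tuple(out)


def child_seed(master_seed: int, *keys) -> int:
    """Derive a child seed (< 2**31) from a master seed and a key path."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key_ints(keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from the same derivation scheme."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key_ints(keys))
    return np.random.default_rng(ss)
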