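"""Deterministic random-substream derivation.

Every stochastic component draws from its own :class:`numpy.random.Generator`
derived from the master seed plus a stable string label. Labels are hashed
with BLAKE2 so that adding or removing one stream never perturbs the draws of
any other stream, and the mapping is stable across processes and platforms
(unlike the builtin ``hash``).
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(master_seed: int, *labels: object) -> np.random.Generator:
    """Return a generator keyed by ``master_seed`` and a label path."""
    tag = "/".join(str(x) for x in labels).encode("utf-8")
    key = int.from_bytes(hashlib.blake2b(tag, digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))
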