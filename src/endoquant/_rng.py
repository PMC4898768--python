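"""Deterministic random-stream derivation.

One master seed drives every generator in a run.  Each generator draws from
its own named substream so that adding or reordering calls to one generator
never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, stream: str) -> int:
    """A 32-bit child seed derived from (master seed, stream name)."""
    digest = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def derive_rng(master_seed: int, stream: str) -> np.random.Generator:
    """Independent Generator for the named substream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                               spawn_key=(derive_seed(master_seed, stream),))
    )
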