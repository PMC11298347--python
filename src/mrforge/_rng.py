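"""Named random-number streams.

One global integer seed drives every stochastic component. Each component
asks for a stream by name; the name is hashed into the SeedSequence spawn
key, so adding a new named stream never perturbs draws in existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "child_seed"]


def _key(name: str) -> int:
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stream ``name`` under global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name),)))


def child_seed(seed: int, name: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for handing to a sub-component."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name), int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
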