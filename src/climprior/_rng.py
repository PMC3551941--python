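"""Deterministic random substreams.

One global seed expands into independent per-stage / per-species streams by
stable hashing of string keys, so adding a species or reordering stages does
not perturb other draws.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_to_ints(*keys: str | int) -> list[int]:
    out = []
    for k in keys:
        digest = hashlib.sha256(str(k).encode("utf-8")).digest()
        out.append(int.from_bytes(digest[:4], "big"))
    return out


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Generator for (seed, keys); identical inputs give identical streams."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key_to_ints(*keys)))
    return np.random.default_rng(ss)


def subseed(seed: int, *keys: str | int) -> int:
    """A derived scalar seed below 2**31, for APIs that take plain ints."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key_to_ints(*keys)))
    return int(ss.generate_state(1)[0] % (2**31))
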