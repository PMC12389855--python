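"""Deterministic seed fan-out.

One root seed is expanded into named sub-streams (data, init, noise, ...)
via counter-based hashing so that every random draw in a run is
reproducible without storing noise tensors.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK31 = 0x7FFFFFFF


def spawn_seed(root: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from a root seed and a tag path."""
    h = zlib.crc32(repr(int(root)).encode())
    for tag in tags:
        h = zlib.crc32(repr(tag).encode(), h)
    return h & _MASK31


def rng(root: int, *tags: object) -> np.random.Generator:
    """A PCG64 generator keyed on (root, *tags)."""
    return np.random.Generator(np.random.PCG64(spawn_seed(root, *tags)))
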