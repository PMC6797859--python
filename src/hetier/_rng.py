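"""Named, reproducible random substreams.

Every stage of the pipeline draws from a substream derived from a single
integer seed plus a tuple of string/int labels, so no code path touches
numpy's global RNG and the same seed always reproduces the same outputs
regardless of stage execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_ints(parts: tuple) -> tuple[int, ...]:
    out = []
    for part in parts:
        if isinstance(part, (int, np.integer)):
            out.append(int(part) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(part).encode("utf-8")))
    return tuple(out)


def substream(seed: int, *key) -> np.random.Generator:
    """Return a Generator for the substream named by ``key`` under ``seed``.

    The mapping (seed, key) -> stream is stable across processes and numpy
    versions that keep SeedSequence's hashing, and distinct keys give
    statistically independent streams.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_key_ints(key))
    return np.random.default_rng(ss)
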