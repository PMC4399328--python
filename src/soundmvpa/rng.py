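"""Named random substreams derived from one master seed.

Every stochastic stage draws from ``substream(master_seed, *names)`` so a
stage can be re-run in isolation and still produce the numbers it produced
inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """A generator keyed by the master seed and a path of names/indices."""
    spawn_key = tuple(_key(n) if isinstance(n, str) else int(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=spawn_key))
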