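"""Named random substreams.

Every stochastic operation in the package derives its generator from one
master seed plus a short stream name, so stages can be re-run in isolation
with unchanged results and whole runs are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _stream_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(_stream_key(name),))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for code that wants a plain int."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(_stream_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
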