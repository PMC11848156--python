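"""Named random substreams.

Every stage of the pipeline draws from its own substream derived from the
single run seed plus a stage name, so any stage can be re-run in isolation
and reproduce its output exactly.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from the run ``seed``.

    The stage name is folded into the seed sequence via CRC32, so distinct
    stage names give statistically independent streams while the same
    (seed, name) pair always yields the same stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
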