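"""Named random substreams.

Every source of randomness in an experiment descends from a single base
seed through named substreams, so that e.g. changing the task stream
leaves weight initialization untouched.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream ``name`` of the base ``seed``.

    The same (seed, name) pair always yields the same stream; distinct
    names yield statistically independent streams.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
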