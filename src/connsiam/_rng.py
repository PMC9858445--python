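"""Named, reproducible random substreams.

Every source of randomness in the package derives from a single integer run
seed through a named substream, so that e.g. the meta-train/meta-test split
and the parameter initialization never share (or race for) generator state.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of run seed ``seed``.

    The mapping (seed, name) -> stream is stable across processes and
    platforms; distinct names yield statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
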