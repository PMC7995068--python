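"""Named, reproducible random substreams.

Every source of randomness in the package is derived from a single integer
seed plus a tuple of string labels, so that two runs with the same seed are
bit-identical and independent components never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a label path.

    The labels are hashed with CRC32 (stable across processes, unlike
    ``hash``) and folded into a :class:`numpy.random.SeedSequence`.
    """
    keys = [zlib.crc32(n.encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *keys]))
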