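"""Deterministic random-stream derivation.

All randomness in the package flows from a single integer seed.  Stages that
need their own stream derive it with :func:`substream_seed`, which hashes a
stable text label into a spawn key, so re-running one stage in isolation
reproduces exactly the stream it saw inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream_rng"]


def substream_seed(seed: int, label: str) -> int:
    """Derive a child seed (< 2**31) from *seed* and a stage *label*."""
    h = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), h])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def substream_rng(seed: int, label: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for stage *label* under *seed*."""
    return np.random.default_rng(substream_seed(seed, label))
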