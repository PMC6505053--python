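"""Named, reproducible random substreams.

A single user-facing integer seed is split into independent substreams, one
per named operation, so that e.g. regenerating a survey does not perturb the
census draw. Streams are derived with :class:`numpy.random.SeedSequence`
keyed on a stable hash of the stream name.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under ``seed``.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
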