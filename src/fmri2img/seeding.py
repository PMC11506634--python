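"""Named seed substreams.

A single experiment seed is expanded into independent generators for data
generation, model initialisation, masking, sampling, ... so each stage is
reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Derive an independent generator from (seed, names...).

    Deterministic across runs and platforms; distinct name paths give
    statistically independent streams via SeedSequence.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(n.encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


def substream_seed(seed: int, *names: str) -> int:
    """A plain integer seed (< 2^31) derived from a named substream."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
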