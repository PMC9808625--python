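"""Deterministic random-stream derivation.

One master seed drives an analysis; every stochastic component draws from a
child stream derived from the master seed plus string labels (library name,
assay name, purpose).  Labels are hashed with CRC-32, which is stable across
platforms and Python versions, so the same (seed, labels) always yields the
same stream, and different labels yield independent streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master: int, *labels) -> np.random.SeedSequence:
    entropy = [int(master) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(lab).encode("utf8")) for lab in labels]
    return np.random.SeedSequence(entropy)


def child_rng(master: int, *labels) -> np.random.Generator:
    """A :class:`numpy.random.Generator` keyed by master seed and labels."""
    return np.random.default_rng(child_seed(master, *labels))
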