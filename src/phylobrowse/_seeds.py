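"""Deterministic derivation of labelled random streams from one master seed.

Every stochastic operation in the package draws from a stream identified by
a master seed plus a tuple of string/integer labels.  The labels are hashed
with CRC-32 into the entropy pool of a :class:`numpy.random.SeedSequence`,
so streams are reproducible across runs and platforms and independent of
the order in which they are created.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(master_seed: int, *labels) -> np.random.SeedSequence:
    entropy = [int(master_seed) % (2**31)]
    entropy.extend(zlib.crc32(repr(lab).encode("utf8")) for lab in labels)
    return np.random.SeedSequence(entropy)


def spawn_rng(master_seed: int, *labels) -> np.random.Generator:
    """A Generator for the stream identified by ``(master_seed, *labels)``."""
    return np.random.default_rng(child_seed_sequence(master_seed, *labels))


def derived_int_seed(master_seed: int, *labels) -> int:
    """A plain integer seed (< 2**31) for the labelled stream."""
    return int(child_seed_sequence(master_seed, *labels).generate_state(1)[0] % (2**31))
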