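"""Deterministic, order-independent random streams.

Every stochastic component of the pipeline draws from a stream keyed by a
master seed plus a tuple of string/int identifiers (subject, variable,
feature, stage ...).  The key is hashed, so the stream obtained for a given
identifier tuple does not depend on how many other streams were opened
before it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, *keys) -> int:
    """Derive a 63-bit child seed from ``seed`` and a tuple of identifiers."""
    msg = "\x1f".join([str(int(seed)), *map(str, keys)])
    digest = hashlib.blake2b(msg.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") >> 1


def substream(seed: int, *keys) -> np.random.Generator:
    """A :class:`numpy.random.Generator` keyed by ``(seed, *keys)``."""
    return np.random.default_rng(subseed(seed, *keys))
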