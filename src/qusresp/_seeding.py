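"""Deterministic seed derivation.

Every source of randomness in the package flows from one integer master
seed.  Sub-streams are derived from the master seed plus a tuple of string
/ integer tags (a counter-based split), so each operation is reproducible
in isolation and independent of call order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0x7FFFFFFF
    return zlib.crc32(str(tag).encode("utf-8")) & 0x7FFFFFFF


def child_seed(master_seed: int, *tags) -> int:
    """Derive a 31-bit child seed from ``master_seed`` and a tag tuple."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF]
                                + [_tag_to_int(t) for t in tags])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def child_rng(master_seed: int, *tags) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the derived sub-stream."""
    return np.random.default_rng(child_seed(master_seed, *tags))
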