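"""Shared plumbing: logging and seed derivation.

All stage-level randomness flows from a single master seed.  Stage seeds are
derived with a CRC32 of ``"<master>:<label>"`` so that (a) runs are exactly
reproducible, (b) stages do not share RNG streams, and (c) derived seeds stay
below 2**31.
"""

from __future__ import annotations

import logging
import zlib

logger = logging.getLogger("featsieve")
if not logger.handlers:  # library default: stderr, terse
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed in [0, 2**31)."""
    return zlib.crc32(f"{master_seed}:{label}".encode()) & 0x7FFFFFFF
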