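"""Small shared helpers: rounding and seeded substreams."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["round_half_up", "substream"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as printed safety tables do.

    Python's built-in round() uses banker's rounding, which disagrees on
    exact .5 ties (e.g. round(0.25, 1) == 0.2); percentage tables in the
    pharmacovigilance literature round half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible random stream from one global seed.

    Each pipeline stage pulls its own stream keyed by a stable hash of its
    name, so adding or reordering stages never perturbs the draws of the
    others.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
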