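"""Small shared helpers: rounding policy and seed fan-out."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    This is the single rounding policy used anywhere a value is presented
    (class percentages, metric tables); internal computation keeps full
    precision.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from one global seed.

    Uses CRC32 of ``"<seed>:<stage>"`` so every stage is independently
    reproducible from the global seed without sharing a stream.
    """
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)
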