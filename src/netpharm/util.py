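"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(base_seed: int, label: str) -> int:
    """Stable per-stage RNG seed derived from one master seed.

    Hashing the (seed, label) pair keeps stages statistically independent
    and insulated from each other: adding a drug to a run cannot perturb
    another drug's permutation null.  Result fits in 31 bits.
    """
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
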