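"""Deterministic seed fan-out.

Every stochastic component draws its seed from the single top-level seed via
``derive_seed(seed, *tokens)`` — a stable hash of the (seed, tokens) tuple —
so no component ever reads global randomness and any sub-computation can be
reproduced in isolation.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *tokens) -> int:
    """Derive a child seed (< 2**31 - 1) from a parent seed and a token path.

    Stable across processes and platforms (blake2b of the repr of the tuple).
    """
    payload = repr((int(seed),) + tuple(tokens)).encode()
    digest = hashlib.blake2b(payload, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)
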