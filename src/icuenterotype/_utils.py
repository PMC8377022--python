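"""Small shared helpers."""

from __future__ import annotations

import hashlib


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from a single global seed, so toggling
    one stochastic stage never shifts another stage's random stream."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
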