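"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(global_seed: int, *tags) -> int:
    """Deterministically split a global seed by a tag tuple.

    Hashes ``(global_seed, *tags)`` with SHA-256 and folds the digest into
    a non-negative 31-bit integer, so every (subject, stage) pair gets an
    independent, reproducible stream.
    """
    key = repr((int(global_seed),) + tuple(tags)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
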