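"""Deterministic child-seed derivation.

A single master seed fans out to every stochastic stage (subset draws,
CV fold shuffles, generator streams) through a hash of the stage name and
any indices, so stages are reproducible yet statistically independent.
"""

from __future__ import annotations

import hashlib


def child_seed(master_seed: int, *tokens: object) -> int:
    """Derive a stage seed < 2**31 from ``master_seed`` and identifying tokens.

    Tokens may be strings or integers (e.g. ``child_seed(7, "calib", combo, i)``).
    The derivation is a SHA-256 hash, stable across platforms and sessions.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
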