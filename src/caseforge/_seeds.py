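"""Stable derivation of per-stage RNG seeds from one root seed.

Each pipeline stage draws from its own child generator so that adding or
reordering stages never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(root: int, *names: object) -> int:
    """Derive a deterministic 31-bit seed from ``root`` and a stage path.

    The derivation hashes the textual path, so it is stable across runs,
    platforms and Python hash randomization.
    """
    path = "|".join([str(int(root))] + [str(n) for n in names])
    digest = hashlib.sha256(path.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(root: int, *names: object) -> np.random.Generator:
    """A ``numpy`` generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(root, *names))
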