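"""Deterministic random-stream plumbing.

All randomness in the pipeline flows from one master seed. Each stage
derives its own independent stream with :func:`spawn`, keyed by a stable
stage name, so that re-running any stage with the same master seed
reproduces its output bit-for-bit regardless of what other stages did.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) from a master seed."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return int((int(master_seed) * 2654435761 + tag) % (2**31 - 1))


def spawn(master_seed: int, stage: str) -> np.random.Generator:
    """Return a fresh PCG64 generator for one named pipeline stage."""
    return np.random.default_rng(derive_seed(master_seed, stage))
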