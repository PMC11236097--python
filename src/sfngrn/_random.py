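"""Seed bookkeeping: every stochastic stage draws from its own named substream.

A master seed plus a fixed stage label deterministically yields the stage
seed, so changing (say) the negative-sampling stage never perturbs weight
initialisation or fold shuffling.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stage-specific 31-bit seed from ``master_seed`` and ``label``."""
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    """Generator seeded by the (master seed, stage label) substream."""
    return np.random.default_rng(derive_seed(master_seed, label))
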