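"""Deterministic random-stream derivation.

Every stochastic stage derives its own substream from a single master seed
and a stage name, so stages can be rerun individually and a whole pipeline
run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a 31-bit substream seed from a master seed and a stage label."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for one named stage of a seeded run."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), stage_seed(master_seed, stage)])
    )
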