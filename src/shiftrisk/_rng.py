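"""Named random substreams.

Every stochastic stage of a trial (component centers, covariances, points,
true function, model, split, ...) draws from its own substream derived from a
single master seed plus a stage name. Changing one stage's consumption of
random numbers therefore never perturbs the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_seed"]


def stream_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic 31-bit seed for a named substream."""
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    # SeedSequence mixes entropy properly; generate_state gives a stable int.
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A Generator for stage ``name`` under ``master_seed``."""
    return np.random.default_rng(stream_seed(master_seed, name))
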