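"""Deterministic, stage-tagged random streams.

Every stochastic stage derives an independent counter-based stream from
``(master seed, stage tag, block index)`` via :class:`numpy.random.SeedSequence`,
so results are bit-identical regardless of how work is chunked across
blocks or workers.
"""

from __future__ import annotations

import numpy as np

STAGE_FMCS = 0
STAGE_PARAMS = 1
STAGE_ORACLE = 2
STAGE_CLUSTER = 3
STAGE_FLUX = 4


def stream(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    """Independent generator for (seed, stage, index)."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence((int(seed), int(stage), int(index))))
    )
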