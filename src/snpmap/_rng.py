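"""Named random substreams derived from a single top-level seed.

Every stage of the pipeline draws from its own named substream so that,
for a fixed top-level seed, rerunning any one stage reproduces its output
exactly, and drawing from one stage's stream never perturbs another's.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` deterministically derived from ``seed``.

    The stage name is folded in through a CRC-32 of its UTF-8 bytes, so
    distinct stage names yield statistically independent streams while the
    (seed, stage) pair fully determines the stream.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
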