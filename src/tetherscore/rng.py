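"""Named random substreams.

All randomness in the package flows from one integer seed through named
substreams, so any stage can be re-run in isolation and reproduce its output
bit for bit. A substream is identified by a short label; the label is hashed
(CRC-32, stable across platforms and Python versions) and combined with the
global seed into a :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the substream ``label`` of ``seed``.

    Identical ``(seed, label)`` pairs always return identically-behaving
    generators; distinct labels give statistically independent streams.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
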