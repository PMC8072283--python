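"""Seed plumbing: one master seed expands deterministically into
per-purpose seeds so components are independently reproducible."""

from __future__ import annotations

import numpy as np


def spawn_seeds(master: int, n: int) -> list[int]:
    """n deterministic child seeds (each < 2**31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
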