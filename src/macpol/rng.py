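"""Seeded random-number service.

One master seed per replicate is split into independent named streams, one per
simulation component, so that adding draws to one component (e.g. a new
reaction rule) does not perturb the draws of another (e.g. diffusion).
"""
from __future__ import annotations

import numpy as np

#: Stream names in a fixed order; the order defines the SeedSequence spawn key.
STREAMS = ("init", "rules", "differentiation", "diffusion", "injection", "decay")


class RngStreams:
    """Named, independently seeded ``numpy.random.Generator`` streams."""

    def __init__(self, seed: int):
        if not (0 <= int(seed) < 2**63):
            raise ValueError(f"seed out of range: {seed}")
        self.seed = int(seed)
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(STREAMS))
        self._gen = {
            name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(STREAMS, children)
        }

    def __getattr__(self, name: str) -> np.random.Generator:
        try:
            return self._gen[name]
        except KeyError:  # pragma: no cover - attribute typo guard
            raise AttributeError(name) from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngStreams(seed={self.seed})"
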