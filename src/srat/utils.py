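"""Small shared helpers."""
from __future__ import annotations

import numpy as np


def sign_pm(v):
    """Sign in {-1, +1} with the convention sign(0) = +1.

    The decision boundary has probability zero under a continuous covariate
    law, but a deterministic tie-break is required for reproducibility.
    """
    return np.where(np.asarray(v) >= 0, 1, -1)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None to a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
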