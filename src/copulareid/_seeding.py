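"""Stream-splitting helper: every source of randomness in the package
derives from one root seed through SeedSequence.spawn."""

from __future__ import annotations

import numpy as np


def seed_seq(seed) -> np.random.SeedSequence:
    """Coerce an int, None, or SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
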