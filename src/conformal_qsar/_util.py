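"""Small shared helpers: seed fan-out and input checks."""

from __future__ import annotations

import numpy as np

# Seeds handed to sklearn must fit in a C long; keep everything below 2**31.
_SEED_MOD = 2**31


def derive_seeds(master_seed: int, n: int, key: str = "") -> np.ndarray:
    """Deterministically derive ``n`` child seeds from one master seed.

    The optional ``key`` namespaces independent consumers (e.g. per-target
    streams vs per-repeat streams) so they never collide.
    """
    entropy = [int(master_seed)]
    if key:
        entropy.extend(key.encode())
    ss = np.random.SeedSequence(entropy)
    return ss.generate_state(n, dtype=np.uint64) % _SEED_MOD


def rng_from(master_seed: int, key: str = "") -> np.random.Generator:
    return np.random.default_rng(int(derive_seeds(master_seed, 1, key)[0]))


def as_bool_series(values) -> np.ndarray:
    """Coerce a CSV-ish column (bools, 0/1, ''/'True'/'false') to booleans."""
    import pandas as pd

    s = pd.Series(values)
    if s.dtype == bool:
        return s.to_numpy()
    truthy = {"true", "1", "1.0", "yes", "t"}
    return s.fillna("").astype(str).str.strip().str.lower().isin(truthy).to_numpy()
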