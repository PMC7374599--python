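"""Seeded, size-balanced, stratified k-fold assignment.

A single round-robin deal over class-shuffled indices keeps total fold sizes
within ±1 of each other (e.g. folds of 5–6 samples for n = 59, k = 10) while
also balancing every class across folds to ±1.
"""

from __future__ import annotations

import numpy as np


def balanced_stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Return a fold index in [0, k) per observation.

    Stratified on the values of ``y``; total fold sizes differ by at most 1.
    """
    y = np.asarray(y)
    n = len(y)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got k={k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    counter = int(rng.integers(k))
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            fold[i] = counter % k
            counter += 1
    return fold
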