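"""Shared resampling utilities: seeded stratified k-fold splitting."""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["stratified_kfold"]


def stratified_kfold(
    labels: Sequence[str], k: int, seed: int = 0
) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment.

    Within each class the sample indices are shuffled with the seeded
    RNG and dealt round-robin into the ``k`` folds, so every fold's
    class proportions match the data as closely as integer counts
    allow.  Returns a list of ``k`` test-index arrays partitioning
    ``range(n)``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds for only {n} samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        # stagger the starting fold so small classes spread across folds
        for offset, i in enumerate(idx):
            folds[(start + offset) % k].append(int(i))
        start += len(idx)
    return [np.array(sorted(f), dtype=int) for f in folds]
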