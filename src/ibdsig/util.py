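"""Small shared numerics: seeded RNG fan-out and integer allocation."""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

__all__ = ["round_half_up", "largest_remainder", "child_seed"]


def round_half_up(x: float) -> int:
    """Round positive x half away from zero (0.5 -> 1)."""
    if x < 0:
        raise ValueError("round_half_up expects a non-negative value")
    return int(math.floor(x + 0.5))


def largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` items over ``proportions`` (largest-remainder method).

    Counts sum exactly to ``total``; ties on the fractional remainder go to
    the earlier category, keeping the result deterministic.
    """
    props = np.asarray(proportions, dtype=float)
    if props.ndim != 1 or len(props) == 0:
        raise ValueError("proportions must be a non-empty 1-D sequence")
    if np.any(props < 0):
        raise ValueError("proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1 within 1e-9")
    quotas = props * total
    counts = np.floor(quotas).astype(int)
    short = total - int(counts.sum())
    # stable sort: descending remainder, ascending index on ties
    order = np.lexsort((np.arange(len(props)), -(quotas - counts)))
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def child_seed(seed_seq: np.random.SeedSequence) -> int:
    """A plain integer seed (< 2**31) derived from a SeedSequence, for APIs
    that take ``random_state`` ints rather than Generators."""
    return int(seed_seq.generate_state(1)[0] % (2**31))
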