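"""The pool of ordered-categorical (Likert) items.

Each item is defined by four ascending category boundaries on the latent
0-100 continuum; the five response categories are the intervals they cut.
The default 27-item pool ships as package data and is the pool every
simulated dataset samples its items from.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["ItemDefinition", "load_item_pool"]


@dataclass(frozen=True)
class ItemDefinition:
    """A five-category Likert item as four ascending latent boundaries.

    Category 1 is (-inf, b1); category k+1 begins at boundary k, so a
    position exactly equal to the fourth boundary scores 5.
    """

    item_id: int
    boundaries: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (4,):
            raise ValueError("an item needs exactly 4 category boundaries")
        if not np.all(np.diff(b) > 0):
            raise ValueError(f"item {self.item_id}: boundaries must be strictly increasing")


def load_item_pool() -> list[ItemDefinition]:
    """Load the default 27-item pool shipped with the package."""
    with resources.files("likertfa.data").joinpath("item_pool.csv").open() as fh:
        header = fh.readline().strip().split(",")
        assert header == ["item_id", "b1", "b2", "b3", "b4"]
        pool = []
        for line in fh:
            if not line.strip():
                continue
            vals = line.strip().split(",")
            pool.append(
                ItemDefinition(int(vals[0]), tuple(float(v) for v in vals[1:5]))
            )
    if len(pool) != 27 or len({it.item_id for it in pool}) != 27:
        raise ValueError("item pool must contain 27 distinct items")
    return pool
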