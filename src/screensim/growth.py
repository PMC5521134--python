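"""Growth/survival-based selection over repeated passages.

In the time a wild-type cell (phenotype 0) divides once, a cell with the
maximal negative phenotype -1 does not divide and a cell with the maximal
positive phenotype +1 divides twice.  A cell with intermediate phenotype
phi picks, independently, whether to behave like a wild-type cell or like
the relevant maximal-phenotype cell, with probability |phi| of the extreme
behaviour — so the expected per-timestep growth factor is 2 + 2*phi for
phi >= 0 and 2 - |phi| for phi <= 0.  After every timestep the pool is
bottlenecked back to ``bottleneck_representation`` cells per guide
(passaging).  The comparison populations are the bottlenecked pool before
the first timestep (t0) and after the last one (tn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pool import CellPool

__all__ = ["GrowthParams", "growth_step", "grow"]


@dataclass
class GrowthParams:
    """Number of passages and per-passage bottleneck representation."""

    num_passages: int = 3
    bottleneck_representation: int = 100

    def validate(self) -> None:
        if self.num_passages < 1:
            raise ValueError("num_passages must be >= 1")
        if self.bottleneck_representation < 1:
            raise ValueError("bottleneck_representation must be >= 1")


def growth_step(pool: CellPool, rng: np.random.Generator) -> CellPool:
    """One division timestep; per-bucket binomial draws of extreme behaviour.

    For a bucket of c cells with phenotype phi, e ~ Binomial(c, |phi|) cells
    take the extreme behaviour: they become 4 cells each if phi > 0 and 1
    cell if phi < 0; the remaining c - e behave like wild type and double.
    """
    if pool.is_empty():
        raise ValueError("cannot grow an empty pool")
    phi = pool.phenotype
    c = pool.counts
    extreme = rng.binomial(c, np.abs(np.clip(phi, -1.0, 1.0)))
    new_counts = np.where(
        phi > 0,
        4 * extreme + 2 * (c - extreme),
        np.where(phi < 0, extreme + 2 * (c - extreme), 2 * c),
    )
    return CellPool(
        pool.guide_idx, pool.knockdown, new_counts, pool.phenotype, pool.n_guides
    ).drop_empty()


def grow(
    pool: CellPool, params: GrowthParams, rng: np.random.Generator
) -> tuple[CellPool, CellPool]:
    """Run the growth screen; returns the (t0, tn) comparison pools.

    t0 is the post-infection pool bottlenecked once (so both endpoints carry
    comparable sampling noise); each passage is a division timestep followed
    by a bottleneck, including after the final timestep.
    """
    params.validate()
    if pool.is_empty():
        raise ValueError("cannot grow an empty pool")

    bottleneck = params.bottleneck_representation * pool.n_guides
    t0 = pool.subsample(bottleneck, rng)
    current = t0
    for _ in range(params.num_passages):
        current = growth_step(current, rng)
        current = current.subsample(bottleneck, rng)
    return t0, current
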