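"""FACS-based phenotypic selection.

The pool is first bottlenecked to ``bottleneck_representation`` cells per
library guide (multinomial resampling — this is where sorting throughput
limits bite).  Each cell's observed reporter phenotype is its theoretical
phenotype plus zero-mean Gaussian noise with sd ``noise_sigma``,
representing biological variance in fluorescence of isogenic cells.  Cells
are ranked by observed phenotype and the bottom and top ``bin_fraction``
tails are kept as the two comparison bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pool import CellPool

__all__ = ["FacsParams", "facs_sort"]


@dataclass
class FacsParams:
    """Bottleneck representation, reporter noise sd and tail bin fraction."""

    bottleneck_representation: int = 100
    noise_sigma: float = 1.0
    bin_fraction: float = 0.25

    def validate(self) -> None:
        if self.bottleneck_representation < 1:
            raise ValueError("bottleneck_representation must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.bin_fraction <= 0.5):
            raise ValueError("bin_fraction must be in (0, 0.5]")


def facs_sort(
    pool: CellPool, params: FacsParams, rng: np.random.Generator
) -> tuple[CellPool, CellPool]:
    """Sort the pool into (low_bin, high_bin) of round(X * bottleneck) cells each.

    Per-cell observed phenotypes are simulated directly; ties (only possible
    at sigma = 0) are broken by random order via a pre-shuffle.
    """
    params.validate()
    if pool.is_empty():
        raise ValueError("cannot sort an empty pool")

    bottleneck = params.bottleneck_representation * pool.n_guides
    pool = pool.subsample(bottleneck, rng)

    cell_bucket = np.repeat(np.arange(len(pool)), pool.counts)
    # random pre-shuffle makes the stable sort break ties in random order
    rng.shuffle(cell_bucket)
    observed = pool.phenotype[cell_bucket]
    if params.noise_sigma > 0:
        observed = observed + rng.normal(0.0, params.noise_sigma, bottleneck)

    n_bin = int(round(params.bin_fraction * bottleneck))
    n_bin = max(n_bin, 1)
    order = np.argsort(observed, kind="stable")
    low_cells = cell_bucket[order[:n_bin]]
    high_cells = cell_bucket[order[-n_bin:]]

    def _bin_pool(cells: np.ndarray) -> CellPool:
        counts = np.bincount(cells, minlength=len(pool))
        return CellPool(
            pool.guide_idx, pool.knockdown, counts, pool.phenotype, pool.n_guides
        ).drop_empty()

    return _bin_pool(low_cells), _bin_pool(high_cells)
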