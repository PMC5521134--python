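"""Cell pool container.

Cells are tracked as counts per (guide, realized knockdown) bucket rather
than individually: all cells in a bucket share a guide, a realized
knockdown fraction and hence a theoretical phenotype, so every downstream
operation (division, subsampling, sorting, sequencing) only needs the
bucket counts.  This is distributionally identical to per-cell tracking and
orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CellPool"]


@dataclass
class CellPool:
    """Counts of cells per (guide, realized knockdown) bucket.

    ``n_guides`` is the size of the library the pool was infected with
    (guides may be absent from the pool but still occupy a row in count
    tables downstream).
    """

    guide_idx: np.ndarray  # int, index into the library arrays
    knockdown: np.ndarray  # float in [0, 1], one per bucket
    counts: np.ndarray  # non-negative int, cells per bucket
    phenotype: np.ndarray  # theoretical phenotype shared by the bucket
    n_guides: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("bucket counts must be non-negative")

    @property
    def total_cells(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)

    def is_empty(self) -> bool:
        return self.total_cells == 0

    def drop_empty(self) -> "CellPool":
        keep = self.counts > 0
        return CellPool(
            self.guide_idx[keep],
            self.knockdown[keep],
            self.counts[keep],
            self.phenotype[keep],
            self.n_guides,
        )

    def subsample(self, size: int, rng: np.random.Generator) -> "CellPool":
        """Multinomial bottleneck: draw ``size`` cells with replacement,
        with probabilities proportional to current bucket counts."""
        if self.is_empty():
            raise ValueError("cannot subsample an empty pool")
        probs = self.counts / self.total_cells
        new_counts = rng.multinomial(size, probs)
        return CellPool(
            self.guide_idx, self.knockdown, new_counts, self.phenotype, self.n_guides
        ).drop_empty()

    def guide_cell_counts(self) -> np.ndarray:
        """Cells per guide (length ``n_guides``), merging knockdown buckets."""
        return np.bincount(self.guide_idx, weights=self.counts, minlength=self.n_guides).astype(
            np.int64
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": self.guide_idx,
                "knockdown": self.knockdown,
                "cell_count": self.counts,
            }
        )
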