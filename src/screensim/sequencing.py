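"""Simulated library preparation and next-generation sequencing.

Sequencing a selected cell population is modelled as multinomial sampling
of a fixed total read count from the categorical distribution of guide
frequencies in that population (PCR amplification makes reads exchangeable
draws with replacement).  Knockdown-realization buckets of the same guide
are merged first: sequencing sees guides, not outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Gene
from .library import Library
from .pool import CellPool

__all__ = ["SeqParams", "sequence_bin", "make_count_table", "COUNT_COLUMNS"]

COUNT_COLUMNS = ["guide_id", "gene_id", "class", "counts_bin1", "counts_bin2"]


@dataclass
class SeqParams:
    """Sequencing depth as reads per library guide (per bin)."""

    representation: int = 100

    def validate(self) -> None:
        if self.representation < 1:
            raise ValueError("sequencing representation must be >= 1")


def sequence_bin(
    bin_pool: CellPool, params: SeqParams, rng: np.random.Generator
) -> np.ndarray:
    """Reads per guide (length n_guides) for one bin; total = depth exactly."""
    params.validate()
    if bin_pool.is_empty():
        raise ValueError("cannot sequence an empty bin")
    depth = params.representation * bin_pool.n_guides
    cells = bin_pool.guide_cell_counts()
    probs = cells / cells.sum()
    return rng.multinomial(depth, probs)


def make_count_table(
    reads_bin1: np.ndarray,
    reads_bin2: np.ndarray,
    library: Library,
    genome: list[Gene],
) -> pd.DataFrame:
    """Interchange count table; bin1 is the low/t0 bin, bin2 the high/tn bin."""
    class_by_gene = {g.id: g.gene_class.value for g in genome}
    return pd.DataFrame(
        {
            "guide_id": library.guide_id,
            "gene_id": library.gene_id,
            "class": [class_by_gene[g] for g in library.gene_id],
            "counts_bin1": np.asarray(reads_bin1, dtype=np.int64),
            "counts_bin2": np.asarray(reads_bin2, dtype=np.int64),
        }
    )
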