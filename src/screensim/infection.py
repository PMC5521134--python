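"""Lentiviral infection at a given MOI and realization of per-cell knockdown.

Each cell in the initial pool receives a Poisson(lambda) number of viral
integrations; only single-integrant cells are informative and are retained
(about 19.5% of the pool at the standard lambda = 0.25).  Retained cells
draw their guide from the plasmid frequency distribution.  CRISPRi cells
realize the guide's knockdown efficiency directly.  CRISPRn cells carrying
an active guide (efficiency 1.0) undergo stochastic DNA repair: assuming
2/3 of repair events at a locus cause a frameshift and a diploid host, a
cell ends up with no functional knockout (both alleles in-frame, 1/9), a
monoallelic knockout treated as 50% knockdown (4/9), or a biallelic
knockout, 100% knockdown (4/9).  The outcome is heritable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Gene, phenotypes_for
from .library import CRISPRN, Library
from .pool import CellPool

__all__ = [
    "InfectionParams",
    "KNOCKOUT_KNOCKDOWNS",
    "KNOCKOUT_PROBS",
    "single_integration_probability",
    "simulate_retention",
    "infect",
]

#: Realized knockdown levels for an active CRISPRn guide and their
#: probabilities under the diploid 2/3-frameshift repair model.
KNOCKOUT_KNOCKDOWNS = np.array([0.0, 0.5, 1.0])
KNOCKOUT_PROBS = np.array([1.0 / 9.0, 4.0 / 9.0, 4.0 / 9.0])


@dataclass
class InfectionParams:
    """MOI and cells-per-guide representation at transfection."""

    moi: float = 0.25
    representation: int = 100

    def validate(self) -> None:
        if self.moi < 0:
            raise ValueError("moi must be >= 0")
        if self.representation < 1:
            raise ValueError("representation must be >= 1")


def single_integration_probability(moi: float) -> float:
    """P(exactly one integration) = lambda * exp(-lambda)."""
    return float(moi * np.exp(-moi))


def simulate_retention(n_cells: int, moi: float, rng: np.random.Generator) -> int:
    """Number of single-integrant cells among ``n_cells`` at the given MOI."""
    if moi < 0:
        raise ValueError("moi must be >= 0")
    return int(np.count_nonzero(rng.poisson(moi, n_cells) == 1))


def infect(
    library: Library,
    genome: list[Gene],
    params: InfectionParams,
    rng: np.random.Generator,
) -> CellPool:
    """Infect ``representation x len(library)`` cells and realize knockdowns.

    Returns the pool of retained single-integrant cells bucketed by
    (guide, realized knockdown); the screen mode is taken from the library.
    """
    params.validate()
    if len(library) == 0:
        raise ValueError("library must be nonempty")

    n_guides = len(library)
    total_initial = params.representation * n_guides
    n_retained = simulate_retention(total_initial, params.moi, rng)
    guide_counts = rng.multinomial(n_retained, library.plasmid_frequency)

    if library.mode == CRISPRN:
        active = library.efficiency == 1.0
        guide_idx_parts: list[np.ndarray] = []
        kd_parts: list[np.ndarray] = []
        count_parts: list[np.ndarray] = []
        # active guides: per-cell knockout outcome, 3 buckets per guide
        act_ids = np.flatnonzero(active & (guide_counts > 0))
        if len(act_ids) > 0:
            outcome = rng.multinomial(guide_counts[act_ids], KNOCKOUT_PROBS)  # (n, 3)
            guide_idx_parts.append(np.repeat(act_ids, 3))
            kd_parts.append(np.tile(KNOCKOUT_KNOCKDOWNS, len(act_ids)))
            count_parts.append(outcome.ravel())
        low_ids = np.flatnonzero(~active & (guide_counts > 0))
        if len(low_ids) > 0:
            guide_idx_parts.append(low_ids)
            kd_parts.append(library.efficiency[low_ids])
            count_parts.append(guide_counts[low_ids])
        guide_idx = np.concatenate(guide_idx_parts) if guide_idx_parts else np.array([], int)
        knockdown = np.concatenate(kd_parts) if kd_parts else np.array([], float)
        counts = np.concatenate(count_parts) if count_parts else np.array([], np.int64)
    else:
        guide_idx = np.flatnonzero(guide_counts > 0)
        knockdown = library.efficiency[guide_idx]
        counts = guide_counts[guide_idx]

    gene_ids = library.gene_id[guide_idx] if len(guide_idx) else np.array([], int)
    phenotype = phenotypes_for(genome, gene_ids, knockdown)
    return CellPool(guide_idx, knockdown, counts, phenotype, n_guides).drop_empty()
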