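"""sgRNA library model: per-guide activity and plasmid frequency.

Each gene is targeted by ``m`` independent guides.  Guide activity (the
knockdown fraction the guide achieves) is bimodal: a small low-activity
component near zero and a dominant high-activity component.  For CRISPRi
the high component is Gaussian (mean 0.90, sd 0.1); for CRISPRn
high-activity guides cut with maximal efficiency 1.0 and the per-cell
knockout outcome is decided later, at infection.  Plasmid frequencies are
log-normal, parameterized so that a guide at the 95th percentile of
frequency is a fixed fold (default 10) more frequent than one at the 5th
percentile — the typical spread of a well-made library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Gene

__all__ = [
    "CRISPRI",
    "CRISPRN",
    "LibraryConfig",
    "Library",
    "build_library",
    "lognormal_sigma_for_ratio",
]

CRISPRI = "CRISPRi"
CRISPRN = "CRISPRn"


@dataclass
class LibraryConfig:
    """Parameters of the simulated sgRNA library."""

    guides_per_gene: int = 5
    mode: str = CRISPRI
    fraction_high_activity: float = 0.9
    low_activity_mean: float = 0.05
    low_activity_sd: float = 0.07
    high_activity_mean: float = 0.90
    high_activity_sd: float = 0.1
    frequency_spread: float = 10.0  # 95th/5th percentile frequency ratio

    def validate(self) -> None:
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if self.mode not in (CRISPRI, CRISPRN):
            raise ValueError(f"mode must be {CRISPRI!r} or {CRISPRN!r}")
        if not (0.0 <= self.fraction_high_activity <= 1.0):
            raise ValueError("fraction_high_activity must be in [0, 1]")
        if self.frequency_spread < 1.0:
            raise ValueError("frequency_spread must be >= 1")


@dataclass
class Library:
    """Column-oriented guide table (one row per sgRNA).

    ``efficiency`` is the knockdown fraction a guide achieves (for CRISPRn
    high-activity guides it is exactly 1.0 and the realized per-cell
    knockdown is drawn at infection).  ``plasmid_frequency`` sums to 1.
    """

    guide_id: np.ndarray
    gene_id: np.ndarray
    efficiency: np.ndarray
    plasmid_frequency: np.ndarray
    mode: str = CRISPRI

    def __len__(self) -> int:
        return len(self.guide_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": self.guide_id,
                "gene_id": self.gene_id,
                "efficiency": self.efficiency,
                "plasmid_frequency": self.plasmid_frequency,
            }
        )


def lognormal_sigma_for_ratio(
    ratio: float, lower_q: float = 0.05, upper_q: float = 0.95
) -> float:
    """Log-scale sd of a log-normal whose upper_q/lower_q quantile ratio is ``ratio``.

    Solves ``exp(sigma * (z_u - z_l)) = ratio`` for sigma, where z are
    standard-normal quantiles.  ``ratio = 1`` gives a degenerate (uniform)
    library with sigma 0.
    """
    if ratio < 1.0:
        raise ValueError("ratio must be >= 1")
    if not (0.0 < lower_q < upper_q < 1.0):
        raise ValueError("quantiles must satisfy 0 < lower_q < upper_q < 1")
    if ratio == 1.0:
        return 0.0
    return float(np.log(ratio) / (stats.norm.ppf(upper_q) - stats.norm.ppf(lower_q)))


def build_library(
    genome: list[Gene], config: LibraryConfig, rng: np.random.Generator
) -> Library:
    """Build an sgRNA library targeting every gene with ``m`` guides."""
    if not genome:
        raise ValueError("genome must be nonempty")
    config.validate()

    m = config.guides_per_gene
    n = len(genome) * m
    gene_id = np.repeat([g.id for g in genome], m)
    guide_id = np.arange(n)

    high = rng.random(n) < config.fraction_high_activity
    low_draws = rng.normal(config.low_activity_mean, config.low_activity_sd, n)
    if config.mode == CRISPRI:
        high_draws = rng.normal(config.high_activity_mean, config.high_activity_sd, n)
    else:
        # CRISPRn: active guides always cut; outcome stochasticity is per cell
        high_draws = np.ones(n)
    efficiency = np.clip(np.where(high, high_draws, low_draws), 0.0, 1.0)

    sigma = lognormal_sigma_for_ratio(config.frequency_spread)
    freq = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    freq /= freq.sum()

    return Library(guide_id, gene_id, efficiency, freq, mode=config.mode)
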