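"""Simulated genome: gene phenotype classes and knockdown-response functions.

A simulated genome assigns each of ``N`` genes a "true" phenotype ``l`` (a
dimensionless selection strength in [-1, 1]) and a knockdown-response
function mapping the realized knockdown fraction ``x`` of the gene to the
fraction of the full phenotype that a cell displays.  Four gene classes
exist: phenotype-free wild-type genes, negative-control genes (phenotype 0
by definition; these define the null distribution downstream), and genes
with positive or negative phenotypes drawn from clamped Gaussians.

Two response families are modelled.  Linear genes interpolate linearly
between no phenotype at zero knockdown and the full phenotype at complete
knockdown.  Sigmoidal ("switch-like") genes show essentially no phenotype
until knockdown passes an inflection point ``p`` and the full phenotype
shortly after; the transition occupies a window of half-width ``k``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneClass",
    "KDResponse",
    "Gene",
    "GenomeConfig",
    "build_genome",
    "response_fraction",
    "cell_phenotype",
    "phenotypes_for",
    "genome_to_frame",
]


class GeneClass(str, enum.Enum):
    """The four phenotype classes a simulated gene can belong to."""

    WILDTYPE = "wildtype"
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_HIT = "positive_hit"
    NEGATIVE_HIT = "negative_hit"


#: Fixed class order used for deterministic count rounding.
CLASS_ORDER: tuple[GeneClass, ...] = (
    GeneClass.WILDTYPE,
    GeneClass.NEGATIVE_CONTROL,
    GeneClass.POSITIVE_HIT,
    GeneClass.NEGATIVE_HIT,
)

LINEAR = "linear"
SIGMOIDAL = "sigmoidal"


@dataclass(frozen=True)
class KDResponse:
    """Knockdown-response function of a gene.

    Parameters
    ----------
    kind
        ``"linear"`` or ``"sigmoidal"``.
    p
        Inflection point (knockdown fraction), sigmoidal only.
    k
        Half-width of the inflection window, sigmoidal only.
    """

    kind: str
    p: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (LINEAR, SIGMOIDAL):
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.kind == SIGMOIDAL:
            if self.p is None or self.k is None:
                raise ValueError("sigmoidal response requires p and k")
            if not (0.0 < self.p < 1.0) or self.k <= 0.0:
                raise ValueError("sigmoidal response requires 0 < p < 1, k > 0")


@dataclass(frozen=True)
class Gene:
    """A simulated gene: identity, class, true phenotype and response."""

    id: int
    gene_class: GeneClass
    true_phenotype: float
    response: KDResponse


@dataclass
class GenomeConfig:
    """Parameters of the simulated genome.

    Defaults mirror a typical screen setup: 500 genes of which 75% are
    wild-type, 5% negative controls, 10% positive and 10% negative hits;
    hit strengths drawn from Gaussians with mean +/-0.55, sd 0.2, clamped
    away from zero; 25% of genes get a sigmoidal response with inflection
    point ~N(0.8, 0.2) and half-width ~N(0.1, 0.05).
    """

    num_genes: int = 500
    fractions: dict[GeneClass, float] = field(
        default_factory=lambda: {
            GeneClass.WILDTYPE: 0.75,
            GeneClass.NEGATIVE_CONTROL: 0.05,
            GeneClass.POSITIVE_HIT: 0.10,
            GeneClass.NEGATIVE_HIT: 0.10,
        }
    )
    positive_mean: float = 0.55
    positive_sd: float = 0.2
    positive_clamp: tuple[float, float] = (0.1, 1.0)
    negative_mean: float = -0.55
    negative_sd: float = 0.2
    negative_clamp: tuple[float, float] = (-1.0, -0.1)
    fraction_sigmoidal: float = 0.25
    sigmoid_p_mean: float = 0.8
    sigmoid_p_sd: float = 0.2
    sigmoid_k_mean: float = 0.1
    sigmoid_k_sd: float = 0.05
    # sanitization bounds for the sigmoid parameters (rejection sampling)
    sigmoid_p_bounds: tuple[float, float] = (0.05, 0.99)
    sigmoid_k_min: float = 0.01

    def validate(self) -> None:
        if self.num_genes < 1:
            raise ValueError("num_genes must be >= 1")
        fracs = {GeneClass(k): float(v) for k, v in self.fractions.items()}
        if any(v < 0 for v in fracs.values()):
            raise ValueError("class fractions must be non-negative")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        if not (0.0 <= self.fraction_sigmoidal <= 1.0):
            raise ValueError("fraction_sigmoidal must be in [0, 1]")

    def class_counts(self) -> dict[GeneClass, int]:
        """Deterministic class counts: floor(N * fraction), remainder
        distributed in fixed class order."""
        self.validate()
        fracs = {GeneClass(k): float(v) for k, v in self.fractions.items()}
        counts = {c: int(np.floor(self.num_genes * fracs.get(c, 0.0))) for c in CLASS_ORDER}
        remainder = self.num_genes - sum(counts.values())
        for c in CLASS_ORDER:
            if remainder == 0:
                break
            if fracs.get(c, 0.0) > 0:
                counts[c] += 1
                remainder -= 1
        # pathological case: all remainder slots exhausted on zero-fraction classes
        for c in CLASS_ORDER:
            if remainder == 0:
                break
            counts[c] += 1
            remainder -= 1
        return counts


def _clamped_normal(
    rng: np.random.Generator, mean: float, sd: float, clamp: tuple[float, float], size: int
) -> np.ndarray:
    """Gaussian draws clipped (not redrawn) to the clamp interval."""
    return np.clip(rng.normal(mean, sd, size), clamp[0], clamp[1])


def _sample_sigmoid_params(config: GenomeConfig, rng: np.random.Generator) -> tuple[float, float]:
    # rejection sampling keeps delta well-defined without reshaping the bulk
    lo, hi = config.sigmoid_p_bounds
    while True:
        p = rng.normal(config.sigmoid_p_mean, config.sigmoid_p_sd)
        if lo <= p <= hi:
            break
    while True:
        k = rng.normal(config.sigmoid_k_mean, config.sigmoid_k_sd)
        if k >= config.sigmoid_k_min:
            break
    return float(p), float(k)


def build_genome(config: GenomeConfig, rng: np.random.Generator) -> list[Gene]:
    """Generate a simulated genome.

    Class counts are a deterministic function of (N, fractions); phenotypes
    and response parameters are drawn from ``rng``.
    """
    config.validate()
    counts = config.class_counts()

    classes: list[GeneClass] = []
    for c in CLASS_ORDER:
        classes.extend([c] * counts[c])

    phenotypes = np.zeros(config.num_genes)
    pos_idx = [i for i, c in enumerate(classes) if c is GeneClass.POSITIVE_HIT]
    neg_idx = [i for i, c in enumerate(classes) if c is GeneClass.NEGATIVE_HIT]
    phenotypes[pos_idx] = _clamped_normal(
        rng, config.positive_mean, config.positive_sd, config.positive_clamp, len(pos_idx)
    )
    phenotypes[neg_idx] = _clamped_normal(
        rng, config.negative_mean, config.negative_sd, config.negative_clamp, len(neg_idx)
    )

    genes: list[Gene] = []
    for i in range(config.num_genes):
        if rng.random() < config.fraction_sigmoidal:
            p, k = _sample_sigmoid_params(config, rng)
            response = KDResponse(SIGMOIDAL, p=p, k=k)
        else:
            response = KDResponse(LINEAR)
        genes.append(Gene(i, classes[i], float(phenotypes[i]), response))
    return genes


def _sigmoid_fraction(x: np.ndarray, p: float, k: float) -> np.ndarray:
    denom = min(p, min(1.0 - p, k))
    delta = (x - p) / denom
    mid = 0.5 * (np.sign(delta) * 1.05 * np.abs(delta) / (np.abs(delta) + 1.0) + 1.0)
    # the printed transition jumps to the plateaus at x = p +/- k; no smoothing
    return np.where(x <= p - k, 0.0, np.where(x >= p + k, 1.0, mid))


def response_fraction(response: KDResponse, x):
    """Fraction of the full phenotype shown at knockdown level ``x``.

    Linear responses return ``x`` itself.  Sigmoidal responses return 0 below
    ``p - k``, 1 above ``p + k``, and inside the window
    ``0.5 * (sign(d) * 1.05*|d| / (|d| + 1) + 1)`` with
    ``d = (x - p) / min(p, min(1 - p, k))``; at ``x = p`` this is exactly 0.5.
    Accepts scalars or arrays; ``x`` must lie in [0, 1].
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("knockdown fraction x must lie in [0, 1]")
    if response.kind == LINEAR:
        out = arr
    else:
        out = _sigmoid_fraction(arr, response.p, response.k)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def cell_phenotype(gene: Gene, x):
    """Signed phenotype of a cell whose target gene is knocked down by ``x``."""
    if gene.true_phenotype == 0.0:
        # still validates the domain of x
        frac = response_fraction(gene.response, x)
        return 0.0 * frac
    return gene.true_phenotype * response_fraction(gene.response, x)


def phenotypes_for(
    genome: list[Gene], gene_ids: np.ndarray, knockdowns: np.ndarray
) -> np.ndarray:
    """Vectorized ``cell_phenotype`` over parallel (gene_id, knockdown) arrays."""
    gene_ids = np.asarray(gene_ids, dtype=int)
    x = np.asarray(knockdowns, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("knockdown fraction x must lie in [0, 1]")
    l = np.array([g.true_phenotype for g in genome])
    is_linear = np.array([g.response.kind == LINEAR for g in genome])
    p = np.array([g.response.p if g.response.p is not None else 0.5 for g in genome])
    k = np.array([g.response.k if g.response.k is not None else 0.1 for g in genome])

    frac = np.empty_like(x)
    lin_mask = is_linear[gene_ids]
    frac[lin_mask] = x[lin_mask]
    sig = ~lin_mask
    if np.any(sig):
        gi = gene_ids[sig]
        ps, ks, xs = p[gi], k[gi], x[sig]
        denom = np.minimum(ps, np.minimum(1.0 - ps, ks))
        delta = (xs - ps) / denom
        mid = 0.5 * (np.sign(delta) * 1.05 * np.abs(delta) / (np.abs(delta) + 1.0) + 1.0)
        frac[sig] = np.where(xs <= ps - ks, 0.0, np.where(xs >= ps + ks, 1.0, mid))
    return l[gene_ids] * frac


def genome_to_frame(genome: list[Gene]) -> pd.DataFrame:
    """Tab-delimited-ready table: gene_id, class, true_phenotype, response_kind, p, k."""
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in genome],
            "class": [g.gene_class.value for g in genome],
            "true_phenotype": [g.true_phenotype for g in genome],
            "response_kind": [g.response.kind for g in genome],
            "p": [g.response.p for g in genome],
            "k": [g.response.k for g in genome],
        }
    )
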