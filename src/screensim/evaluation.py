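"""Screen-performance metrics against the ground-truth genome.

Three families of metrics: the overlap of the called top-n hit genes with
the actual top-n (by |true phenotype|); the area under the precision-recall
curve for recovering genes with nonzero true phenotype; and signal / noise
/ SNR, where signal is the median over true-hit genes of the mean per-guide
ratio of observed log2 fold change to theoretical phenotype, and noise is
the standard deviation of negative-control guide phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Gene, GeneClass, phenotypes_for
from .infection import KNOCKOUT_KNOCKDOWNS, KNOCKOUT_PROBS
from .library import CRISPRN, Library

__all__ = [
    "Metrics",
    "top_overlap",
    "auprc",
    "class_auprc",
    "theoretical_phenotypes",
    "signal_noise",
]

HIT_CLASSES = (GeneClass.POSITIVE_HIT.value, GeneClass.NEGATIVE_HIT.value)


@dataclass
class Metrics:
    """Screen-level performance summary."""

    overlap: float
    auprc: float
    signal: float
    noise: float
    snr: float

    def to_dict(self) -> dict[str, float]:
        return {
            "overlap": self.overlap,
            "auprc": self.auprc,
            "signal": self.signal,
            "noise": self.noise,
            "snr": self.snr,
        }


def top_overlap(ranked_genes: pd.DataFrame, genome: list[Gene], n: int = 50) -> float:
    """Fraction of the called top-n genes that are actual top-n genes.

    Actual top-n genes are ranked by descending |true phenotype| with ties
    broken by ascending gene_id; the called ranking comes from
    :func:`screensim.hitcalling.rank_genes` (or any frame with gene_id and
    rank/score columns).
    """
    if n > len(genome):
        raise ValueError("n exceeds the number of genes")
    actual = sorted(genome, key=lambda g: (-abs(g.true_phenotype), g.id))
    actual_top = {g.id for g in actual[:n]}
    if "rank" in ranked_genes.columns:
        called = ranked_genes.sort_values("rank")
    else:
        called = ranked_genes.sort_values(
            ["score", "gene_id"], ascending=[False, True], kind="mergesort"
        )
    called_top = set(called["gene_id"].head(n))
    return len(actual_top & called_top) / n


def _pr_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Achievable (recall, precision) points at each distinct score threshold,
    thresholds from strictest to loosest."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order].astype(float)
    # threshold boundaries: last index of each tied block
    boundary = np.flatnonzero(np.diff(s) != 0)
    idx = np.append(boundary, len(s) - 1)
    tp = np.cumsum(y)[idx]
    pred_pos = idx + 1.0
    total_pos = y.sum()
    recall = tp / total_pos
    precision = tp / pred_pos
    return recall, precision


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve, lower trapezoidal estimator.

    Linear interpolation between successive achievable PR points, anchored
    at recall 0 with the first point's precision.  ``labels`` marks the
    positive class (genes with nonzero true phenotype).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    recall, precision = _pr_points(scores, labels)
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(p, r))


def class_auprc(
    gene_results: pd.DataFrame,
    positive_class: str,
    exclude_classes: tuple[str, ...] = (),
) -> float:
    """AUPRC for detecting one hit class only.

    Genes of ``exclude_classes`` are removed before scoring (e.g. exclude
    positive hits when asking how well negative hits are recovered);
    remaining non-positive-class genes are the negatives.
    """
    df = gene_results[~gene_results["class"].isin(exclude_classes)]
    return auprc(
        df["score"].to_numpy(), (df["class"] == positive_class).to_numpy()
    )


def theoretical_phenotypes(genome: list[Gene], library: Library) -> np.ndarray:
    """Deterministic expected phenotype per guide.

    CRISPRi guides (and low-activity CRISPRn guides) map their fixed
    knockdown efficiency through the gene's response.  Active CRISPRn guides
    average the response over the 1/9-4/9-4/9 knockout outcome mix, giving
    the expected per-cell phenotype.
    """
    direct = phenotypes_for(genome, library.gene_id, library.efficiency)
    if library.mode != CRISPRN:
        return direct
    active = library.efficiency == 1.0
    mix = np.zeros(len(library))
    for kd, prob in zip(KNOCKOUT_KNOCKDOWNS, KNOCKOUT_PROBS):
        mix += prob * phenotypes_for(
            genome, library.gene_id, np.full(len(library), kd)
        )
    return np.where(active, mix, direct)


def signal_noise(
    guide_results: pd.DataFrame, theoretical: np.ndarray
) -> tuple[float, float, float]:
    """(signal, noise, snr) for one screen.

    ``guide_results`` is the output of :func:`screensim.hitcalling.guide_phenotypes`
    with guides in library order; ``theoretical`` the matching per-guide
    theoretical phenotypes.  Dropped guides and guides with theoretical
    phenotype 0 are excluded from the signal.  snr is NaN when noise is 0.
    """
    df = guide_results.copy()
    df["theoretical"] = np.asarray(theoretical, dtype=float)

    usable = df[~df["dropped"]]
    hits = usable[usable["class"].isin(HIT_CLASSES) & (usable["theoretical"] != 0.0)]
    if hits.empty:
        raise ValueError("no usable hit guides for the signal calculation")
    per_gene = (hits["log2fc"] / hits["theoretical"]).groupby(hits["gene_id"]).mean()
    signal = float(per_gene.median())

    controls = usable.loc[
        usable["class"] == GeneClass.NEGATIVE_CONTROL.value, "log2fc"
    ].to_numpy()
    if len(controls) < 2:
        raise ValueError("need >= 2 negative-control guide phenotypes")
    noise = float(np.std(controls, ddof=1))
    snr = signal / noise if noise > 0 else float("nan")
    return signal, noise, snr
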