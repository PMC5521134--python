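"""Guide- and gene-level hit calling from a two-bin count table.

Guide phenotypes are log2 ratios of pseudocounted read frequencies between
the two bins (high over low, or tn over t0).  Gene phenotypes are the
arithmetic mean of member guide phenotypes.  Significance is assessed with
a two-sided Mann-Whitney rank-sum test of a gene's guide phenotypes against
the phenotypes of all negative-control guides, and genes are ranked by
|gene phenotype| * -log10(p).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneClass

__all__ = [
    "guide_phenotypes",
    "gene_stats",
    "rank_genes",
    "mann_whitney_p",
]

#: -log10(p) is capped here to avoid infinities from p-value underflow.
MAX_NEG_LOG10_P = 300.0

#: Largest tie-free total sample size handled by the exact U distribution.
_EXACT_MAX_N = 30


@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of rank arrangements per U value (tie-free null), U = 0..n1*n2.

    U = u in as many arrangements as there are partitions of u into at most
    n1 parts each <= n2, via the recursion
    N(u; a, b) = N(u; a, b-1) + N(u-b; a-1, b).
    """
    table: dict[tuple[int, int], np.ndarray] = {}
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            arr = np.zeros(a * b + 1)
            if a == 0 or b == 0:
                arr[0] = 1.0
            else:
                shorter = table[(a, b - 1)]  # all parts <= b-1
                removed = table[(a - 1, b)]  # at least one part == b
                arr[: len(shorter)] += shorter
                arr[b : b + len(removed)] += removed
            table[(a, b)] = arr
    return table[(n1, n2)]


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p for tie-free samples.

    p = P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) under the permutation null.
    """
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    dist = _u_distribution(n1, n2)
    probs = dist / dist.sum()
    center = n1 * n2 / 2.0
    d = abs(u - center)
    support = np.arange(n1 * n2 + 1)
    return float(probs[np.abs(support - center) >= d - 1e-9].sum())


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact permutation distribution for tie-free samples with
    n1 + n2 <= 30; otherwise the normal approximation with tie and
    continuity correction.  Result is clipped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    tie_free = len(np.unique(combined)) == len(combined)
    if tie_free and len(combined) <= _EXACT_MAX_N:
        p = _exact_two_sided_p(x, y)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return float(min(max(p, 1e-300), 1.0))


def guide_phenotypes(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-guide log2 frequency ratios (bin2 over bin1).

    freq_b(g) = (reads_b(g) + pseudocount) / (depth_b + pseudocount * G)
    with G the number of guides in the table.  Guides with zero reads in
    both bins are flagged ``dropped`` and carry no log2fc.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c1 = counts["counts_bin1"].to_numpy(dtype=float)
    c2 = counts["counts_bin2"].to_numpy(dtype=float)
    depth1, depth2 = c1.sum(), c2.sum()
    if depth1 <= 0 or depth2 <= 0:
        raise ValueError("both bins must have positive total reads")
    n_guides = len(counts)
    dropped = (c1 == 0) & (c2 == 0)
    f1 = (c1 + pseudocount) / (depth1 + pseudocount * n_guides)
    f2 = (c2 + pseudocount) / (depth2 + pseudocount * n_guides)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(f2 / f1)
    log2fc[dropped] = np.nan

    out = counts.copy()
    out["log2fc"] = log2fc
    out["dropped"] = dropped
    return out


def gene_stats(guide_results: pd.DataFrame) -> pd.DataFrame:
    """Gene-level phenotype, Mann-Whitney p vs negative controls, and score.

    Expects the output of :func:`guide_phenotypes` (columns gene_id, class,
    log2fc, dropped).  The null set is the phenotypes of all non-dropped
    guides of negative-control genes.  Genes whose guides all dropped out
    get phenotype 0, p = 1, score 0.
    """
    usable = guide_results[~guide_results["dropped"]]
    controls = usable.loc[
        usable["class"] == GeneClass.NEGATIVE_CONTROL.value, "log2fc"
    ].to_numpy()
    if len(controls) < 2:
        raise ValueError("need >= 2 negative-control guide phenotypes")

    records = []
    for (gene_id, gene_class), grp in guide_results.groupby(
        ["gene_id", "class"], sort=True
    ):
        member = grp.loc[~grp["dropped"], "log2fc"].to_numpy()
        if len(member) == 0:
            phenotype, p = 0.0, 1.0
        else:
            phenotype = float(member.mean())
            p = mann_whitney_p(member, controls)
        score = abs(phenotype) * min(-np.log10(p), MAX_NEG_LOG10_P)
        records.append(
            {
                "gene_id": gene_id,
                "class": gene_class,
                "phenotype": phenotype,
                "p_value": p,
                "score": score,
            }
        )
    return pd.DataFrame.from_records(records)


def rank_genes(gene_results: pd.DataFrame) -> pd.DataFrame:
    """Order genes by descending score, ties broken by ascending gene_id."""
    out = gene_results.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
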