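"""End-to-end screens, replicate sweeps over parameter grids, and the SNR
bin-size curve.

A screen is the composition genome -> library -> infection -> selection
(FACS or growth) -> sequencing of both bins -> guide phenotypes -> gene
statistics -> ranking -> performance metrics, fully reproducible from
(config, seed).  Sweeps derive one decorrelated seed per (grid cell,
replicate) from the base seed, so any single cell can be re-run in
isolation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import evaluation, hitcalling
from .config import FACS, GROWTH, ScreenConfig
from .facs import facs_sort
from .genome import Gene, build_genome
from .growth import grow
from .infection import infect
from .library import Library, build_library
from .sequencing import make_count_table, sequence_bin

__all__ = ["ScreenResult", "SweepSpec", "run_screen", "run_sweep", "snr_curve", "replicate_seed"]

logger = logging.getLogger("screensim")


@dataclass
class ScreenResult:
    """Everything one simulated screen produces."""

    genome: list[Gene]
    library: Library
    counts: pd.DataFrame
    guide_results: pd.DataFrame
    gene_results: pd.DataFrame
    metrics: evaluation.Metrics


def run_screen(config: ScreenConfig, seed) -> ScreenResult:
    """Run one screen; ``seed`` may be an int or a numpy SeedSequence."""
    config.validate()
    rng = np.random.default_rng(seed)

    genome = build_genome(config.genome, rng)
    library = build_library(genome, config.library, rng)
    pool = infect(library, genome, config.infection, rng)
    logger.debug("infection retained %d cells", pool.total_cells)

    if config.selection_type == FACS:
        bin1, bin2 = facs_sort(pool, config.facs, rng)  # low, high
    elif config.selection_type == GROWTH:
        bin1, bin2 = grow(pool, config.growth, rng)  # t0, tn
    else:  # pragma: no cover - validated above
        raise ValueError(config.selection_type)

    reads1 = sequence_bin(bin1, config.sequencing, rng)
    reads2 = sequence_bin(bin2, config.sequencing, rng)
    counts = make_count_table(reads1, reads2, library, genome)

    guide_results = hitcalling.guide_phenotypes(counts, config.pseudocount)
    gene_results = hitcalling.rank_genes(hitcalling.gene_stats(guide_results))

    theoretical = evaluation.theoretical_phenotypes(genome, library)
    overlap = evaluation.top_overlap(gene_results, genome, config.top_n)
    area = evaluation.auprc(
        gene_results["score"].to_numpy(),
        gene_results["class"].isin(evaluation.HIT_CLASSES).to_numpy(),
    )
    signal, noise, snr = evaluation.signal_noise(guide_results, theoretical)
    metrics = evaluation.Metrics(overlap, area, signal, noise, snr)
    logger.info(
        "screen done: overlap=%.3f auprc=%.3f signal=%.3f noise=%.3f snr=%.3f",
        overlap, area, signal, noise, snr,
    )
    return ScreenResult(genome, library, counts, guide_results, gene_results, metrics)


def replicate_seed(base_seed: int, cell_index: int, rep_index: int) -> np.random.SeedSequence:
    """Decorrelated per-run seed, a pure function of its arguments."""
    return np.random.SeedSequence([int(base_seed), int(cell_index), int(rep_index)])


def _set_by_path(config: ScreenConfig, path: str, value: Any) -> None:
    obj: Any = config
    parts = path.split(".")
    for part in parts[:-1]:
        obj = getattr(obj, part)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise AttributeError(f"unknown config path {path!r}")
    current = getattr(obj, leaf)
    if isinstance(current, int) and not isinstance(current, bool):
        fv = float(value)
        if fv.is_integer():
            value = int(fv)
    setattr(obj, leaf, value)


@dataclass
class SweepSpec:
    """A parameter grid sweep: cartesian product of value grids x replicates."""

    base_config: ScreenConfig
    params: list[tuple[str, Sequence[Any]]]
    replicates: int = 10
    base_seed: int = 0
    extra_metrics: dict[str, Any] = field(default_factory=dict)  # name -> fn(ScreenResult)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(len(values) == 0 for _, values in self.params):
            raise ValueError("parameter grids must be nonempty")


def run_sweep(spec: SweepSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sweep; returns (per-run tidy table, per-cell summary table).

    The tidy table has one row per (grid cell, replicate) carrying the swept
    parameter values and all metrics; failed runs are recorded with an
    ``error`` message and NaN metrics, and the sweep continues.  The summary
    has per-cell means with 95% and 99% normal-approximation confidence
    half-widths for each metric.
    """
    spec.validate()
    paths = [p for p, _ in spec.params]
    grids = [list(v) for _, v in spec.params]
    cells = list(itertools.product(*grids)) if grids else [()]

    rows: list[dict[str, Any]] = []
    for cell_index, cell_values in enumerate(cells):
        for rep in range(spec.replicates):
            cfg = spec.base_config.copy()
            for path, value in zip(paths, cell_values):
                _set_by_path(cfg, path, value)
            seed = replicate_seed(spec.base_seed, cell_index, rep)
            row: dict[str, Any] = dict(zip(paths, cell_values))
            row.update({"cell_index": cell_index, "replicate": rep, "error": ""})
            try:
                result = run_screen(cfg, seed)
                row.update(result.metrics.to_dict())
                for name, fn in spec.extra_metrics.items():
                    row[name] = fn(result)
            except Exception as exc:  # record and continue
                logger.warning("run failed (cell %d rep %d): %s", cell_index, rep, exc)
                row["error"] = str(exc)
            rows.append(row)

    results = pd.DataFrame(rows)
    metric_cols = [
        c
        for c in results.columns
        if c not in paths and c not in ("cell_index", "replicate", "error")
    ]
    summary_rows = []
    for cell_index, grp in results.groupby("cell_index"):
        srow: dict[str, Any] = {"cell_index": cell_index}
        for path in paths:
            srow[path] = grp[path].iloc[0]
        n = len(grp)
        srow["n"] = n
        for col in metric_cols:
            vals = pd.to_numeric(grp[col], errors="coerce").dropna()
            mean = vals.mean() if len(vals) else np.nan
            sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            srow[f"{col}_mean"] = mean
            srow[f"{col}_ci95"] = 1.959963984540054 * sem
            srow[f"{col}_ci99"] = 2.5758293035489004 * sem
        summary_rows.append(srow)
    return results, pd.DataFrame(summary_rows)


def snr_curve(
    base_config: ScreenConfig,
    bin_fractions: Sequence[float],
    replicates: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean signal, noise and SNR across a grid of FACS bin fractions.

    Returns one row per bin fraction with means, confidence half-widths and
    per-metric max-normalized columns (for display, mirroring how such
    curves are usually plotted).
    """
    if len(bin_fractions) < 1:
        raise ValueError("need at least one bin fraction")
    cfg = base_config.copy()
    cfg.selection_type = FACS
    spec = SweepSpec(
        base_config=cfg,
        params=[("facs.bin_fraction", list(bin_fractions))],
        replicates=replicates,
        base_seed=base_seed,
    )
    _, summary = run_sweep(spec)
    out = summary.rename(columns={"facs.bin_fraction": "bin_fraction"})
    for metric in ("signal", "noise", "snr"):
        peak = out[f"{metric}_mean"].abs().max()
        out[f"{metric}_norm"] = out[f"{metric}_mean"] / peak if peak > 0 else np.nan
    return out
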