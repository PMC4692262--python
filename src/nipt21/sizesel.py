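"""In-silico size selection: length filtering, cutoff sweep, enrichment.

Fetal cfDNA fragments run shorter than maternal ones, so keeping only
reads whose effective length is at most a cutoff enriches the fetal
signal — the "effective" fetal fraction rises while the physical sample
is unchanged.  The sweep tries cutoffs from 140 to 180 bp in 5-bp steps;
for each cutoff the whole downstream pipeline is re-run (re-filter,
recount, re-correct GC, retrain on the euploid training set, rescore) and
the cutoff maximizing the mean z of the known trisomic samples wins, with
ties broken toward the smaller cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortCounts, DEFAULT_GRID
from .ingest import ReadBatch
from .zscore import score_matrix, train_model

logger = logging.getLogger(__name__)

MIN_USABLE_READS = 10_000


def filter_by_length(batch: ReadBatch, max_len: int) -> ReadBatch:
    """Keep reads with effective length <= max_len (inclusive boundary).

    Reads without a usable effective length (<= 0) are dropped and counted
    in ``meta['n_no_length']``.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    has_len = batch.eff_length > 0
    out = batch.take(has_len & (batch.eff_length <= max_len))
    out.meta["n_no_length"] = int((~has_len).sum())
    return out


@dataclass
class CutoffSweep:
    """Result of the 140-180 bp cutoff sweep."""

    table: pd.DataFrame  # index cutoff; mean_trisomic_z, retained_fraction, usable
    chosen: int
    method: int

    def __str__(self) -> str:
        lines = [f"cutoff sweep (method {self.method}); chosen = {self.chosen} bp"]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def sweep_cutoffs(
    cohort: CohortCounts,
    trisomic_ids: list[str],
    training_ids: list[str],
    grid: tuple[int, ...] = DEFAULT_GRID,
    method: int = 3,
    min_reads: int = MIN_USABLE_READS,
    refit_gc: bool = True,
    span: float = 0.3,
) -> CutoffSweep:
    """Re-run the pipeline per cutoff and pick the mean-trisomic-z argmax.

    A cutoff leaving fewer than ``min_reads`` reads in any sample is
    flagged unusable and excluded from the argmax.  Euploid z dispersion
    is not part of the objective.
    """
    grid = tuple(int(g) for g in grid)
    if not grid:
        raise ValueError("cutoff grid must be non-empty")
    if list(grid) != sorted(set(grid)):
        raise ValueError("cutoff grid must be strictly increasing")
    if not trisomic_ids:
        raise ValueError("need at least one known trisomic sample")
    missing = [g for g in grid if g not in cohort.grid]
    if missing:
        raise ValueError(f"cutoffs {missing} not on the cohort's counting grid")

    total_reads = cohort.retained_reads(None)
    gc_mode = "refit" if refit_gc else "all_reads"
    rows = []
    for cutoff in grid:
        retained = cohort.retained_reads(cutoff)
        usable = bool(retained.min() >= min_reads)
        mean_z = np.nan
        if usable:
            matrix = cohort.chrom_matrix(cutoff, gc_mode=gc_mode, span=span)
            model = train_model(matrix.subset(training_ids), method)
            scores = score_matrix(matrix.subset(trisomic_ids), model, cutoff)
            mean_z = float(scores["z"].mean())
        else:
            logger.warning("cutoff %d bp unusable: a sample has < %d reads",
                           cutoff, min_reads)
        rows.append(
            {
                "cutoff": cutoff,
                "mean_trisomic_z": mean_z,
                "retained_fraction": float((retained / total_reads).mean()),
                "usable": usable,
            }
        )
    table = pd.DataFrame(rows).set_index("cutoff")
    usable_tab = table[table["usable"]]
    if usable_tab.empty:
        raise ValueError("no usable cutoff in the grid")
    best = usable_tab["mean_trisomic_z"].max()
    chosen = int(usable_tab.index[usable_tab["mean_trisomic_z"] == best].min())
    return CutoffSweep(table=table, chosen=chosen, method=method)


def effective_ff_gain(
    ff_all: pd.Series, ff_selected: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Paired comparison of effective vs all-reads fetal-fraction estimates.

    Returns the per-sample table (all, selected, difference, gain ratio)
    and a summary with the two medians and the median gain.
    """
    ids_all, ids_sel = set(ff_all.index), set(ff_selected.index)
    if ids_all != ids_sel:
        raise ValueError(
            "sample id mismatch between estimates: "
            f"only in all-reads {sorted(ids_all - ids_sel)}, "
            f"only in size-selected {sorted(ids_sel - ids_all)}"
        )
    ff_selected = ff_selected.loc[ff_all.index]
    table = pd.DataFrame(
        {
            "ff_all": ff_all,
            "ff_selected": ff_selected,
            "difference": ff_selected - ff_all,
            "gain": ff_selected / ff_all,
        }
    )
    summary = {
        "median_ff_all": float(ff_all.median()),
        "median_ff_selected": float(ff_selected.median()),
        "median_gain": float(table["gain"].median()),
    }
    return table, summary
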