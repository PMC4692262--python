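"""Cohort-level container of length-stratified bin counts.

:class:`CohortCounts` holds, for every sample, the binned read counts
stratified by effective-length class, so that any inclusive length cutoff
on the sweep grid can be re-derived without touching the read records
again.  It is the bridge between read-level processing (simulation or
ingestion, filtering, counting) and ratio-level analysis (GC correction,
training, scoring, the cutoff sweep).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .gc import correct_sample, fit_gc_curve, apply_gc_correction
from .genome import GenomeModel
from .ingest import (
    BinCounts,
    CountMatrix,
    ReadBatch,
    apply_quality_filters,
    count_reads,
    downsample,
)
from .simulate import CohortTruth

logger = logging.getLogger(__name__)

DEFAULT_GRID: tuple[int, ...] = tuple(range(140, 185, 5))


@dataclass
class CohortCounts:
    """Per-sample, per-bin, per-length-class counts for a whole cohort."""

    genome: GenomeModel
    grid: tuple[int, ...]
    sample_ids: list[str] = field(default_factory=list)
    by_length: list[np.ndarray] = field(default_factory=list)  # (n_bins, n_cls) each
    truth: CohortTruth | None = None
    filter_log: dict[str, dict] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def add_sample(self, batch: ReadBatch, *, max_reads: int = 3_000_000,
                   seed: int | None = None, min_mapq: int = 40,
                   min_len: int = 35, dedupe: bool = True) -> None:
        """Run one raw batch through downsample -> filters -> counting."""
        batch = downsample(batch, n_max=max_reads, seed=seed)
        filtered, stats = apply_quality_filters(
            batch, min_mapq=min_mapq, min_len=min_len, dedupe=dedupe
        )
        bins = count_reads(filtered, self.genome, grid=self.grid)
        self.sample_ids.append(batch.sample_id)
        self.by_length.append(bins.by_length.astype(np.float32))
        self.filter_log[batch.sample_id] = {
            "filters": stats.__dict__,
            "n_out_of_range": bins.meta.get("n_out_of_range", 0),
        }
        self._cache.clear()

    def bin_counts(self, i: int) -> BinCounts:
        bl = self.by_length[i].astype(np.float64)
        return BinCounts(
            genome=self.genome,
            counts=bl.sum(axis=1),
            by_length=bl,
            grid=self.grid,
            meta={"sample_id": self.sample_ids[i]},
        )

    def retained_reads(self, cutoff: int | None = None) -> pd.Series:
        """Filtered read count per sample at a length cutoff (None = all)."""
        if cutoff is None:
            vals = [bl.sum() for bl in self.by_length]
        else:
            j = self.grid.index(int(cutoff))
            vals = [bl[:, : j + 1].sum() for bl in self.by_length]
        return pd.Series(vals, index=self.sample_ids, dtype=float)

    def chrom_matrix(
        self,
        cutoff: int | None = None,
        gc_mode: str = "refit",
        span: float = 0.3,
    ) -> CountMatrix:
        """Samples x 24 chromosome matrix at a length cutoff.

        ``gc_mode``: 'refit' fits a fresh per-sample GC curve on the
        cutoff-filtered counts (length filtering changes the GC mix of the
        library); 'all_reads' reuses each sample's unfiltered curve;
        'none' skips correction.
        """
        key = (cutoff, gc_mode, span)
        if key in self._cache:
            return self._cache[key]
        rows = []
        for i, sid in enumerate(self.sample_ids):
            bins = self.bin_counts(i)
            y = bins.counts_at_cutoff(cutoff)
            if gc_mode == "refit":
                corrected = correct_sample(bins, span=span, counts=y)
            elif gc_mode == "all_reads":
                curve = self._all_reads_curve(i, span)
                corrected = apply_gc_correction(bins, curve, counts=y)
            elif gc_mode == "none":
                corrected = BinCounts(genome=self.genome, counts=y)
            else:
                raise ValueError(f"unknown gc_mode {gc_mode!r}")
            rows.append(pd.Series(self.genome.chrom_sums(corrected.counts),
                                  index=self.genome.chroms, name=sid))
        matrix = CountMatrix(
            data=pd.DataFrame(rows),
            corrected=gc_mode != "none",
            cutoff=cutoff,
        )
        self._cache[key] = matrix
        return matrix

    def _all_reads_curve(self, i: int, span: float):
        key = ("curve", i, span)
        if key not in self._cache:
            self._cache[key] = fit_gc_curve(self.bin_counts(i), span=span)
        return self._cache[key]

    @classmethod
    def from_batches(
        cls,
        batches: Iterable[ReadBatch],
        genome: GenomeModel,
        grid: tuple[int, ...] = DEFAULT_GRID,
        truth: CohortTruth | None = None,
        **filter_kwargs,
    ) -> "CohortCounts":
        cohort = cls(genome=genome, grid=tuple(grid), truth=truth)
        shared_seed = filter_kwargs.pop("seed", None)
        for batch in batches:
            seed = shared_seed
            if seed is None and truth is not None:
                try:
                    seed = truth.spec(batch.sample_id).seed
                except KeyError:
                    seed = None
            cohort.add_sample(batch, seed=seed, **filter_kwargs)
        return cohort


def simulate_cohort_counts(
    config,
    genome: GenomeModel,
    seed: int | None = None,
    grid: tuple[int, ...] = DEFAULT_GRID,
) -> CohortCounts:
    """Simulate a cohort and stream it straight into counted form."""
    from .simulate import build_truth, generate_sample

    truth = build_truth(config, seed)
    lengths = config.length_model()
    cohort = CohortCounts(genome=genome, grid=tuple(grid), truth=truth)
    for spec in truth.samples:
        batch = generate_sample(spec, genome, lengths)
        # per-sample downsample seed derives from the sample's own seed
        cohort.add_sample(batch, seed=spec.seed)
        logger.debug("simulated %s: %s", spec.sample_id,
                     cohort.filter_log[spec.sample_id])
    return cohort


def choose_training_samples(
    truth: CohortTruth, n_training: int = 60, seed: int | None = None
) -> list[str]:
    """Randomly choose euploid training samples from the cohort."""
    euploid = truth.ids("euploid")
    if len(euploid) < n_training:
        raise ValueError(
            f"cohort has {len(euploid)} euploid samples; need {n_training} for training"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(euploid), size=n_training, replace=False)
    return [euploid[int(i)] for i in sorted(picked)]
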