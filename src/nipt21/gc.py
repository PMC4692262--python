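"""GC-bias correction of binned read counts.

Coverage in low-coverage cfDNA sequencing depends smoothly on bin GC
content, with run-to-run variation that inflates the between-sample
variance of the chromosome-21 representation.  The correction is the
classic single-sample scheme: fit a local-regression (LOWESS) curve of
bin count versus bin GC on autosomal bins — excluding chromosomes 13, 18
and 21, which may carry the aneuploidy signal — and rescale every bin by
reference_level / fitted(GC), where the reference level is the median
fitted value.  No cross-sample (intrarun) normalization is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import CHROMS, SIGNAL_CHROMS
from .ingest import BinCounts, CountMatrix

logger = logging.getLogger(__name__)

#: Per-bin correction factors are clamped to this range to bound the
#: leverage of GC-extreme bins.
FACTOR_CLAMP = (0.2, 5.0)

MIN_FIT_BINS = 50


@dataclass
class GcCurve:
    """Fitted expected-count-versus-GC curve for one sample."""

    gc_grid: np.ndarray  # sorted GC values at which the fit was evaluated
    fitted: np.ndarray  # expected count at each grid point
    reference: float  # median fitted value (global reference level)
    span: float
    n_bins_used: int

    def predict(self, gc: np.ndarray) -> np.ndarray:
        """Fitted expected count at arbitrary GC (linear interpolation)."""
        return np.interp(gc, self.gc_grid, self.fitted)


def _autosomal_fit_mask(bins: BinCounts) -> np.ndarray:
    g = bins.genome
    excluded = set(SIGNAL_CHROMS) | {"chrX", "chrY"}
    chrom_ok = np.array([c not in excluded for c in g.chroms])
    return chrom_ok[g.bin_chrom] & (g.mappability > 0)


def fit_gc_curve(bins: BinCounts, span: float = 0.3,
                 counts: np.ndarray | None = None) -> GcCurve:
    """LOWESS fit of bin count against bin GC on reference autosomal bins.

    ``counts`` overrides ``bins.counts`` (used when fitting a cutoff-
    filtered view of the same binning).  Chromosome 13/18/21 and sex-
    chromosome bins never enter the fit; the reference level is the median
    of the fitted values.
    """
    g = bins.genome
    y = bins.counts if counts is None else counts
    mask = _autosomal_fit_mask(bins)
    if int((y[mask] > 0).sum()) < MIN_FIT_BINS:
        raise ValueError(
            f"only {int((y[mask] > 0).sum())} autosomal bins with reads "
            f"(need >= {MIN_FIT_BINS}); use larger bins or more reads"
        )
    x = g.gc[mask]
    yy = y[mask]
    gc_range = float(x.max() - x.min())
    if gc_range == 0.0:
        # degenerate input: constant curve at the mean count
        ref = float(yy.mean())
        return GcCurve(
            gc_grid=np.array([x[0] - 1e-6, x[0] + 1e-6]),
            fitted=np.array([ref, ref]),
            reference=ref,
            span=span,
            n_bins_used=int(mask.sum()),
        )
    fit = lowess(
        yy, x, frac=span, it=1, delta=0.005 * gc_range, return_sorted=True
    )
    # collapse duplicate abscissae so interpolation is well defined
    grid, inv = np.unique(fit[:, 0], return_inverse=True)
    fitted = np.bincount(inv, weights=fit[:, 1]) / np.bincount(inv)
    return GcCurve(
        gc_grid=grid,
        fitted=fitted,
        reference=float(np.median(fitted)),
        span=span,
        n_bins_used=int(mask.sum()),
    )


def apply_gc_correction(
    bins: BinCounts, curve: GcCurve, counts: np.ndarray | None = None
) -> BinCounts:
    """Rescale per-bin counts by reference / fitted(GC), clamped.

    corrected(bin) = raw(bin) * reference / fitted(GC(bin)); non-positive
    fitted values are clamped (with a counted warning) so factors stay in
    ``FACTOR_CLAMP``.
    """
    y = bins.counts if counts is None else counts
    fitted = curve.predict(bins.genome.gc)
    n_bad = int((fitted <= 0).sum())
    if n_bad:
        logger.warning("%d bins with non-positive fitted GC level; clamped", n_bad)
    factor = curve.reference / np.clip(fitted, 1e-12, None)
    np.clip(factor, FACTOR_CLAMP[0], FACTOR_CLAMP[1], out=factor)
    corrected = y * factor
    meta = dict(bins.meta)
    meta["n_clamped_bins"] = n_bad
    return BinCounts(genome=bins.genome, counts=corrected, meta=meta)


def correct_sample(bins: BinCounts, span: float = 0.3,
                   counts: np.ndarray | None = None) -> BinCounts:
    """Fit and apply the GC curve for one sample in one step."""
    curve = fit_gc_curve(bins, span=span, counts=counts)
    return apply_gc_correction(bins, curve, counts=counts)


def chr21_cv(matrix: CountMatrix, reference_set: tuple[str, ...]) -> float:
    """CV of the chr21 fractional genomic representation across samples.

    Per sample: ratio = chr21 count / summed count of ``reference_set``;
    CV = sample standard deviation (n-1) / mean.  Depth-invariant because
    the ratio is fractional.
    """
    if len(matrix.data) < 2:
        raise ValueError("need at least 2 samples to compute a CV")
    denom = matrix.data[list(reference_set)].sum(axis=1)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(
            f"zero reference-set counts in sample(s): {list(zero.index)}"
        )
    ratios = matrix.data["chr21"] / denom
    return float(ratios.std(ddof=1) / ratios.mean())
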