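"""Binned genome model used by both the cfDNA simulator and the counting pipeline.

The model is a stand-in for an unmasked hg19 reference: 24 chromosomes
(chr1..chr22, chrX, chrY) tiled with fixed-size, half-open, 0-based bins.
Each bin carries a GC fraction and a mappability weight.  Chromosome-level
GC means follow the human genome (chr19/chr22 GC-rich, chr4/chr13 AT-rich);
within-chromosome variation is a smooth, seeded, spatially correlated
process.  Chromosome-to-chromosome GC contrast is what lets a sample-specific
GC bias distort the chromosome-21 representation, which the GC-correction
stage then has to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Canonical chromosome order used for every 24-vector in the package
#: (columns 1..22, X, Y).
CHROMS: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

AUTOSOMES: tuple[str, ...] = CHROMS[:22]

#: Chromosomes that may carry the aneuploidy signal of clinical interest;
#: they are excluded from GC-curve fitting and from reference denominators.
SIGNAL_CHROMS: tuple[str, ...] = ("chr13", "chr18", "chr21")

#: The 19 autosomes eligible as internal-reference members.
ELIGIBLE_IR_CHROMS: tuple[str, ...] = tuple(
    c for c in AUTOSOMES if c not in SIGNAL_CHROMS
)

CHR21 = "chr21"

#: hg19 chromosome sizes in bp.
HG19_SIZES: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

#: Approximate chromosome-level GC fractions of the human reference.
HG19_CHROM_GC: dict[str, float] = {
    "chr1": 0.417,
    "chr2": 0.402,
    "chr3": 0.397,
    "chr4": 0.382,
    "chr5": 0.395,
    "chr6": 0.396,
    "chr7": 0.407,
    "chr8": 0.401,
    "chr9": 0.413,
    "chr10": 0.415,
    "chr11": 0.415,
    "chr12": 0.408,
    "chr13": 0.385,
    "chr14": 0.408,
    "chr15": 0.422,
    "chr16": 0.447,
    "chr17": 0.455,
    "chr18": 0.398,
    "chr19": 0.483,
    "chr20": 0.441,
    "chr21": 0.408,
    "chr22": 0.479,
    "chrX": 0.395,
    "chrY": 0.391,
}

GC_CENTER = 0.41
GC_CLIP = (0.25, 0.70)


@dataclass(frozen=True)
class GenomeModel:
    """Fixed binning of a chromosome set, with per-bin GC and mappability."""

    chroms: tuple[str, ...]
    lengths: np.ndarray  # (n_chroms,) int64, bp
    bin_size: int
    gc: np.ndarray  # (n_bins,) float64 in [0, 1]
    mappability: np.ndarray  # (n_bins,) float64 in [0, 1]
    bin_chrom: np.ndarray = field(repr=False, default=None)  # (n_bins,) int16
    bin_start: np.ndarray = field(repr=False, default=None)  # (n_bins,) int64
    bin_len: np.ndarray = field(repr=False, default=None)  # (n_bins,) int64
    bin_offset: np.ndarray = field(repr=False, default=None)  # (n_chroms+1,)

    @property
    def n_bins(self) -> int:
        return self.gc.shape[0]

    @property
    def n_chroms(self) -> int:
        return len(self.chroms)

    def chrom_index(self, name: str) -> int:
        try:
            return self.chroms.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def bins_of(self, name: str) -> slice:
        i = self.chrom_index(name)
        return slice(int(self.bin_offset[i]), int(self.bin_offset[i + 1]))

    def global_bin(self, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Map (chromosome index, 0-based position) to global bin index."""
        return self.bin_offset[chrom_idx] + pos // self.bin_size

    def chrom_sums(self, per_bin: np.ndarray) -> np.ndarray:
        """Sum a per-bin vector (or trailing-axis stack) per chromosome."""
        if per_bin.ndim == 1:
            return np.bincount(
                self.bin_chrom, weights=per_bin, minlength=self.n_chroms
            )
        out = np.empty((self.n_chroms,) + per_bin.shape[1:], dtype=float)
        for j in range(per_bin.shape[1]):
            out[:, j] = np.bincount(
                self.bin_chrom, weights=per_bin[:, j], minlength=self.n_chroms
            )
        return out


def _smooth_noise(n: int, window: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance, spatially correlated noise along a chromosome."""
    if n == 0:
        return np.zeros(0)
    window = max(1, min(window, n))
    raw = rng.standard_normal(n + window - 1)
    kernel = np.ones(window) / window
    sm = np.convolve(raw, kernel, mode="valid")
    return sm * np.sqrt(window)


def build_genome_model(
    chrom_table: Mapping[str, int] | None = None,
    bin_size: int = 50_000,
    gc_seed: int = 0,
    chrom_gc: Mapping[str, float] | None = None,
    gc_spatial_sd: float = 0.04,
    gc_corr_bins: int = 20,
) -> GenomeModel:
    """Build the binned genome.

    Parameters
    ----------
    chrom_table
        Chromosome name -> length (bp).  Defaults to hg19 sizes.
    bin_size
        Bin width in bp (>= 1000).  Bins are half-open ``[k*b, (k+1)*b)``;
        the last bin of a chromosome may be short (ceiling rule).
    gc_seed
        Seed for the within-chromosome GC process; the same seed always
        yields the same GC vector.
    chrom_gc
        Chromosome-level mean GC.  Defaults to hg19 values; unknown names
        fall back to 0.41.
    gc_spatial_sd, gc_corr_bins
        Standard deviation and correlation length (in bins) of the smooth
        within-chromosome GC variation.
    """
    if chrom_table is None:
        chrom_table = HG19_SIZES
    if chrom_gc is None:
        chrom_gc = HG19_CHROM_GC
    if len(chrom_table) < 2:
        raise ValueError("need at least 2 chromosomes")
    if bin_size < 1_000:
        raise ValueError(f"bin_size must be >= 1000 bp, got {bin_size}")

    chroms = tuple(chrom_table)
    lengths = np.array([chrom_table[c] for c in chroms], dtype=np.int64)
    for c, ln in zip(chroms, lengths):
        if ln <= 0:
            raise ValueError(f"chromosome {c!r} has non-positive length {ln}")

    n_per = (lengths + bin_size - 1) // bin_size  # ceiling
    bin_offset = np.concatenate([[0], np.cumsum(n_per)]).astype(np.int64)
    n_bins = int(bin_offset[-1])

    bin_chrom = np.repeat(np.arange(len(chroms), dtype=np.int16), n_per)
    within = np.concatenate([np.arange(k, dtype=np.int64) for k in n_per])
    bin_start = within * bin_size
    bin_len = np.minimum(bin_start + bin_size, lengths[bin_chrom]) - bin_start

    rng = np.random.default_rng(gc_seed)
    gc = np.empty(n_bins)
    for i, c in enumerate(chroms):
        sl = slice(int(bin_offset[i]), int(bin_offset[i + 1]))
        base = float(chrom_gc.get(c, GC_CENTER))
        gc[sl] = base + gc_spatial_sd * _smooth_noise(sl.stop - sl.start, gc_corr_bins, rng)
    np.clip(gc, GC_CLIP[0], GC_CLIP[1], out=gc)

    mappability = np.ones(n_bins)

    model = GenomeModel(
        chroms=chroms,
        lengths=lengths,
        bin_size=int(bin_size),
        gc=gc,
        mappability=mappability,
        bin_chrom=bin_chrom,
        bin_start=bin_start,
        bin_len=bin_len,
        bin_offset=bin_offset,
    )
    if float(np.sum(model.bin_len * model.mappability)) <= 0:
        raise ValueError("degenerate genome: total mappable length is zero")
    return model
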