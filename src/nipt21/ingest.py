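"""Aligned-read ingestion, quality filtering, downsampling and counting.

Reads arrive either as SAM/BAM (via pysam) or as the package's plain
tab-separated read-record dialect.  Records are held column-wise in a
:class:`ReadBatch` (numpy arrays), the natural container for millions of
low-coverage cfDNA reads.  The filtering chain mirrors a standard NIPT
preprocessing recipe: keep primary alignments with MAPQ >= 40 and length
>= 35 bp, collapse duplicates sharing (chromosome, 5' position, strand),
and cap each sample at 3 million raw reads drawn uniformly at random.

Coordinates are 0-based half-open throughout; SAM positions are converted
on ingestion.  The ``eff_length`` field is the pre-trim original read
length for single-end data and |template length| for paired-end data — the
quantity later used for in-silico size selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .genome import CHROMS, GenomeModel

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["sample_id", "chrom", "pos", "strand", "mapq", "eff_length", "origin"]

ORIGIN_CODES = {"maternal": 0, "fetal": 1, "NA": -1}
ORIGIN_NAMES = {v: k for k, v in ORIGIN_CODES.items()}


class ReadRecord(NamedTuple):
    """One aligned, filtered sequencing read."""

    sample_id: str
    chrom: str
    pos: int  # 0-based leftmost
    strand: str  # '+' or '-'
    mapq: int
    eff_length: int
    origin: str = "NA"


@dataclass
class ReadBatch:
    """Column-wise batch of read records for one sample."""

    sample_id: str
    chrom_idx: np.ndarray  # int16, index into ``chroms``
    pos: np.ndarray  # int64, 0-based
    strand: np.ndarray  # int8, 0='+', 1='-'
    mapq: np.ndarray  # int16
    eff_length: np.ndarray  # int32
    origin: np.ndarray = None  # int8 codes; -1 = unknown
    chroms: tuple[str, ...] = CHROMS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.origin is None:
            self.origin = np.full(len(self.pos), -1, dtype=np.int8)

    def __len__(self) -> int:
        return int(self.pos.shape[0])

    def take(self, idx_or_mask: np.ndarray) -> "ReadBatch":
        return ReadBatch(
            sample_id=self.sample_id,
            chrom_idx=self.chrom_idx[idx_or_mask],
            pos=self.pos[idx_or_mask],
            strand=self.strand[idx_or_mask],
            mapq=self.mapq[idx_or_mask],
            eff_length=self.eff_length[idx_or_mask],
            origin=self.origin[idx_or_mask],
            chroms=self.chroms,
            meta=dict(self.meta),
        )

    def records(self) -> Iterator[ReadRecord]:
        for i in range(len(self)):
            yield ReadRecord(
                self.sample_id,
                self.chroms[self.chrom_idx[i]],
                int(self.pos[i]),
                "+" if self.strand[i] == 0 else "-",
                int(self.mapq[i]),
                int(self.eff_length[i]),
                ORIGIN_NAMES[int(self.origin[i])],
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "chrom": np.asarray(self.chroms, dtype=object)[self.chrom_idx],
                "pos": self.pos,
                "strand": np.where(self.strand == 0, "+", "-"),
                "mapq": self.mapq,
                "eff_length": self.eff_length,
                "origin": pd.Series(self.origin).map(ORIGIN_NAMES).to_numpy(),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_sam(self, path: str | Path, genome: GenomeModel) -> None:
        """Write a minimal SAM rendering (template length carries eff_length)."""
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": int(ln)}
                for c, ln in zip(genome.chroms, genome.lengths)
            ],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for i in range(len(self)):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"{self.sample_id}:{i}"
                a.reference_id = int(self.chrom_idx[i])
                a.reference_start = int(self.pos[i])
                a.mapping_quality = int(self.mapq[i])
                a.flag = 0x1 | 0x2 | 0x40  # paired, proper pair, first mate
                if self.strand[i] == 1:
                    a.flag |= 0x10
                a.cigarstring = "50M"
                a.query_sequence = "N" * 50
                a.next_reference_id = int(self.chrom_idx[i])
                a.next_reference_start = int(self.pos[i])
                a.template_length = int(self.eff_length[i])
                a.set_tag("OL", int(self.eff_length[i]))
                fh.write(a)


@dataclass
class FilterStats:
    """Bookkeeping of reads removed by each quality rule."""

    n_input: int = 0
    n_mapq_removed: int = 0
    n_len_removed: int = 0
    n_dup_removed: int = 0
    n_retained: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class BinCounts:
    """Per-bin read counts for one sample (optionally length-stratified).

    ``by_length`` holds counts split into length classes bounded by
    ``grid`` cutoffs: class j covers lengths in (grid[j-1], grid[j]], the
    last class everything above the final cutoff, so counts at cutoff
    grid[j] are the cumulative sum of classes 0..j (inclusive filter).
    Before correction the counts are integers summing to the number of
    counted reads; GC correction turns them into non-negative reals.
    """

    genome: GenomeModel
    counts: np.ndarray  # (n_bins,) float64
    by_length: np.ndarray | None = None  # (n_bins, len(grid)+1)
    grid: tuple[int, ...] | None = None
    meta: dict = field(default_factory=dict)

    def chrom_totals(self) -> pd.Series:
        return pd.Series(self.genome.chrom_sums(self.counts), index=self.genome.chroms)

    def counts_at_cutoff(self, cutoff: int | None) -> np.ndarray:
        """Per-bin counts of reads with eff_length <= cutoff (None = all)."""
        if cutoff is None:
            return self.counts
        if self.by_length is None or self.grid is None:
            raise ValueError("BinCounts was built without length stratification")
        j = self.grid.index(int(cutoff))
        return self.by_length[:, : j + 1].sum(axis=1)


@dataclass
class CountMatrix:
    """Samples x 24-chromosome count matrix with processing flags."""

    data: pd.DataFrame  # index sample ids, columns CHROMS
    corrected: bool = False
    cutoff: int | None = None

    def __post_init__(self):
        if list(self.data.columns) != list(self.data.columns):  # pragma: no cover
            raise ValueError("column order corrupted")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.data.sum(axis=1) <= 0).any():
            bad = self.data.index[self.data.sum(axis=1) <= 0].tolist()
            raise ValueError(f"samples with zero total counts: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def row(self, sample_id: str) -> pd.Series:
        return self.data.loc[sample_id]

    def subset(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            data=self.data.loc[list(sample_ids)],
            corrected=self.corrected,
            cutoff=self.cutoff,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path: str | Path, corrected: bool = False,
                 cutoff: int | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(data=df[list(CHROMS)], corrected=corrected, cutoff=cutoff)


def _read_tsv_alignments(path: Path, chrom_to_idx: dict[str, int]) -> ReadBatch:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    except Exception as exc:  # malformed file -> hard error with context
        raise ValueError(f"malformed read-record TSV {path}: {exc}") from exc
    missing = [c for c in TSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    idx = df["chrom"].map(chrom_to_idx)
    n_unknown = int(idx.isna().sum())
    if n_unknown:
        logger.warning("%s: skipped %d reads on unmodeled chromosomes", path, n_unknown)
        df = df[idx.notna()]
        idx = idx[idx.notna()]

    sample_id = str(df["sample_id"].iloc[0]) if len(df) else path.stem
    origin = (
        df["origin"].map(ORIGIN_CODES).fillna(-1).to_numpy(dtype=np.int8)
        if "origin" in df.columns
        else None
    )
    batch = ReadBatch(
        sample_id=sample_id,
        chrom_idx=idx.to_numpy(dtype=np.int16),
        pos=df["pos"].to_numpy(dtype=np.int64),
        strand=(df["strand"].to_numpy() == "-").astype(np.int8),
        mapq=df["mapq"].to_numpy(dtype=np.int16),
        eff_length=df["eff_length"].to_numpy(dtype=np.int32),
        origin=origin,
    )
    batch.meta["n_unknown_chrom"] = n_unknown
    return batch


def _read_sam_alignments(path: Path, mode: str, chrom_to_idx: dict[str, int]) -> ReadBatch:
    import pysam

    cols: dict[str, list] = {k: [] for k in ("chrom", "pos", "strand", "mapq", "len")}
    n_unknown = 0
    sample_id = path.stem
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.is_paired:
                # one record per template: first mate of a proper pair
                if not (a.is_proper_pair and a.is_read1):
                    continue
                eff = abs(a.template_length)
            else:
                eff = a.get_tag("OL") if a.has_tag("OL") else a.query_length
            ci = chrom_to_idx.get(a.reference_name)
            if ci is None:
                n_unknown += 1
                continue
            cols["chrom"].append(ci)
            cols["pos"].append(a.reference_start)
            cols["strand"].append(1 if a.is_reverse else 0)
            cols["mapq"].append(a.mapping_quality)
            cols["len"].append(eff)
    if n_unknown:
        logger.warning("%s: skipped %d reads on unmodeled chromosomes", path, n_unknown)
    batch = ReadBatch(
        sample_id=sample_id,
        chrom_idx=np.asarray(cols["chrom"], dtype=np.int16),
        pos=np.asarray(cols["pos"], dtype=np.int64),
        strand=np.asarray(cols["strand"], dtype=np.int8),
        mapq=np.asarray(cols["mapq"], dtype=np.int16),
        eff_length=np.asarray(cols["len"], dtype=np.int32),
    )
    batch.meta["n_unknown_chrom"] = n_unknown
    return batch


def read_alignments(path: str | Path, dialect: str | None = None) -> ReadBatch:
    """Load aligned reads from SAM, BAM or the tabular read-record dialect.

    One record per primary alignment; for paired-end input only the first
    mate of a proper pair yields a record, with eff_length = |TLEN|.
    Records on chromosomes outside the 24 modeled ones are skipped with a
    counted warning; a malformed file raises with context.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".sam": "sam", ".bam": "bam"}.get(suffix, "tsv")
    chrom_to_idx = {c: i for i, c in enumerate(CHROMS)}
    if dialect == "tsv":
        return _read_tsv_alignments(path, chrom_to_idx)
    if dialect in ("sam", "bam"):
        return _read_sam_alignments(path, "r" if dialect == "sam" else "rb", chrom_to_idx)
    raise ValueError(f"unknown dialect {dialect!r}")


def apply_quality_filters(
    batch: ReadBatch,
    min_mapq: int = 40,
    min_len: int = 35,
    dedupe: bool = True,
) -> tuple[ReadBatch, FilterStats]:
    """MAPQ/length filtering plus duplicate collapse.

    Retained reads satisfy mapq >= min_mapq and eff_length >= min_len; with
    ``dedupe`` on, reads sharing (chromosome, position, strand) collapse to
    the one with the highest (mapq, eff_length).  The three rules are
    applied jointly, so splitting the call into per-rule passes gives the
    same result in any order when duplicates are true copies.
    """
    if min_mapq < 0 or min_len < 0:
        raise ValueError("thresholds must be non-negative")
    stats = FilterStats(n_input=len(batch))
    ok_mapq = batch.mapq >= min_mapq
    ok_len = batch.eff_length >= min_len
    stats.n_mapq_removed = int((~ok_mapq).sum())
    stats.n_len_removed = int((ok_mapq & ~ok_len).sum())
    keep = ok_mapq & ok_len
    out = batch.take(keep)

    if dedupe and len(out):
        # canonical site key; pick the best (mapq, eff_length) per site.
        # single composite int64 sort: site in the high bits, inverted
        # mapq (6 bits) and inverted length (9 bits) below, so the first
        # record of each site run is its best representative.
        site = (
            out.chrom_idx.astype(np.int64) << 34
        ) | (out.pos << 1) | out.strand.astype(np.int64)
        composite = (
            (site << 15)
            | ((63 - np.minimum(out.mapq, 63).astype(np.int64)) << 9)
            | (511 - np.minimum(out.eff_length, 511).astype(np.int64))
        )
        order = np.argsort(composite, kind="stable")
        sorted_key = site[order]
        first = np.ones(len(sorted_key), dtype=bool)
        first[1:] = sorted_key[1:] != sorted_key[:-1]
        kept_idx = np.sort(order[first])
        stats.n_dup_removed = len(out) - len(kept_idx)
        out = out.take(kept_idx)

    stats.n_retained = len(out)
    return out, stats


def downsample(batch: ReadBatch, n_max: int = 3_000_000, seed: int | None = None) -> ReadBatch:
    """Uniform without-replacement cap at ``n_max`` reads (identity below it)."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if len(batch) <= n_max:
        return batch
    if seed is None:
        raise ValueError("downsampling requires a seed (reproducibility contract)")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(batch), size=n_max, replace=False))
    return batch.take(idx)


def count_reads(
    batch: ReadBatch,
    genome: GenomeModel,
    grid: tuple[int, ...] | None = None,
) -> BinCounts:
    """Tally reads into genome bins by leftmost position (half-open bins).

    With ``grid`` given, counts are additionally stratified into length
    classes so any inclusive length cutoff on the grid can be recovered
    without re-reading the records.  Reads positioned beyond their
    chromosome end are skipped with a counted warning.
    """
    if tuple(batch.chroms) != tuple(genome.chroms):
        raise ValueError("read batch and genome use different chromosome sets")
    valid = batch.pos < genome.lengths[batch.chrom_idx]
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%s: skipped %d reads beyond chromosome ends",
                       batch.sample_id, n_bad)
        batch = batch.take(valid)
    gb = genome.global_bin(batch.chrom_idx, batch.pos)
    n_bins = genome.n_bins
    if grid is None:
        counts = np.bincount(gb, minlength=n_bins).astype(float)
        return BinCounts(genome=genome, counts=counts,
                         meta={"n_out_of_range": n_bad, "sample_id": batch.sample_id})
    grid = tuple(int(g) for g in grid)
    edges = np.asarray(grid)
    cls = np.searchsorted(edges, batch.eff_length, side="left")  # len<=g[0] -> 0
    n_cls = len(grid) + 1
    flat = np.bincount(gb * n_cls + cls, minlength=n_bins * n_cls)
    by_length = flat.reshape(n_bins, n_cls).astype(float)
    return BinCounts(
        genome=genome,
        counts=by_length.sum(axis=1),
        by_length=by_length,
        grid=grid,
        meta={"n_out_of_range": n_bad, "sample_id": batch.sample_id},
    )
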