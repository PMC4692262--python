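import itertools

import numpy as np
import pandas as pd
import pytest

from nipt21 import (
    CHROMS,
    ReadBatch,
    apply_quality_filters,
    count_reads,
    downsample,
    read_alignments,
)


def make_batch(rows, sample_id="fx"):
    """rows: list of (chrom, pos, strand, mapq, eff_length)."""
    chrom_to_idx = {c: i for i, c in enumerate(CHROMS)}
    return ReadBatch(
        sample_id=sample_id,
        chrom_idx=np.array([chrom_to_idx[r[0]] for r in rows], dtype=np.int16),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        strand=np.array([0 if r[2] == "+" else 1 for r in rows], dtype=np.int8),
        mapq=np.array([r[3] for r in rows], dtype=np.int16),
        eff_length=np.array([r[4] for r in rows], dtype=np.int32),
    )


# ---------------------------------------------------------------- I/O


def test_tsv_roundtrip_preserves_records(tmp_path):
    rows = [
        ("chr1", 100, "+", 60, 150),
        ("chr2", 5_000, "-", 42, 166),
        ("chr21", 0, "+", 40, 143),
        ("chrX", 77, "-", 55, 200),
        ("chr14", 1234, "+", 60, 90),
    ]
    batch = make_batch(rows)
    path = tmp_path / "s.reads.tsv"
    batch.write_tsv(path)
    back = read_alignments(path)
    assert len(back) == 5
    pd.testing.assert_frame_equal(back.to_dataframe(), batch.to_dataframe())


def test_unknown_chromosome_skipped_with_count(tmp_path):
    path = tmp_path / "s.reads.tsv"
    df = pd.DataFrame(
        {
            "sample_id": ["s"] * 3,
            "chrom": ["chr1", "chrM", "chr2"],
            "pos": [1, 2, 3],
            "strand": ["+", "+", "-"],
            "mapq": [60, 60, 60],
            "eff_length": [100, 100, 100],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    back = read_alignments(path)
    assert len(back) == 2
    assert back.meta["n_unknown_chrom"] == 1


def test_malformed_tsv_raises_with_context(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample_id\tchrom\n")  # missing required columns
    with pytest.raises(ValueError, match="missing required columns"):
        read_alignments(path)


def test_sam_ingestion_flags_and_template_length(tmp_path):
    """Secondary alignments, unmapped reads and non-first mates are skipped;
    eff_length comes from |TLEN| for paired records."""
    import pysam

    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": 10_000_000} for c in CHROMS]}
    path = tmp_path / "fx.sam"

    def seg(name, flag, pos, mapq=60, tlen=0):
        a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
        a.query_name = name
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = mapq
        a.cigarstring = "50M" if not flag & 0x4 else None
        a.query_sequence = "A" * 50
        a.template_length = tlen
        return a

    with pysam.AlignmentFile(str(path), "w",
                             header=pysam.AlignmentHeader.from_dict(header)) as fh:
        fh.write(seg("pair_ok", 0x1 | 0x2 | 0x40, 100, tlen=-150))  # kept
        fh.write(seg("pair_mate2", 0x1 | 0x2 | 0x80, 100, tlen=150))  # mate 2
        fh.write(seg("secondary", 0x100, 500))  # secondary
        fh.write(seg("single", 0x0, 900))  # kept, single-end
        fh.write(seg("unmapped", 0x4, 0))

    batch = read_alignments(path)
    assert len(batch) == 2
    df = batch.to_dataframe().set_index("pos")
    assert df.loc[100, "eff_length"] == 150  # |TLEN -150|
    assert df.loc[900, "eff_length"] == 50  # single-end query length


# ---------------------------------------------------------------- filters


def test_mapq_and_length_thresholds_are_inclusive():
    batch = make_batch(
        [
            ("chr1", 1, "+", 39, 100),  # mapq below threshold
            ("chr1", 2, "+", 40, 35),  # exactly at both thresholds
            ("chr1", 3, "+", 60, 34),  # too short
        ]
    )
    out, stats = apply_quality_filters(batch)
    assert len(out) == 1 and out.pos[0] == 2
    assert stats.n_mapq_removed == 1 and stats.n_len_removed == 1


def test_duplicates_collapse_to_single_best_record():
    batch = make_batch(
        [
            ("chr3", 10, "+", 50, 120),
            ("chr3", 10, "+", 60, 120),  # same site, higher mapq wins
            ("chr3", 10, "-", 60, 120),  # other strand: distinct site
            ("chr3", 11, "+", 60, 120),  # other position
            ("chr4", 10, "+", 60, 120),  # other chromosome
            ("chr3", 10, "+", 50, 130),
        ]
    )
    out, stats = apply_quality_filters(batch)
    assert len(out) == 4
    assert stats.n_dup_removed == 2
    site = out.to_dataframe().query("chrom=='chr3' and pos==10 and strand=='+'")
    assert site["mapq"].tolist() == [60]


def test_filter_rules_commute_on_true_copy_duplicates():
    """With duplicates that are exact copies (the PCR-duplicate model),
    applying mapq/length/dedup in any order yields the same retained set."""
    rows = [
        ("chr1", 5, "+", 60, 150),
        ("chr1", 5, "+", 60, 150),
        ("chr1", 9, "-", 30, 150),
        ("chr1", 9, "-", 30, 150),
        ("chr2", 1, "+", 55, 20),
        ("chr2", 2, "+", 44, 80),
    ]
    batch = make_batch(rows)

    def signature(b):
        return sorted(map(tuple, b.to_dataframe().itertuples(index=False)))

    results = []
    steps = {
        "mapq": dict(min_mapq=40, min_len=0, dedupe=False),
        "len": dict(min_mapq=0, min_len=35, dedupe=False),
        "dedup": dict(min_mapq=0, min_len=0, dedupe=True),
    }
    for order in itertools.permutations(steps):
        b = batch
        for step in order:
            b, _ = apply_quality_filters(b, **steps[step])
        results.append(signature(b))
    assert all(r == results[0] for r in results)
    joint, _ = apply_quality_filters(batch)
    assert signature(joint) == results[0]


def test_empty_output_is_legal():
    batch = make_batch([("chr1", 1, "+", 10, 100)])
    out, stats = apply_quality_filters(batch)
    assert len(out) == 0 and stats.n_retained == 0


# ---------------------------------------------------------------- downsample


def test_downsample_caps_and_is_reproducible():
    batch = make_batch([("chr1", i, "+", 60, 100) for i in range(10)])
    d1 = downsample(batch, n_max=3, seed=1)
    d2 = downsample(batch, n_max=3, seed=1)
    assert len(d1) == 3
    np.testing.assert_array_equal(d1.pos, d2.pos)
    assert len(downsample(batch, n_max=3_000_000, seed=1)) == 10  # no-op
    with pytest.raises(ValueError, match="seed"):
        downsample(batch, n_max=3)


def test_downsample_preserves_chromosome_proportions(small_genome, rng):
    """Uniform subsampling leaves per-chromosome shares unbiased
    (chi-square goodness-of-fit not rejected at alpha = 0.001)."""
    from scipy.stats import chisquare

    n = 100_000
    probs = small_genome.lengths / small_genome.lengths.sum()
    ci = rng.choice(small_genome.n_chroms, size=n, p=probs).astype(np.int16)
    batch = ReadBatch(
        sample_id="x",
        chrom_idx=ci,
        pos=np.zeros(n, dtype=np.int64),
        strand=np.zeros(n, dtype=np.int8),
        mapq=np.full(n, 60, dtype=np.int16),
        eff_length=np.full(n, 150, dtype=np.int32),
    )
    sub = downsample(batch, n_max=30_000, seed=3)
    obs = np.bincount(sub.chrom_idx, minlength=24)
    exp = np.bincount(ci, minlength=24) / n * len(sub)
    keep = exp > 5
    _, p = chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
    assert p > 0.001


# ---------------------------------------------------------------- counting


def test_counts_match_manual_tally(small_genome):
    batch = make_batch(
        [("chr1", 0, "+", 60, 100)] * 3
        + [("chr2", 500, "-", 60, 100)] * 2
        + [("chr21", 999, "+", 60, 100)]
    )
    bins = count_reads(batch, small_genome)
    totals = bins.chrom_totals()
    assert totals["chr1"] == 3 and totals["chr2"] == 2 and totals["chr21"] == 1
    assert totals.sum() == 6


def test_empty_input_gives_zero_vector(small_genome):
    bins = count_reads(make_batch([]), small_genome)
    assert bins.counts.sum() == 0


def test_count_conservation_and_length_stratification(small_genome, rng):
    n = 10_000
    ci = rng.integers(0, 24, n).astype(np.int16)
    pos = (rng.random(n) * small_genome.lengths[ci]).astype(np.int64)
    batch = ReadBatch(
        sample_id="x", chrom_idx=ci, pos=pos,
        strand=np.zeros(n, dtype=np.int8),
        mapq=np.full(n, 60, dtype=np.int16),
        eff_length=rng.integers(50, 400, n).astype(np.int32),
    )
    grid = tuple(range(140, 185, 5))
    bins = count_reads(batch, small_genome, grid=grid)
    assert bins.counts.sum() == n  # conservation, exact
    np.testing.assert_allclose(bins.by_length.sum(axis=1), bins.counts)
    # cumulative class sums reproduce an inclusive length filter
    for cutoff in (140, 160, 180):
        direct = (batch.eff_length <= cutoff).sum()
        assert bins.counts_at_cutoff(cutoff).sum() == direct


def test_position_beyond_chromosome_end_skipped(small_genome):
    ln = int(small_genome.lengths[0])
    batch = make_batch([("chr1", ln + 10, "+", 60, 100),
                        ("chr1", ln - 1, "+", 60, 100)])
    bins = count_reads(batch, small_genome)
    assert bins.counts.sum() == 1
    assert bins.meta["n_out_of_range"] == 1
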