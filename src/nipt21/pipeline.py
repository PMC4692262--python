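"""End-to-end pipeline: simulate/ingest -> count -> correct -> score -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortCounts, DEFAULT_GRID, choose_training_samples, simulate_cohort_counts
from .gc import chr21_cv
from .genome import GenomeModel, build_genome_model
from .ingest import read_alignments
from .report import CohortMetrics, evaluate_cohort
from .simulate import CohortConfig, CohortTruth, TRISOMY21
from .sizesel import CutoffSweep, effective_ff_gain, sweep_cutoffs
from .zscore import (
    TrainingModel,
    estimate_fetal_fraction,
    score_matrix,
    train_model,
)

logger = logging.getLogger(__name__)

N_TRAINING_DEFAULT = 60


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, in memory."""

    truth: CohortTruth | None
    cohort: CohortCounts
    models: dict[int, TrainingModel]
    scores: pd.DataFrame  # all-reads scores, one row per (sample, method)
    sweep: CutoffSweep | None
    scores_selected: pd.DataFrame | None
    metrics: list[CohortMetrics] = field(default_factory=list)
    ff_table: pd.DataFrame | None = None
    ff_summary: dict | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def build_cohort_from_files(
    reads_dir: str | Path,
    genome: GenomeModel,
    grid=DEFAULT_GRID,
    max_reads: int = 3_000_000,
    seed: int | None = None,
) -> CohortCounts:
    """Ingest every read-record file in a directory into a counted cohort."""
    reads_dir = Path(reads_dir)
    paths = sorted(
        p for p in reads_dir.iterdir()
        if p.suffix in (".tsv", ".sam", ".bam") and "truth" not in p.name
    )
    if not paths:
        raise FileNotFoundError(f"no read-record files under {reads_dir}")
    truth = None
    truth_path = reads_dir / "truth.tsv"
    if truth_path.exists():
        truth = CohortTruth.read_tsv(truth_path)
    cohort = CohortCounts(genome=genome, grid=tuple(grid), truth=truth)
    for p in paths:
        batch = read_alignments(p)
        cohort.add_sample(batch, max_reads=max_reads, seed=seed)
    return cohort


def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    genome: GenomeModel | None = None,
    bin_size: int = 50_000,
    n_training: int = N_TRAINING_DEFAULT,
    grid=DEFAULT_GRID,
    methods: tuple[int, ...] = (1, 2, 3),
    sweep_method: int = 3,
    reads_dir: str | Path | None = None,
    span: float = 0.3,
) -> PipelineResult:
    """Drive the full analysis and (optionally) write a result bundle.

    Stages: simulate (or ingest ``reads_dir``) -> filter/count ->
    GC-correct -> train methods 1-3 on a euploid training set -> score all
    samples -> cutoff sweep -> rescore at the chosen cutoff -> effective
    fetal fractions -> sensitivity/specificity against truth.  Without a
    truth table the evaluation step is skipped with a warning.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config = CohortConfig.from_yaml(config_path)
    if seed is None:
        seed = config.seed
    if genome is None:
        genome = _stage("genome")(build_genome_model)(bin_size=bin_size)

    if reads_dir is not None:
        cohort = _stage("ingest")(build_cohort_from_files)(
            reads_dir, genome, grid=grid, max_reads=config.n_reads, seed=seed
        )
    else:
        cohort = _stage("simulate+count")(simulate_cohort_counts)(
            config, genome, seed=seed, grid=grid
        )
    truth = cohort.truth

    matrix = _stage("gc-correct")(cohort.chrom_matrix)(None, gc_mode="refit", span=span)

    if truth is not None:
        training_ids = choose_training_samples(truth, n_training, seed=seed)
        trisomic_ids = truth.ids(TRISOMY21)
    else:
        logger.warning("no truth table: training on all samples, no evaluation")
        training_ids = cohort.sample_ids[: max(2, len(cohort) // 2)]
        trisomic_ids = []
    training = matrix.subset(training_ids)

    min_ir = max(2, min(10, len(training_ids)))
    models = {
        m: _stage("train")(train_model)(training, m, min_ir_samples=min_ir)
        for m in methods
    }

    scores = pd.concat(
        [score_matrix(matrix, models[m]) for m in methods]
    ).reset_index().set_index(["sample_id", "method"])

    sweep = None
    scores_selected = None
    ff_table = None
    ff_summary = None
    metrics: list[CohortMetrics] = []
    if trisomic_ids:
        sweep = _stage("sweep")(sweep_cutoffs)(
            cohort, trisomic_ids, training_ids,
            grid=grid, method=sweep_method, span=span,
        )
        sel_matrix = cohort.chrom_matrix(sweep.chosen, gc_mode="refit", span=span)
        sel_training = sel_matrix.subset(training_ids)
        sel_models = {m: train_model(sel_training, m) for m in methods}
        scores_selected = pd.concat(
            [score_matrix(sel_matrix, sel_models[m], sweep.chosen) for m in methods]
        ).reset_index().set_index(["sample_id", "method"])

        # effective fetal fraction of confirmed trisomics (sweep method)
        m = sweep_method
        ff_all = pd.Series({
            sid: estimate_fetal_fraction(
                scores.loc[(sid, m), "ratio"], models[m], sid
            ).fetal_fraction
            for sid in trisomic_ids
        })
        ff_sel = pd.Series({
            sid: estimate_fetal_fraction(
                scores_selected.loc[(sid, m), "ratio"], sel_models[m],
                sid, sweep.chosen
            ).fetal_fraction
            for sid in trisomic_ids
        })
        ff_table, ff_summary = effective_ff_gain(ff_all, ff_sel)

        for m in methods:
            metrics.append(evaluate_cohort(
                scores.xs(m, level="method"), truth, method=m, cutoff=None
            ))
            metrics.append(evaluate_cohort(
                scores_selected.xs(m, level="method"), truth,
                method=m, cutoff=sweep.chosen,
            ))

    manifest = {
        "nipt21_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "bin_size": genome.bin_size,
        "n_training": len(training_ids),
        "grid": list(grid),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "per_sample_reads": {
            sid: log["filters"] for sid, log in cohort.filter_log.items()
        },
        "cv_before_after": {
            "uncorrected": chr21_cv(
                cohort.chrom_matrix(None, gc_mode="none").subset(training_ids),
                models[1].reference_set if 1 in models else ("chr14",),
            ),
            "corrected": models[1].cv if 1 in models else None,
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    result = PipelineResult(
        truth=truth, cohort=cohort, models=models, scores=scores,
        sweep=sweep, scores_selected=scores_selected, metrics=metrics,
        ff_table=ff_table, ff_summary=ff_summary, manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.truth is not None:
        result.truth.write_tsv(out_dir / "truth.tsv")
    for m, model in result.models.items():
        model.to_json(out_dir / f"model_method{m}.json")
    result.scores.reset_index().to_csv(out_dir / "scores_all_reads.tsv",
                                       sep="\t", index=False)
    if result.scores_selected is not None:
        result.scores_selected.reset_index().to_csv(
            out_dir / "scores_size_selected.tsv", sep="\t", index=False
        )
    if result.sweep is not None:
        result.sweep.table.to_csv(out_dir / "sweep.tsv", sep="\t")
    if result.ff_table is not None:
        result.ff_table.to_csv(out_dir / "fetal_fractions.tsv", sep="\t",
                               index_label="sample_id")
    if result.metrics:
        rows = []
        for met in result.metrics:
            d = asdict(met)
            d["sensitivity_ci_low"], d["sensitivity_ci_high"] = d.pop("sensitivity_ci")
            d["specificity_ci_low"], d["specificity_ci_high"] = d.pop("specificity_ci")
            rows.append(d)
        pd.DataFrame(rows).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    manifest = dict(result.manifest)
    manifest["artifacts"] = sorted(p.name for p in out_dir.iterdir())
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
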