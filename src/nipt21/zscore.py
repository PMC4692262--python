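"""The three z-score calculation methods and the internal-reference search.

All three methods score a test sample by the ratio r between its chr21
count and a reference denominator, standardized against a euploid training
set: z = (r - M) / S, where M and S are the mean and standard deviation of
the 60 training ratios.  A sample is called trisomic at z >= 3.

* method 1 — reference = all autosomes except chromosomes 13, 18 and 21
  (19 chromosomes; sex chromosomes excluded so scoring is fetal-sex
  independent);
* method 2 — reference = chromosome 14 alone;
* method 3 — reference = the chromosome combination with the lowest
  training CV (S/M), found by exhaustively enumerating every non-empty
  subset of the 19 eligible autosomes (a 2^19-combination search space).

The fetal fraction of a trisomic sample follows from the same ratio: an
extra fetal chr21 copy lifts r by a factor (1 + ff/2), so
ff = 2 (r - M) / M, equivalently ff = 2 * z * CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import CHR21, ELIGIBLE_IR_CHROMS
from .ingest import CountMatrix

Z_CUTOFF = 3.0

METHOD1_REFERENCE: tuple[str, ...] = ELIGIBLE_IR_CHROMS
METHOD2_REFERENCE: tuple[str, ...] = ("chr14",)


@dataclass
class IRSelection:
    """Outcome of the exhaustive internal-reference (IR) search."""

    chosen: tuple[str, ...]
    cv: float
    n_evaluated: int
    search_space: int
    runner_up_cv: float


@dataclass
class TrainingModel:
    """Euploid reference model for one z-score method."""

    method: int
    reference_set: tuple[str, ...]
    ratios: pd.Series  # per training sample
    mean: float
    sd: float
    cv: float
    training_ids: tuple[str, ...]
    ir_selection: IRSelection | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "reference_set": list(self.reference_set),
                "mean": self.mean,
                "sd": self.sd,
                "cv": self.cv,
                "training_ids": list(self.training_ids),
                "ratios": {k: float(v) for k, v in self.ratios.items()},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainingModel":
        d = json.loads(Path(path).read_text())
        ratios = pd.Series(d["ratios"])
        return cls(
            method=int(d["method"]),
            reference_set=tuple(d["reference_set"]),
            ratios=ratios,
            mean=float(d["mean"]),
            sd=float(d["sd"]),
            cv=float(d["cv"]),
            training_ids=tuple(d["training_ids"]),
        )


@dataclass
class ZScoreResult:
    """Per-sample, per-method z value and ploidy call."""

    sample_id: str
    method: int
    cutoff: int | None
    ratio: float
    z: float
    call: str = field(init=False)

    def __post_init__(self):
        self.call = "trisomy21" if self.z >= Z_CUTOFF else "euploid"


@dataclass
class FetalFractionEstimate:
    sample_id: str
    fetal_fraction: float  # signed fraction; negative estimates are flagged
    mode: str  # 'all_reads' or 'size_selected(<cutoff>)'

    @property
    def flagged_negative(self) -> bool:
        return self.fetal_fraction < 0


def _chrom_number(name: str) -> int:
    return int(name.replace("chr", ""))


def reference_ratio(
    counts: pd.Series,
    method: int,
    ir_set: tuple[str, ...] | None = None,
    sample_id: str = "?",
) -> float:
    """chr21 / reference-denominator ratio under one of the three methods."""
    if method == 1:
        ref = METHOD1_REFERENCE
    elif method == 2:
        ref = METHOD2_REFERENCE
    elif method == 3:
        if ir_set is None:
            raise ValueError("method 3 requires an internal-reference set")
        ref = tuple(ir_set)
    else:
        raise ValueError(f"method must be 1, 2 or 3, got {method}")
    denom = float(counts[list(ref)].sum())
    if denom <= 0:
        raise ZeroDivisionError(
            f"zero reference denominator for sample {sample_id!r}, method {method}"
        )
    return float(counts[CHR21]) / denom


def _subset_sums(cols: np.ndarray) -> np.ndarray:
    """All-subset column sums by bit-indexed dynamic programming.

    ``cols`` is (k, n_samples); returns (2^k, n_samples) where row m is the
    sum of the columns whose bit is set in m.  Row 0 is all-zero (empty set).
    """
    k, n = cols.shape
    out = np.zeros((1 << k, n), dtype=np.float64)
    for b in range(k):
        lo, hi = 1 << b, 1 << (b + 1)
        out[lo:hi] = out[:lo] + cols[b]
    return out


def select_internal_reference(
    training: CountMatrix,
    universe: tuple[str, ...] = ELIGIBLE_IR_CHROMS,
    min_samples: int = 10,
) -> IRSelection:
    """Exhaustive CV-optimal internal-reference search.

    Evaluates every non-empty subset of ``universe`` (2^k - 1 candidates;
    the full eligible universe of 19 autosomes gives the 2^19 search
    space): per training sample the ratio chr21 / subset sum, then
    CV = S/M over samples; the subset with the lowest CV wins, ties going
    to the lexicographically smallest set by chromosome number.
    """
    n_s = len(training.data)
    if n_s < min_samples:
        raise ValueError(f"need >= {min_samples} training samples, got {n_s}")
    universe = tuple(universe)
    k = len(universe)

    sub = training.data[list(universe)]
    zero_rows = sub.index[(sub <= 0).any(axis=1)]
    if len(zero_rows):
        raise ZeroDivisionError(
            "training sample(s) with zero count on an eligible autosome: "
            f"{list(zero_rows)}"
        )

    cols = sub.to_numpy(dtype=np.float64).T  # (k, n_samples)
    c21 = training.data[CHR21].to_numpy(dtype=np.float64)

    sums = _subset_sums(cols)
    ratios = c21[None, :] / sums[1:]  # skip the empty set
    m = ratios.mean(axis=1)
    s = ratios.std(axis=1, ddof=1)
    cv = s / m

    order = np.argsort(cv, kind="stable")
    best_cv = cv[order[0]]
    tied = np.flatnonzero(cv == best_cv) + 1  # back to mask indexing
    masks_as_sets = [
        tuple(sorted(_chrom_number(universe[b]) for b in range(k) if mask >> b & 1))
        for mask in tied
    ]
    best_mask = int(tied[min(range(len(tied)), key=masks_as_sets.__getitem__)])
    chosen = tuple(
        sorted(
            (universe[b] for b in range(k) if best_mask >> b & 1),
            key=_chrom_number,
        )
    )
    runner_up = float(cv[order[1]]) if len(cv) > 1 else float("nan")
    return IRSelection(
        chosen=chosen,
        cv=float(best_cv),
        n_evaluated=(1 << k) - 1,
        search_space=1 << k,
        runner_up_cv=runner_up,
    )


def train_model(
    training: CountMatrix,
    method: int,
    ir_selection: IRSelection | None = None,
    min_ir_samples: int = 10,
) -> TrainingModel:
    """Fit M, S and CV of the training ratios under one method.

    Method 3 runs :func:`select_internal_reference` first unless a
    pre-computed selection is supplied.
    """
    if len(training.data) < 2:
        raise ValueError("need >= 2 training samples (S undefined)")
    ir_set = None
    if method == 3:
        if ir_selection is None:
            ir_selection = select_internal_reference(
                training, min_samples=min_ir_samples
            )
        ir_set = ir_selection.chosen
    ratios = pd.Series(
        {
            sid: reference_ratio(training.data.loc[sid], method, ir_set, sid)
            for sid in training.sample_ids
        }
    )
    m = float(np.mean(ratios.to_numpy()))
    s = float(np.std(ratios.to_numpy(), ddof=1))
    if method == 1:
        ref = METHOD1_REFERENCE
    elif method == 2:
        ref = METHOD2_REFERENCE
    else:
        ref = ir_set
    return TrainingModel(
        method=method,
        reference_set=tuple(ref),
        ratios=ratios,
        mean=m,
        sd=s,
        cv=s / m,
        training_ids=tuple(training.sample_ids),
        ir_selection=ir_selection if method == 3 else None,
    )


def z_score(
    sample_counts: pd.Series,
    model: TrainingModel,
    sample_id: str = "?",
    cutoff: int | None = None,
) -> ZScoreResult:
    """Standardized chr21 representation of one sample; call at z >= 3."""
    if model.sd == 0:
        raise ZeroDivisionError("degenerate training model: S = 0")
    ir = model.reference_set if model.method == 3 else None
    r = reference_ratio(sample_counts, model.method, ir, sample_id)
    z = (r - model.mean) / model.sd
    return ZScoreResult(sample_id=sample_id, method=model.method,
                        cutoff=cutoff, ratio=r, z=z)


def score_matrix(
    matrix: CountMatrix, model: TrainingModel, cutoff: int | None = None
) -> pd.DataFrame:
    """Score every sample of a count matrix; one row per sample."""
    rows = [
        z_score(matrix.data.loc[sid], model, sid, cutoff)
        for sid in matrix.sample_ids
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "method": [r.method for r in rows],
            "cutoff": [r.cutoff for r in rows],
            "ratio": [r.ratio for r in rows],
            "z": [r.z for r in rows],
            "call": [r.call for r in rows],
        }
    ).set_index("sample_id")


def estimate_fetal_fraction(
    ratio: float,
    model: TrainingModel,
    sample_id: str = "?",
    cutoff: int | None = None,
    reference_stat: str = "mean",
) -> FetalFractionEstimate:
    """Fetal fraction from the chr21 ratio of a trisomic sample.

    ff = 2 (r - M) / M with M the training mean (default), which keeps the
    identity ff = 2 * z * CV exact; ``reference_stat='median'`` substitutes
    the training median as the reference level.
    """
    if reference_stat == "mean":
        ref = model.mean
    elif reference_stat == "median":
        ref = float(model.ratios.median())
    else:
        raise ValueError("reference_stat must be 'mean' or 'median'")
    if ref <= 0:
        raise ValueError("non-positive training reference level")
    ff = 2.0 * (ratio - ref) / ref
    mode = "all_reads" if cutoff is None else f"size_selected({cutoff})"
    return FetalFractionEstimate(sample_id=sample_id, fetal_fraction=ff, mode=mode)
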