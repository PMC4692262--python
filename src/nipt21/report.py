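"""Cohort performance metrics with exact binomial confidence intervals."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import beta

from .simulate import CohortTruth, TRISOMY21


def exact_binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    Obtained by inverting the binomial CDF via beta quantiles; at the
    boundary successes = trials the lower bound has the closed form
    (alpha/2)^(1/trials) and the upper bound is 1.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    if not 0.0 <= lower <= upper <= 1.0:
        raise ValueError("confidence bounds out of order")
    return lower, upper


@dataclass
class CohortMetrics:
    """Confusion counts plus sensitivity/specificity with 95% exact CIs.

    Undefined proportions on degenerate cohorts (no positives or no
    negatives in truth) are reported as NaN, not raised.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    method: int | None = None
    cutoff: int | None = None

    def to_json(self) -> str:
        d = asdict(self)
        d["cutoff_mode"] = "all_reads" if self.cutoff is None else f"<= {self.cutoff} bp"
        return json.dumps(d, indent=2)


def evaluate_cohort(
    results: pd.DataFrame,
    truth: CohortTruth,
    method: int | None = None,
    cutoff: int | None = None,
    level: float = 0.95,
) -> CohortMetrics:
    """Compare per-sample calls against truth.

    ``results`` is a score table indexed by sample id with a ``call``
    column (as produced by :func:`nipt21.zscore.score_matrix`).
    """
    if results.empty:
        raise ValueError("empty result set")
    truth_ids = set(truth.ids())
    unknown = sorted(set(results.index) - truth_ids)
    if unknown:
        raise ValueError(f"result sample ids missing from truth: {unknown}")

    status = {s.sample_id: s.status for s in truth.samples}
    is_pos = np.array([status[sid] == TRISOMY21 for sid in results.index])
    called_pos = (results["call"] == TRISOMY21).to_numpy()

    tp = int((is_pos & called_pos).sum())
    fn = int((is_pos & ~called_pos).sum())
    fp = int((~is_pos & called_pos).sum())
    tn = int((~is_pos & ~called_pos).sum())

    if tp + fn > 0:
        sens = tp / (tp + fn)
        sens_ci = exact_binomial_ci(tp, tp + fn, level)
    else:
        sens, sens_ci = math.nan, (math.nan, math.nan)
    if tn + fp > 0:
        spec = tn / (tn + fp)
        spec_ci = exact_binomial_ci(tn, tn + fp, level)
    else:
        spec, spec_ci = math.nan, (math.nan, math.nan)

    return CohortMetrics(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci,
        method=method, cutoff=cutoff,
    )
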