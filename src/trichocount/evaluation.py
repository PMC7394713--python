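"""Validation of counting methods against reference counts.

A counting method is judged the way manual-versus-automated comparisons are
reported in plant phenotyping: ordinary least squares of the predicted
counts on the reference counts (R-squared and the two-sided P-value of the
slope), the root-mean-square error of the raw differences, and the two group
means.  RMSE is computed on ``predicted - reference`` directly, not on
regression residuals, so a systematic over- or under-count shows up in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError

__all__ = ["EvalReport", "evaluate_counts", "evaluate_by_group"]


@dataclass(frozen=True)
class EvalReport:
    """Agreement statistics between predicted and reference counts."""

    n: int
    r_squared: float
    p_value: float
    rmse: float
    mean_predicted: float
    mean_reference: float
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_counts(predicted, reference) -> EvalReport:
    """OLS regression of predicted on reference counts plus raw-error RMSE.

    Requires at least 3 pairs and a non-constant reference.
    """
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise EvaluationError(
            f"predicted and reference must be equal-length 1-D sequences "
            f"(got {pred.shape} vs {ref.shape})"
        )
    if pred.size < 3:
        raise EvaluationError("need at least 3 pairs to evaluate")
    if np.ptp(ref) == 0:
        raise EvaluationError("reference counts are constant; regression undefined")
    fit = stats.linregress(ref, pred)
    return EvalReport(
        n=int(pred.size),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        rmse=float(np.sqrt(np.mean((pred - ref) ** 2))),
        mean_predicted=float(pred.mean()),
        mean_reference=float(ref.mean()),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def evaluate_by_group(
    manifest: pd.DataFrame,
    results: pd.DataFrame,
    group_key: str,
    id_key: str = "scene_id",
    predicted_col: str = "count",
    reference_col: str = "truth_count",
) -> dict:
    """One :class:`EvalReport` per group (repetition, genotype, noise level...).

    ``manifest`` holds the reference counts and grouping column; ``results``
    holds the predicted counts; the two are joined on ``id_key``.  Groups
    with fewer than 3 usable pairs, or a constant reference, are skipped
    with a warning.
    """
    for df, cols, name in (
        (manifest, {id_key, reference_col, group_key}, "manifest"),
        (results, {id_key, predicted_col}, "results"),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise EvaluationError(f"{name} is missing columns {sorted(missing)}")
    merged = manifest.merge(results, on=id_key, suffixes=("_ref", "_pred"))
    ref_col = reference_col if reference_col in merged else f"{reference_col}_ref"
    pred_col = predicted_col if predicted_col in merged else f"{predicted_col}_pred"
    reports: dict = {}
    for group, sub in merged.groupby(group_key):
        try:
            reports[group] = evaluate_counts(sub[pred_col], sub[ref_col])
        except EvaluationError as exc:
            warnings.warn(f"group {group!r} skipped: {exc}")
    return reports
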