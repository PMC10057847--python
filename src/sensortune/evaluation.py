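"""Accuracy metrics for engineered-sensor benchmarks.

The primary statistic is the fold-accuracy, exp[RMSE(ln x)]: the
root-mean-square difference between log predicted (or targeted) and
log actual parameter values, exponentiated back to a fold factor.  A
fold-accuracy of 1.0 is perfect; 2.0 means predictions are off by
2-fold in RMS.  It is complemented by the fraction of variants whose
prediction lands within k-fold of the actual value, and by the slope
of the ln-ln regression of actual on predicted (systematic bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .hill import HillPosterior
from .selection import SelectionResult

__all__ = [
    "fold_accuracy",
    "within_fold_fraction",
    "AccuracyReport",
    "evaluate_selection",
]


def _check_pairs(predicted, actual):
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 1:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    if np.any(p <= 0) or np.any(a <= 0):
        raise ValueError("fold metrics require strictly positive values")
    return p, a


def fold_accuracy(predicted, actual) -> float:
    """exp[RMSE(ln actual - ln predicted)]; >= 1, symmetric, scale-free."""
    p, a = _check_pairs(predicted, actual)
    return float(np.exp(np.sqrt(np.mean((np.log(a) - np.log(p)) ** 2))))


def within_fold_fraction(predicted, actual, k: float) -> float:
    """Fraction of pairs agreeing within k-fold (max ratio <= k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p, a = _check_pairs(predicted, actual)
    return float(np.mean(np.abs(np.log(a) - np.log(p)) <= np.log(k)))


@dataclass
class AccuracyReport:
    """Per-parameter accuracy summary of a selection or prediction run."""

    fold_accuracy: dict[str, float]
    within_k_fraction: dict[str, float]
    k: float
    residuals: pd.DataFrame  # per-variant ln(actual/predicted) per parameter
    bias_slope: dict[str, float]

    def __post_init__(self) -> None:
        for p, fa in self.fold_accuracy.items():
            if fa < 1.0 - 1e-12:
                raise ValueError(f"fold accuracy for {p} below 1: {fa}")

    def summary_frame(self) -> pd.DataFrame:
        params = list(self.fold_accuracy)
        return pd.DataFrame(
            {
                "parameter": params,
                "fold_accuracy": [self.fold_accuracy[p] for p in params],
                f"within_{self.k:g}_fold": [self.within_k_fraction[p] for p in params],
                "bias_slope": [self.bias_slope.get(p, np.nan) for p in params],
            }
        )


def _report(pred: dict[str, np.ndarray], act: dict[str, np.ndarray], variants, k):
    fa, wf, slopes = {}, {}, {}
    resid = {"variant": list(variants)}
    for p in pred:
        fa[p] = fold_accuracy(pred[p], act[p])
        wf[p] = within_fold_fraction(pred[p], act[p], k)
        resid[p] = np.log(act[p]) - np.log(pred[p])
        lx = np.log(pred[p])
        if np.unique(lx).size >= 2:
            slopes[p] = float(stats.linregress(lx, np.log(act[p])).slope)
        else:
            slopes[p] = float("nan")
    return AccuracyReport(
        fold_accuracy=fa,
        within_k_fraction=wf,
        k=k,
        residuals=pd.DataFrame(resid),
        bias_slope=slopes,
    )


def evaluate_selection(
    result: SelectionResult,
    measured: Mapping[str, HillPosterior],
    mode: str = "selection",
    k: float = 2.0,
) -> AccuracyReport:
    """Score a selection against follow-up measurements.

    mode="selection": actual (measured posterior-median) parameters are
    compared against the specification targets, for the parameters the
    spec targets (EC50 and/or Ginf).
    mode="validation": measured medians are compared against the
    landscape medians of the selected records, for EC50, Ginf and G0.
    Missing measurements raise an error listing the variants.
    """
    if mode not in ("selection", "validation"):
        raise ValueError("mode must be 'selection' or 'validation'")
    if len(result) == 0:
        raise ValueError("empty selection result")
    missing = [v for v in result.variants if v not in measured]
    if missing:
        raise ValueError(f"missing measurements for variants: {missing}")

    meas = {
        v: measured[v].median_params() for v in result.variants
    }
    if mode == "selection":
        pred: dict[str, list] = {}
        act: dict[str, list] = {}
        spec = result.spec
        for rec, _ in result.entries:
            m = meas[rec.variant]
            if spec.ec50_target is not None:
                pred.setdefault("ec50", []).append(spec.ec50_target)
                act.setdefault("ec50", []).append(m.ec50)
            if spec.ginf_target is not None:
                pred.setdefault("ginf", []).append(spec.ginf_target)
                act.setdefault("ginf", []).append(m.ginf)
        if not pred:
            raise ValueError("specification has no targeted parameters to score")
    else:
        pred, act = {"ec50": [], "ginf": [], "g0": []}, {"ec50": [], "ginf": [], "g0": []}
        for rec, _ in result.entries:
            land = rec.posterior.median_params()
            m = meas[rec.variant]
            for p in pred:
                pred[p].append(getattr(land, p))
                act[p].append(getattr(m, p))
    pred = {p: np.asarray(v, dtype=float) for p, v in pred.items()}
    act = {p: np.asarray(v, dtype=float) for p, v in act.items()}
    return _report(pred, act, result.variants, k)
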