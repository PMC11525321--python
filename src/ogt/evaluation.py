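"""Scoring ground truths against scalar references and simulator truth.

A continuous ground truth is validated *concurrently*: reduce each stimulus's
signal to a scalar with an aggregation function (min, max, mean, median, sum)
and rank-correlate those scalars with reference ratings (e.g. a 1-5 violence
rating per movie).  Spearman with average ranks is used throughout because
the ordinal-embedding values carry rank information only — any strictly
increasing rescaling of the ground truth must (and does) leave the score
unchanged.  Against simulator truth, per-signal Kendall tau and SDA quantify
how well a candidate tracks the latent construct dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .agreement import sda
from .errors import DegenerateInputError, ShapeError, UndefinedMetricError
from .ordinal_fusion import GroundTruth

__all__ = [
    "AGGREGATIONS",
    "EvaluationReport",
    "aggregate",
    "score_against_ratings",
    "evaluation_report",
    "tau_against_truth",
]

AGGREGATIONS = ("min", "max", "mean", "median", "sum")

_FUNCS = {
    "min": np.nanmin,
    "max": np.nanmax,
    "mean": np.nanmean,
    "median": np.nanmedian,
    "sum": np.nansum,
}


@dataclass
class EvaluationReport:
    """Per-stimulus aggregates and their rank correlation with references."""

    aggregates: dict[str, dict[str, float]]  # fn -> stimulus -> value
    spearman: dict[str, float]  # fn -> rho vs reference ratings
    per_signal: dict[str, dict[str, float]] = field(default_factory=dict)


def aggregate(gt: GroundTruth | np.ndarray, fn: str) -> float:
    """Apply a named many-to-one function over the non-missing samples."""
    if fn not in AGGREGATIONS:
        raise UndefinedMetricError(f"unknown aggregation {fn!r}; use one of {AGGREGATIONS}")
    values = gt.values if isinstance(gt, GroundTruth) else np.asarray(gt, dtype=float)
    if not np.any(~np.isnan(values)):
        raise DegenerateInputError("all samples missing")
    return float(_FUNCS[fn](values))


def score_against_ratings(
    aggregates: Mapping[str, float],
    ratings: Mapping[str, float],
) -> float:
    """Spearman rho (average-rank ties) between aggregates and reference ratings.

    Stimuli are matched by id; both mappings must cover at least 3 common
    stimuli.  A constant vector has no ranking and raises
    :class:`UndefinedMetricError`.
    """
    common = sorted(set(aggregates) & set(ratings))
    if len(common) < 3:
        raise ShapeError(f"need >= 3 common stimuli, got {len(common)}")
    x = np.array([aggregates[s] for s in common])
    y = np.array([ratings[s] for s in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("constant vector; Spearman undefined")
    return float(stats.spearmanr(x, y).statistic)


def tau_against_truth(candidate: np.ndarray, truth: np.ndarray) -> float:
    """Kendall tau-b between a candidate ground truth and the latent signal."""
    candidate = np.asarray(candidate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if candidate.shape != truth.shape:
        raise ShapeError("candidate and truth must share a grid")
    ok = ~np.isnan(candidate) & ~np.isnan(truth)
    if ok.sum() < 2:
        raise DegenerateInputError("fewer than 2 comparable samples")
    tau = stats.kendalltau(candidate[ok], truth[ok]).statistic
    return float(tau)


def evaluation_report(
    ground_truths: Mapping[str, GroundTruth],
    ratings: Mapping[str, float] | None = None,
    truths: Mapping[str, np.ndarray] | None = None,
) -> EvaluationReport:
    """All five aggregations per stimulus, plus the available comparisons.

    ``ratings`` enables the Spearman-vs-reference scores; ``truths`` (latent
    simulator signals keyed by stimulus) enables per-signal tau and SDA.
    """
    aggs = {
        fn: {s: aggregate(gt, fn) for s, gt in ground_truths.items()}
        for fn in AGGREGATIONS
    }
    spearman: dict[str, float] = {}
    if ratings is not None:
        for fn in AGGREGATIONS:
            try:
                spearman[fn] = score_against_ratings(aggs[fn], ratings)
            except (ShapeError, UndefinedMetricError):
                spearman[fn] = float("nan")
    per_signal: dict[str, dict[str, float]] = {}
    if truths is not None:
        for s, gt in ground_truths.items():
            if s not in truths:
                continue
            per_signal[s] = {
                "kendall_tau": tau_against_truth(gt.values, truths[s]),
                "sda": sda(gt.values, np.asarray(truths[s], dtype=float)),
            }
    return EvaluationReport(aggs, spearman, per_signal)
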