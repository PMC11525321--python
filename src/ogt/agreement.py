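"""Trend-based and classical agreement between continuous annotations.

The workhorse is *signed differential agreement* (SDA): for each grid step the
signs of the two signals' successive differences are compared, scoring +1 when
they match and -1 when they do not, and the scores are averaged over the valid
steps.  SDA is therefore blind to each rater's personal value scale — any
strictly increasing transform of a signal leaves its difference signs, and
hence its SDA with anything else, unchanged — which is exactly the property a
trend-trusting pipeline needs.  Steps touching a missing (NaN) sample are
dropped and the average renormalizes over the remaining steps.

Classical interval-scale measures (correlations, Cronbach's alpha, ICC(3,k),
interval Krippendorff's alpha) are provided for reporting and for the
Kendall-tau leg of the segment-budget heuristic; they are standard textbook
definitions delegated to scipy/pingouin where possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import Annotation
from .errors import ShapeError, UndefinedAgreementError, UndefinedMetricError

__all__ = [
    "AgreementMatrix",
    "sda",
    "sda_matrix",
    "classical_agreement",
    "krippendorff_alpha_interval",
    "CLASSICAL_METRICS",
]

#: Default tolerance below which a successive difference counts as "no change".
ZERO_TOL = 1e-9


@dataclass
class AgreementMatrix:
    """Symmetric table of pairwise agreement values with annotator ids."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = "sda"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def mean_offdiagonal(self, i: int) -> float:
        """Mean agreement of annotator ``i`` with everyone else (NaN-aware)."""
        row = np.delete(self.values[i], i)
        return float(np.nanmean(row)) if np.any(~np.isnan(row)) else np.nan


def _signs(x: np.ndarray, zero_tol: float) -> np.ndarray:
    d = np.diff(x)
    s = np.sign(d)
    s[np.abs(d) <= zero_tol] = 0.0
    return s


def sda(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    zero_tol: float = ZERO_TOL,
) -> float:
    """Signed differential agreement between two equal-length signals.

    Returns ``(1/M) * sum_t delta(sgn(x_t - x_{t-1}), sgn(y_t - y_{t-1}))``
    where ``delta`` is +1 on equal signs and -1 otherwise, differences of
    magnitude <= ``zero_tol`` have sign 0, and the M valid steps exclude any
    step whose four involved samples are not all present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"signals must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise UndefinedAgreementError("need at least 2 samples")
    sx, sy = _signs(x, zero_tol), _signs(y, zero_tol)
    valid = ~np.isnan(x[1:]) & ~np.isnan(x[:-1]) & ~np.isnan(y[1:]) & ~np.isnan(y[:-1])
    m = int(valid.sum())
    if m == 0:
        raise UndefinedAgreementError("no step with all four samples present")
    agree = np.where(sx[valid] == sy[valid], 1.0, -1.0)
    return float(agree.sum() / m)


def sda_matrix(
    annotations: Sequence[Annotation],
    pair_aligner: Callable[[Annotation, Annotation], tuple[Annotation, Annotation]]
    | None = None,
    zero_tol: float = ZERO_TOL,
) -> AgreementMatrix:
    """Pairwise SDA over a set of annotations of the same stimulus.

    ``pair_aligner`` (e.g. a seeded DTW hook from :mod:`ogt.align_select`) is
    applied to each unordered pair before measuring agreement.  Pairs on which
    SDA is undefined get a NaN entry; downstream selection imputes these.
    """
    if len(annotations) < 2:
        raise ShapeError("need at least 2 annotations")
    n = len(annotations)
    ids = [a.annotator_id for a in annotations]
    out = np.eye(n)
    for i, j in combinations(range(n), 2):
        a, b = annotations[i], annotations[j]
        if pair_aligner is not None:
            a, b = pair_aligner(a, b)
        try:
            v = sda(a.values, b.values, zero_tol=zero_tol)
        except UndefinedAgreementError:
            v = np.nan
        out[i, j] = out[j, i] = v
    return AgreementMatrix(ids, out, metric_name="sda")


def krippendorff_alpha_interval(table: np.ndarray) -> float:
    """Krippendorff's alpha with the interval metric ``(a - b)^2``.

    ``table`` is raters x units with NaN for missing cells.  Units with fewer
    than two ratings do not contribute to observed disagreement; expected
    disagreement pools every pairable value.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ShapeError("table must be raters x units")
    pairable = ~np.isnan(table)
    m_u = pairable.sum(axis=0)
    use = m_u >= 2
    if not np.any(use):
        raise UndefinedMetricError("no unit has two or more ratings")
    values = table[:, use]
    m_u = m_u[use]
    n_total = int(m_u.sum())

    d_o = 0.0
    for u in range(values.shape[1]):
        col = values[:, u]
        col = col[~np.isnan(col)]
        diffs = (col[:, None] - col[None, :]) ** 2
        d_o += diffs.sum() / (m_u[u] - 1)
    d_o /= n_total

    pool = values[~np.isnan(values)]
    diffs = (pool[:, None] - pool[None, :]) ** 2
    d_e = diffs.sum() / (n_total * (n_total - 1))
    if d_e == 0:
        raise UndefinedMetricError("all pairable values identical; alpha undefined")
    return float(1.0 - d_o / d_e)


def _cronbach_alpha(table: np.ndarray) -> float:
    # items = raters, observations = time samples; variance-ratio definition
    k = table.shape[0]
    if k < 2:
        raise UndefinedMetricError("Cronbach's alpha needs >= 2 raters")
    item_vars = table.var(axis=1, ddof=1)
    total_var = table.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise UndefinedMetricError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def _icc_3k(table: np.ndarray) -> float:
    import pingouin as pg

    k, n = table.shape
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "score": table.T.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=df, targets="targets", raters="raters", ratings="score"
    )
    # consistency, average of k raters; pingouin labels this ICC3k or ICC(C,k)
    sel = res.loc[res["Type"].isin(["ICC3k", "ICC(C,k)"]), "ICC"]
    return float(sel.iloc[0])


CLASSICAL_METRICS = (
    "kendall_tau",
    "pearson",
    "spearman",
    "cronbach_alpha",
    "icc_3k",
    "krippendorff_alpha_interval",
)


def classical_agreement(
    annotations: Sequence[Annotation] | Sequence[Sequence[float]],
    metric: str = "pearson",
) -> float:
    """Classical agreement/reliability over complete-case samples.

    Pairwise metrics (``kendall_tau``, ``pearson``, ``spearman``) require
    exactly two annotations; the multi-rater ones accept any number >= 2.
    Rows (time samples) containing a missing value are dropped for the
    pairwise and Cronbach/ICC metrics; Krippendorff's alpha keeps partial
    units.  Raises :class:`UndefinedMetricError` on degenerate input.
    """
    if metric not in CLASSICAL_METRICS:
        raise UndefinedMetricError(f"unknown metric {metric!r}")
    rows = [
        np.asarray(a.values if isinstance(a, Annotation) else a, dtype=float)
        for a in annotations
    ]
    if len(rows) < 2:
        raise ShapeError("need at least 2 annotations")
    if len({r.size for r in rows}) != 1:
        raise ShapeError("annotations must share a grid")
    table = np.vstack(rows)

    if metric == "krippendorff_alpha_interval":
        return krippendorff_alpha_interval(table)

    table = table[:, ~np.isnan(table).any(axis=0)]
    if table.shape[1] < 2:
        raise UndefinedMetricError("fewer than 2 complete-case samples")
    if metric in ("kendall_tau", "pearson", "spearman"):
        if table.shape[0] != 2:
            raise ShapeError(f"{metric} is pairwise; got {table.shape[0]} annotations")
        x, y = table
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedMetricError(f"constant input; {metric} undefined")
        if metric == "kendall_tau":
            return float(stats.kendalltau(x, y).statistic)
        if metric == "pearson":
            return float(stats.pearsonr(x, y).statistic)
        return float(stats.spearmanr(x, y).statistic)
    if metric == "cronbach_alpha":
        return _cronbach_alpha(table)
    return _icc_3k(table)
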