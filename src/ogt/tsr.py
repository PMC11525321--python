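"""Trapezoidal segmented regression (TSR) and trend-code extraction.

A trapezoidal segmented signal is a continuous piecewise-linear function whose
segments strictly alternate between *flat* (slope exactly zero) and *sloped*
(a free linear piece).  Fitting one to an annotation separates what raters
report reliably — the direction of change — from what they report unreliably —
the values — because the fit's per-sample slope signs form a trend code
sequence (TSS) over {-1, 0, +1} that downstream voting and ordinal machinery
consume.

The fit is an exact dynamic program over a finite search space, pinned as the
package's contract:

* breakpoints are restricted to sample indices;
* breakpoint values are restricted to a finite *level grid* — the unique
  sample values plus the sample mean (the mean guarantees the T=1 fit is the
  exact least-squares constant);
* both parities (first segment flat or first segment sloped) are searched and
  the better kept; ``T`` counts all segments of either kind.

Within that space the DP returns the global least-squares optimum for every
segment budget up to ``T`` in a single pass, which the budget-selection
heuristic exploits.  Any trapezoid whose corners lie on the sample grid is
representable (corner values are themselves samples), so realizable inputs
are recovered with zero error.  "Sloped" segments may degenerate to zero
slope in an optimal fit; their trend code is then 0, consistent with reading
codes off slope signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .agreement import sda
from .errors import BudgetTooLargeError, DegenerateInputError, ShapeError

__all__ = [
    "TSRModel",
    "TSS",
    "SegmentBudget",
    "fit_tsr",
    "fit_tsr_all",
    "estimate_T_hat",
    "select_segment_count",
    "to_tss",
    "annotation_tss",
]


@dataclass
class TSRModel:
    """An alternating flat/sloped piecewise-linear fit to a sampled signal.

    ``breakpoints`` are sample indices ``0 = b_0 < ... < b_T = N-1``;
    ``segment_values`` the fitted values at the breakpoints; ``segment_kinds``
    the alternating ``"flat"``/``"sloped"`` labels of the ``T`` segments.
    """

    breakpoints: np.ndarray
    segment_values: np.ndarray
    segment_kinds: list[str]
    T: int
    sse: float

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=int)
        self.segment_values = np.asarray(self.segment_values, dtype=float)

    def slopes(self) -> np.ndarray:
        """Per-segment slope in value units per sample."""
        db = np.diff(self.breakpoints)
        return np.diff(self.segment_values) / db

    def evaluate(self) -> np.ndarray:
        """The fitted signal on its sample grid ``0..b_T``."""
        grid = np.arange(self.breakpoints[-1] + 1)
        return np.interp(grid, self.breakpoints, self.segment_values)


@dataclass
class TSS:
    """Per-sample trend codes in {-1, 0, +1} read off a TSR fit."""

    codes: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass
class SegmentBudget:
    """Result of the SDA-then-Kendall segment-count heuristic."""

    T_hat: int
    candidates: list[int]
    T_prime: int
    sda_profile: list[float]
    tau_profile: list[float]
    models: dict[int, TSRModel] = field(default_factory=dict)


def _prefix_sums(x: np.ndarray) -> dict[str, np.ndarray]:
    t = np.arange(x.size, dtype=float)
    z = np.zeros(1)
    return {
        "x": np.concatenate([z, np.cumsum(x)]),
        "xx": np.concatenate([z, np.cumsum(x * x)]),
        "xt": np.concatenate([z, np.cumsum(x * t)]),
        "t": np.concatenate([z, np.cumsum(t)]),
        "tt": np.concatenate([z, np.cumsum(t * t)]),
    }


def _dp(x: np.ndarray, levels: np.ndarray, t_max: int, flat_first: bool):
    """Exact DP over (breakpoint, level) states for one parity.

    Returns ``(totals, parents)`` where ``totals[s]`` is the optimal sse using
    exactly ``s`` segments (1-based, inf if infeasible) and ``parents`` allows
    traceback.  Segment ``s`` covers samples ``[b_{s-1}, b_s)``; the final
    sample's residual is added when closing the fit at ``b_T = N-1``.
    """
    n, nv = x.size, levels.size
    ps = _prefix_sums(x)
    v = levels

    def flat_cost_rows(ps_, p_arr, q):
        # cost over samples [p, q) of a constant fit, for all p in p_arr x levels
        a = q - p_arr
        sx = ps_["x"][q] - ps_["x"][p_arr]
        s2 = ps_["xx"][q] - ps_["xx"][p_arr]
        return (
            s2[:, None]
            - 2.0 * sx[:, None] * v[None, :]
            + a[:, None] * (v**2)[None, :]
        )

    def sloped_cost_tensor(p_arr, q):
        # cost over samples [p, q) of the line from (p, v) to (q, w),
        # shape (P, V, V) indexed [p, v, w]
        L = (q - p_arr).astype(float)
        a = (q - p_arr).astype(float)
        sx = ps_x[q] - ps_x[p_arr]
        s2 = ps_xx[q] - ps_xx[p_arr]
        sxt = ps_xt[q] - ps_xt[p_arr]
        st = ps_t[q] - ps_t[p_arr]
        stt = ps_tt[q] - ps_tt[p_arr]
        u = (v[None, None, :] - v[None, :, None]) / L[:, None, None]
        c = v[None, :, None] - u * p_arr[:, None, None]
        return (
            s2[:, None, None]
            - 2.0 * c * sx[:, None, None]
            - 2.0 * u * sxt[:, None, None]
            + c * c * a[:, None, None]
            + 2.0 * c * u * st[:, None, None]
            + u * u * stt[:, None, None]
        )

    ps_x, ps_xx, ps_xt, ps_t, ps_tt = ps["x"], ps["xx"], ps["xt"], ps["t"], ps["tt"]

    inf = np.inf
    J = np.full((t_max + 1, n, nv), inf)
    parent_p = np.full((t_max + 1, n, nv), -1, dtype=np.int32)
    parent_v = np.full((t_max + 1, n, nv), -1, dtype=np.int32)

    def kind(s: int) -> str:
        odd = s % 2 == 1
        return "flat" if (odd == flat_first) else "sloped"

    # s = 1: first segment starts at breakpoint 0
    zero = np.array([0])
    for q in range(1, n):
        if kind(1) == "flat":
            J[1, q] = flat_cost_rows(ps, zero, q)[0]
            parent_v[1, q] = np.arange(nv)  # level at breakpoint 0 equals level at q
        else:
            tens = sloped_cost_tensor(zero, q)[0]  # (V, V)
            J[1, q] = tens.min(axis=0)
            parent_v[1, q] = tens.argmin(axis=0)
        parent_p[1, q] = 0

    for s in range(1, t_max):
        k = kind(s + 1)
        for q in range(s + 1, n):
            p_arr = np.arange(s, q)
            base = J[s, s:q]  # (P, V)
            if not np.any(np.isfinite(base)):
                continue
            if k == "flat":
                tot = base + flat_cost_rows(ps, p_arr, q)  # (P, V)
                pi = tot.argmin(axis=0)
                J[s + 1, q] = tot[pi, np.arange(nv)]
                parent_p[s + 1, q] = p_arr[pi]
                parent_v[s + 1, q] = np.arange(nv)
            else:
                tot = base[:, :, None] + sloped_cost_tensor(p_arr, q)
                flat_idx = tot.reshape(-1, nv).argmin(axis=0)
                J[s + 1, q] = tot.reshape(-1, nv)[flat_idx, np.arange(nv)]
                parent_p[s + 1, q] = p_arr[flat_idx // nv]
                parent_v[s + 1, q] = flat_idx % nv

    closing = (x[-1] - v) ** 2
    totals = np.full(t_max + 1, inf)
    final_v = np.full(t_max + 1, -1, dtype=int)
    for s in range(1, t_max + 1):
        end = J[s, n - 1] + closing
        if np.any(np.isfinite(end)):
            totals[s] = end.min()
            final_v[s] = int(end.argmin())
    return totals, final_v, parent_p, parent_v


def _traceback(
    s: int, final_v: int, parent_p, parent_v, n: int, levels: np.ndarray, flat_first: bool
):
    bps = [n - 1]
    vals = [levels[final_v]]
    q, w = n - 1, final_v
    for seg in range(s, 0, -1):
        p = int(parent_p[seg, q, w])
        pv = int(parent_v[seg, q, w])
        bps.append(p)
        vals.append(levels[pv])
        q, w = p, pv
    kinds = ["flat" if ((j % 2 == 1) == flat_first) else "sloped" for j in range(1, s + 1)]
    return np.array(bps[::-1]), np.array(vals[::-1]), kinds


def fit_tsr_all(values: Sequence[float] | np.ndarray, t_max: int) -> dict[int, TSRModel]:
    """Optimal TSR fits for every segment budget ``1..t_max`` in one DP pass.

    For each budget the better of the two parities is kept (ties go to
    flat-first).  Raises :class:`BudgetTooLargeError` if ``t_max`` exceeds
    ``N - 1`` (each segment needs at least one grid interval).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need a 1-D signal with >= 2 samples")
    if np.any(np.isnan(x)):
        raise DegenerateInputError("fit_tsr requires no missing values")
    if t_max < 1:
        raise BudgetTooLargeError("segment budget must be >= 1")
    if t_max > x.size - 1:
        raise BudgetTooLargeError(
            f"budget {t_max} not representable with {x.size} samples (max {x.size - 1})"
        )
    levels = np.unique(np.concatenate([x, [x.mean()]]))
    out: dict[int, TSRModel] = {}
    results = {}
    for flat_first in (True, False):
        results[flat_first] = _dp(x, levels, t_max, flat_first)
    for t in range(1, t_max + 1):
        best_parity, best_sse = None, np.inf
        for flat_first in (True, False):
            totals = results[flat_first][0]
            if totals[t] < best_sse - 1e-15 or (
                best_parity is None and np.isfinite(totals[t])
            ):
                best_parity, best_sse = flat_first, totals[t]
        if best_parity is None:
            continue
        totals, final_v, pp, pv = results[best_parity]
        bps, vals, kinds = _traceback(
            t, int(final_v[t]), pp, pv, x.size, levels, best_parity
        )
        out[t] = TSRModel(bps, vals, kinds, t, float(max(best_sse, 0.0)))
    return out


def fit_tsr(values: Sequence[float] | np.ndarray, T: int) -> TSRModel:
    """Least-squares trapezoidal fit with exactly ``T`` segments.

    Global minimum of the sum of squared residuals over the pinned finite
    search space (grid breakpoints, level-grid breakpoint values, both
    parities).
    """
    models = fit_tsr_all(values, T)
    if T not in models:
        raise BudgetTooLargeError(f"no feasible {T}-segment fit")
    return models[T]


def estimate_T_hat(
    values: Sequence[float] | np.ndarray,
    smooth_w: int = 5,
    rel_tol: float = 0.15,
) -> int:
    """Automated proxy for the human-inspected initial segment count.

    Smooths the signal with a ``smooth_w``-sample moving average, quantizes
    the first difference to {-1, 0, +1} using a threshold of ``rel_tol`` times
    the largest absolute smoothed difference, and counts maximal runs of equal
    sign (a plateau run counts once).  The count is clipped to ``[1, N-1]``.
    A manual count can always be passed to the budget heuristic instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DegenerateInputError("need >= 4 samples")
    x = x[~np.isnan(x)]
    if x.size < 4:
        raise DegenerateInputError("need >= 4 non-missing samples")
    w = max(1, int(smooth_w))
    kernel = np.ones(w)
    smooth = np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )
    d = np.diff(smooth)
    tol = rel_tol * np.max(np.abs(d)) if np.max(np.abs(d)) > 0 else 0.0
    s = np.sign(d)
    s[np.abs(d) <= tol] = 0.0
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    return int(np.clip(runs, 1, x.size - 1))


def _first_local_max(profile: np.ndarray, start: int) -> int:
    """Index of the first local maximum scanning upward from ``start``.

    A point is a local maximum when it is not exceeded by its successor; on a
    monotone profile this is its last point of increase, and the final index
    always qualifies.
    """
    for i in range(start, profile.size - 1):
        if profile[i] >= profile[i + 1]:
            return i
    return profile.size - 1


def select_segment_count(
    values: Sequence[float] | np.ndarray,
    T_hat: int,
) -> SegmentBudget:
    """Choose the segment budget by the SDA-then-Kendall heuristic.

    Candidates are ``{floor(4/5 * T_hat), ..., ceil(6/5 * T_hat)}`` (floored
    at 1, capped at ``N - 1``).  Each candidate TSR is scored by SDA and by
    Kendall's tau-b between the fitted signal and the annotation; the scan
    walks up to the first local maximum of SDA, then on to the next local
    maximum of tau, whose candidate is the selected budget.
    """
    x = np.asarray(values, dtype=float)
    if T_hat < 1:
        raise BudgetTooLargeError("T_hat must be >= 1")
    lo = max(1, int(np.floor(4 * T_hat / 5)))
    hi = int(np.ceil(6 * T_hat / 5))
    hi = min(hi, x.size - 1)
    lo = min(lo, hi)
    candidates = list(range(lo, hi + 1))
    models = fit_tsr_all(x, hi)
    sda_prof, tau_prof = [], []
    for t in candidates:
        fitted = models[t].evaluate()
        sda_prof.append(sda(fitted, x))
        tau = stats.kendalltau(fitted, x).statistic
        tau_prof.append(tau if np.isfinite(tau) else -np.inf)
    sda_arr = np.array(sda_prof)
    tau_arr = np.array(tau_prof)
    i_sda = _first_local_max(sda_arr, 0)
    i_tau = _first_local_max(tau_arr, i_sda)
    return SegmentBudget(
        T_hat=T_hat,
        candidates=candidates,
        T_prime=candidates[i_tau],
        sda_profile=[float(s) for s in sda_prof],
        tau_profile=[float(t) for t in tau_prof],
        models={t: models[t] for t in candidates},
    )


def to_tss(model: TSRModel, grid_len: int, source_id: str = "") -> TSS:
    """Per-sample trend codes: the sign of the containing segment's slope.

    Segments are half-open — a boundary sample belongs to the segment starting
    at it — and the final sample belongs to the last segment.  ``grid_len``
    must match the grid the model covers.
    """
    if grid_len != model.breakpoints[-1] + 1:
        raise ShapeError(
            f"model covers {model.breakpoints[-1] + 1} samples, asked for {grid_len}"
        )
    slopes = model.slopes()
    codes = np.zeros(grid_len, dtype=np.int8)
    for j, s in enumerate(slopes):
        a, b = model.breakpoints[j], model.breakpoints[j + 1]
        end = b if j < len(slopes) - 1 else b + 1
        codes[a:end] = int(np.sign(s))
    return TSS(codes, source_id=source_id)


def annotation_tss(
    values: Sequence[float] | np.ndarray,
    t_hat: int | None = None,
    smooth_w: int = 5,
    source_id: str = "",
) -> tuple[TSS, SegmentBudget]:
    """TSR-fit an annotation end to end and return its trend codes.

    Missing samples are handled by fitting the longest contiguous non-missing
    block; samples outside that block receive code 0.  ``t_hat`` overrides the
    automated initial segment estimate.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if not ok.any():
        raise DegenerateInputError("all samples missing")
    # longest contiguous non-missing block
    edges = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    k = int(np.argmax(ends - starts))
    block = slice(int(starts[k]), int(ends[k]))
    xb = x[block]
    if xb.size < 4:
        raise DegenerateInputError("longest non-missing block too short to segment")
    if t_hat is None:
        t_hat = estimate_T_hat(xb, smooth_w=smooth_w)
    budget = select_segment_count(xb, t_hat)
    model = budget.models[budget.T_prime]
    tss_block = to_tss(model, xb.size, source_id=source_id)
    codes = np.zeros(x.size, dtype=np.int8)
    codes[block] = tss_block.codes
    return TSS(codes, source_id=source_id), budget
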