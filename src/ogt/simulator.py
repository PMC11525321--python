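"""Synthetic annotators with structured, realistic errors.

The test bed for every pipeline stage.  A latent *construct* signal T(t) is a
trapezoid train — alternating flat levels and linear trends — whose flat
windows and levels are recorded as recoverable ground truth.  Each simulated
annotator observes it through a personal strictly increasing perception map
P_i (raters agree on direction, not on values) and commits the documented
error structure of real continuous annotation:

* a reaction **lag** before changes are registered;
* an **overshoot** pulse at each trend onset, decaying over a few seconds
  (raters over-adjust when marking increases or decreases);
* a slow **drift** in valuation (the same construct level gets different
  values at different times, even within one sitting);
* white jitter **noise**.

Crucially the monotone-perception assumption means trends survive all of the
value errors except noise: with zero noise the sign of every change is
preserved exactly, which is the formal reason a trend-trusting pipeline can
work at all.  A logistic pairwise-comparison oracle stands in for the crowd
raters who judge which of two excerpts is lower on the construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .annotation_io import Annotation, RawEventLog
from .errors import DegenerateInputError, ShapeError
from .ordinal_fusion import FlatRegion, PairwiseComparison

__all__ = [
    "TrueSignal",
    "AnnotatorModel",
    "ComparisonOracle",
    "generate_true_signal",
    "make_annotator_pool",
    "simulate_annotation",
    "oracle_compare",
    "annotation_to_event_log",
]


@dataclass
class TrueSignal:
    """A latent trapezoidal construct signal with known flat structure."""

    values: np.ndarray
    flat_windows: list[tuple[int, int, float]]  # (start, end) half-open, level
    level_range: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class AnnotatorModel:
    """One rater: a monotone perception map plus structured error magnitudes.

    ``perception_x``/``perception_y`` are the knots of a strictly increasing
    piecewise-linear map from construct units to the annotation scale.
    ``invert=True`` plants an adversarial rater whose perception decreases —
    the kind of outlier inlier-selection must reject.
    """

    annotator_id: str
    perception_x: np.ndarray
    perception_y: np.ndarray
    lag_s: float = 1.0
    overshoot_gain: float = 0.5
    drift_sd: float = 20.0
    shared_drift_frac: float = 0.5
    noise_sd: float = 2.0
    move_threshold: float = 5.0
    seed: int = 0
    invert: bool = False
    v_min: float = -100.0
    v_max: float = 100.0

    def __post_init__(self) -> None:
        self.perception_x = np.asarray(self.perception_x, dtype=float)
        self.perception_y = np.asarray(self.perception_y, dtype=float)
        if np.any(np.diff(self.perception_x) <= 0):
            raise ShapeError("perception knots must strictly increase in x")
        dy = np.diff(self.perception_y)
        if not (np.all(dy > 0) or (self.invert and np.all(dy < 0))):
            raise ShapeError("perception must be strictly monotone")
        if self.lag_s < 0 or self.overshoot_gain < 0 or self.drift_sd < 0 or self.noise_sd < 0:
            raise ShapeError("error magnitudes must be nonnegative")

    def perceive(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.perception_x, self.perception_y)


def generate_true_signal(
    n_runs: int,
    grid_len: int,
    level_range: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    min_run_len: int = 2,
    min_level_step: float | None = None,
) -> TrueSignal:
    """Alternating flat/trend runs with random durations and flat levels.

    Runs start flat; ``n_runs=1`` is a constant signal.  Consecutive flat
    levels differ by at least ``min_level_step`` (default a quarter of the
    level range) so every trend is a real trend.  Flat windows and levels are
    recorded for recovery tests and for the comparison oracle.
    """
    if n_runs < 1:
        raise DegenerateInputError("n_runs must be >= 1")
    if grid_len < max(2, min_run_len * n_runs):
        raise DegenerateInputError(
            f"grid_len {grid_len} cannot hold {n_runs} runs of >= {min_run_len} samples"
        )
    lo, hi = level_range
    if not hi > lo:
        raise DegenerateInputError("level_range must be nondegenerate")
    if min_level_step is None:
        min_level_step = 0.25 * (hi - lo)
    rng = np.random.default_rng(seed)

    # Durations: minimum per run, remainder spread at random.
    durations = np.full(n_runs, min_run_len)
    extra = grid_len - durations.sum()
    if extra > 0:
        durations += rng.multinomial(extra, np.ones(n_runs) / n_runs)
    bounds = np.concatenate([[0], np.cumsum(durations)])

    n_flats = (n_runs + 1) // 2
    n_levels = n_flats + (1 if n_runs % 2 == 0 else 0)  # trailing trend needs a target
    levels = [float(rng.uniform(lo, hi))]
    while len(levels) < n_levels:
        cand = float(rng.uniform(lo, hi))
        if abs(cand - levels[-1]) >= min_level_step:
            levels.append(cand)

    xs: list[int] = []
    ys: list[float] = []
    flats: list[tuple[int, int, float]] = []
    li = 0
    for k in range(n_runs):
        a, b = int(bounds[k]), int(bounds[k + 1])
        if k % 2 == 0:  # flat run
            xs.extend([a, b - 1])
            ys.extend([levels[li], levels[li]])
            flats.append((a, b, levels[li]))
        else:  # trend run: ramp toward the next level, reached at its end
            li += 1
            xs.append(b - 1 if k == n_runs - 1 else b)
            ys.append(levels[li])
    values = np.interp(np.arange(grid_len), xs, ys)
    return TrueSignal(values, flats, (lo, hi), seed)


def _random_perception(
    rng: np.random.Generator,
    construct_range: tuple[float, float],
    v_min: float,
    v_max: float,
    n_knots: int = 6,
    invert: bool = False,
    inc_range: tuple[float, float] = (0.05, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """A random strictly increasing piecewise-linear map (4 interior knots).

    ``inc_range`` bounds the relative slope of each linear piece; a wide range
    yields raters whose sensitivity varies a lot across the construct scale.
    """
    xk = np.linspace(construct_range[0], construct_range[1], n_knots)
    inc = rng.uniform(*inc_range, size=n_knots - 1)
    yk = np.concatenate([[0.0], np.cumsum(inc)])
    yk = v_min + (v_max - v_min) * yk / yk[-1]
    if invert:
        yk = yk[::-1].copy()
    return xk, yk


def make_annotator_pool(
    n: int,
    seed: int = 0,
    n_adversarial: int = 0,
    construct_range: tuple[float, float] = (0.0, 1.0),
    lag_range_s: tuple[float, float] = (0.5, 2.0),
    overshoot_gain: float = 0.5,
    drift_sd: float = 20.0,
    noise_sd: float = 2.0,
    perception_inc_range: tuple[float, float] = (0.05, 1.0),
    v_min: float = -100.0,
    v_max: float = 100.0,
) -> list[AnnotatorModel]:
    """A seeded pool of annotators, the last ``n_adversarial`` inverted."""
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n):
        invert = i >= n - n_adversarial
        xk, yk = _random_perception(rng, construct_range, v_min, v_max,
                                    invert=invert, inc_range=perception_inc_range)
        pool.append(
            AnnotatorModel(
                annotator_id=f"a{i}" + ("_adv" if invert else ""),
                perception_x=xk,
                perception_y=yk,
                lag_s=float(rng.uniform(*lag_range_s)),
                overshoot_gain=overshoot_gain,
                drift_sd=drift_sd,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
                invert=invert,
                v_min=v_min,
                v_max=v_max,
            )
        )
    return pool


def _drift(rng: np.random.Generator, n: int, sd: float, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Slow revaluation offset: a low-pass filtered random walk, rescaled to sd."""
    walk = np.cumsum(rng.standard_normal(n))
    nyq = rate_hz / 2.0
    if n > 15 and 0 < cutoff_hz < nyq:
        b, a = sp_signal.butter(2, cutoff_hz / nyq)
        walk = sp_signal.filtfilt(b, a, walk)
    walk = walk - walk.mean()
    s = walk.std()
    return walk * (sd / s) if s > 0 else np.zeros(n)


def simulate_annotation(
    true_signal: TrueSignal,
    annotator: AnnotatorModel,
    rate_hz: float = 1.0,
    stimulus_id: str = "stim",
    drift_cutoff_hz: float = 0.02,
) -> Annotation:
    """One rater's trace: lagged monotone perception plus structured errors.

    ``value(t) = P(T(t - lag)) + overshoot pulse + drift + noise``, clipped to
    the annotation scale.  With all error magnitudes zero and an identity
    perception the trace equals the latent signal exactly; with zero noise
    and any monotone perception the trace preserves every difference sign.
    """
    rng = np.random.default_rng(annotator.seed)
    n = len(true_signal)
    lag = int(round(annotator.lag_s * rate_hz))
    idx = np.clip(np.arange(n) - lag, 0, n - 1)
    perceived = annotator.perceive(true_signal.values[idx])

    out = perceived.copy()
    if annotator.overshoot_gain > 0:
        flats = true_signal.flat_windows
        for (_s, e, lv), (_s2, _e2, lv2) in zip(flats, flats[1:]):
            onset = min(e + lag, n - 1)
            step = annotator.perceive(np.array([lv2]))[0] - annotator.perceive(
                np.array([lv])
            )[0]
            k = np.arange(n - onset)
            out[onset:] += annotator.overshoot_gain * step * np.exp(-k / 3.0)
    if annotator.drift_sd > 0:
        # Valuation drift: a slow low-pass-filtered random walk, *sampled at
        # revaluation instants* (run onsets, i.e. whenever the rater starts
        # moving) and held constant in between.  Raters re-anchor their value
        # scale when they act, not while the slider is parked, so equal
        # construct levels at different times get inconsistent values while
        # trends within a run stay intact.  The drift is partly shared across
        # the panel (context-driven recalibration, seeded by the stimulus) —
        # the component sample-wise averaging cannot remove — and partly
        # individual.
        bnds = sorted({0} | {s for s, _, _ in true_signal.flat_windows}
                      | {e for _, e, _ in true_signal.flat_windows if e < n})
        bnds_arr = np.array(bnds)
        anchors = bnds_arr[np.searchsorted(bnds_arr, idx, side="right") - 1]
        frac = float(np.clip(annotator.shared_drift_frac, 0.0, 1.0))
        if frac > 0:
            rng_shared = np.random.default_rng(
                np.random.SeedSequence([true_signal.seed, 915237461])
            )
            walk = _drift(rng_shared, n, annotator.drift_sd * np.sqrt(frac),
                          rate_hz, drift_cutoff_hz)
            out += walk[anchors]
        if frac < 1:
            walk = _drift(rng, n, annotator.drift_sd * np.sqrt(1 - frac),
                          rate_hz, drift_cutoff_hz)
            out += walk[anchors]
    if annotator.noise_sd > 0:
        out += rng.standard_normal(n) * annotator.noise_sd
    if annotator.move_threshold > 0:
        # Slider dead zone: the rater only moves once the intended position
        # differs enough from where the slider already sits, so perceived-flat
        # stretches come out exactly constant (as in real changes-only logs)
        # while accumulated drift eventually forces a spurious revaluation step.
        held = out.copy()
        for t in range(1, n):
            if abs(out[t] - held[t - 1]) < annotator.move_threshold:
                held[t] = held[t - 1]
        out = held
    out = np.clip(out, annotator.v_min, annotator.v_max)
    return Annotation(
        annotator.annotator_id,
        stimulus_id,
        rate_hz,
        out,
        v_min=annotator.v_min,
        v_max=annotator.v_max,
    )


@dataclass
class ComparisonOracle:
    """Noisy stand-in for crowd raters judging which excerpt is lower.

    Picks the truly lower region with probability ``1 / (1 + exp(-beta *
    |level_a - level_b|))``: ``beta -> inf`` is the noiseless oracle, ``beta =
    0`` a coin flip.  Equal levels draw uniformly and are flagged.  One oracle
    instance holds one seeded random stream, so a sequence of calls is
    deterministic under (levels, beta, seed).
    """

    true_levels: Mapping[str, float]
    beta: float = np.inf
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ShapeError("beta must be nonnegative")
        self._rng = np.random.default_rng(self.seed)

    def __call__(self, a: FlatRegion, b: FlatRegion) -> PairwiseComparison:
        la, lb = self.true_levels[a.region_id], self.true_levels[b.region_id]
        if la == lb:
            lower = a.region_id if self._rng.integers(2) == 0 else b.region_id
            return PairwiseComparison(a.region_id, b.region_id, lower,
                                      source="oracle", flagged=True)
        delta = abs(la - lb)
        p_correct = 1.0 if np.isinf(self.beta) else 1.0 / (1.0 + np.exp(-self.beta * delta))
        truly_lower = a.region_id if la < lb else b.region_id
        other = b.region_id if truly_lower == a.region_id else a.region_id
        lower = truly_lower if self._rng.random() < p_correct else other
        return PairwiseComparison(a.region_id, b.region_id, lower, source="oracle")


def oracle_compare(
    region_pair: tuple[FlatRegion, FlatRegion],
    true_levels: Mapping[str, float],
    beta: float = np.inf,
    seed: int = 0,
) -> PairwiseComparison:
    """Single seeded oracle judgement; see :class:`ComparisonOracle`."""
    oracle = ComparisonOracle(true_levels, beta=beta, seed=seed)
    return oracle(*region_pair)


def annotation_to_event_log(
    ann: Annotation,
    seed: int | None = None,
    n_gaps: int = 0,
    gap_len_s: float = 4.0,
) -> RawEventLog:
    """Convert a sampled annotation to a changes-only event log.

    Events are emitted at the first sample and at every value change; missing
    samples emit nothing (creating a logging lapse).  ``n_gaps`` randomly
    placed spans of ``gap_len_s`` additionally have their events removed, to
    exercise the unequal-endpoint gap rule downstream.
    """
    times = ann.times
    vals = ann.values
    events: list[tuple[float, float]] = []

    def emit(i: int) -> None:
        if not np.isnan(vals[i]) and (not events or events[-1][0] < float(times[i])):
            events.append((float(times[i]), float(vals[i])))

    prev_ok = None
    for i in range(len(vals)):
        if np.isnan(vals[i]):
            continue
        if prev_ok is None:
            emit(i)
        elif vals[i] != vals[prev_ok]:
            # log the last held sample too, so a hold followed by a jump
            # survives linear-interpolation resampling exactly
            emit(prev_ok)
            emit(i)
        prev_ok = i
    if prev_ok is not None:
        emit(prev_ok)  # close the final hold
    if n_gaps > 0:
        rng = np.random.default_rng(seed)
        span = gap_len_s
        for _ in range(n_gaps):
            start = float(rng.uniform(times[0], times[-1] - span))
            events = [
                (t, v) for t, v in events if not (start < t < start + span)
            ]
    if len(events) < 2:
        raise DegenerateInputError("annotation collapsed to fewer than 2 events")
    return RawEventLog(ann.annotator_id, ann.stimulus_id, events,
                       v_min=ann.v_min, v_max=ann.v_max)
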