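"""Trend voting, flat-region extraction, ordinal embedding and reconstruction.

This is the fusion half of the pipeline.  Per-annotation trend codes (TSS)
are merged by per-sample plurality vote; maximal runs of merged zeros become
*flat regions* — stimulus excerpts over which the construct is approximately
constant.  Pairwise "which excerpt is lower?" judgements about those excerpts
are converted to triplets against a hypothetical dummy excerpt ``r`` assumed
lower than everything (if ``j`` is judged lower than ``k``, then ``j`` is more
similar to ``r`` than ``k`` is), embedded on the line with t-distributed
stochastic triplet embedding (t-STE), and the embedded values are written back
onto the grid: constant over each flat region, linear ramps in between.  The
result is a trapezoidal ground-truth signal whose values are internally
consistent — comparable across time and, when regions of several stimuli are
embedded jointly, across stimuli — but carry ordinal meaning only.

A sample-wise averaging baseline and the batched comparison-collection loop
with its Spearman stopping rule live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .annotation_io import Annotation
from .errors import (
    ExhaustedPairsError,
    NoInformationError,
    ReconstructionImpossibleError,
    ShapeError,
)
from .tsr import TSS

__all__ = [
    "MergedTSS",
    "FlatRegion",
    "PairwiseComparison",
    "Triplet",
    "Embedding",
    "GroundTruth",
    "DUMMY_ID",
    "trend_vote",
    "extract_flat_regions",
    "sample_pairs",
    "pairs_to_triplets",
    "tste_embed",
    "reconstruct",
    "baseline_average",
    "run_comparison_loop",
]

#: Default id of the hypothetical lowest-construct dummy excerpt.
DUMMY_ID = "__dummy_low__"


@dataclass
class MergedTSS:
    """Consensus trend codes with per-sample vote margins."""

    codes: np.ndarray
    vote_margins: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.vote_margins = np.asarray(self.vote_margins, dtype=int)


@dataclass(frozen=True)
class FlatRegion:
    """A half-open sample window ``[start, end)`` of constant merged trend."""

    region_id: str
    stimulus_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ShapeError(f"empty region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PairwiseComparison:
    """A judgement of which of two regions sits LOWER on the construct."""

    region_a: str
    region_b: str
    choice: str  # the lower one; must be region_a or region_b
    source: str = "human"
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.region_a == self.region_b:
            raise ShapeError("a comparison needs two distinct regions")
        if self.choice not in (self.region_a, self.region_b):
            raise ShapeError("choice must name one of the compared regions")


@dataclass(frozen=True)
class Triplet:
    """Encodes s(anchor, near) > s(anchor, far): near is more similar to anchor."""

    anchor: Hashable
    near: Hashable
    far: Hashable


@dataclass
class Embedding:
    """1-D item values from t-STE, oriented and with the dummy removed."""

    values: dict[Hashable, float]
    converged: bool
    loss: float
    isolated: list[Hashable] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Reconstructed trapezoidal construct signal with region provenance."""

    stimulus_id: str
    values: np.ndarray
    provenance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def scaled01(self) -> np.ndarray:
        """Display transform to [0, 1]; never applied before rank-based scoring."""
        lo, hi = np.nanmin(self.values), np.nanmax(self.values)
        if hi == lo:
            return np.zeros_like(self.values)
        return (self.values - lo) / (hi - lo)


def trend_vote(tss_list: Sequence[TSS]) -> MergedTSS:
    """Per-sample plurality vote over trend codes; ties resolve to 0 (flat).

    The margin is the winning count minus the runner-up count (0 on a tie).
    """
    if not tss_list:
        raise ShapeError("need at least one TSS")
    lens = {len(t) for t in tss_list}
    if len(lens) != 1:
        raise ShapeError(f"TSS lengths differ: {sorted(lens)}")
    stack = np.stack([t.codes for t in tss_list])
    counts = np.stack([(stack == c).sum(axis=0) for c in (-1, 0, 1)])  # (3, n)
    order = np.sort(counts, axis=0)
    margins = order[-1] - order[-2]
    winners = np.array([-1, 0, 1], dtype=np.int8)[counts.argmax(axis=0)]
    winners = np.where(margins == 0, np.int8(0), winners)
    return MergedTSS(winners, margins)


def extract_flat_regions(
    merged: MergedTSS,
    min_len_samples: int = 2,
    stimulus_id: str = "",
    id_prefix: str = "r",
) -> list[FlatRegion]:
    """Maximal all-zero runs of the merged TSS, at least ``min_len_samples`` long.

    Regions are half-open windows ordered by start; an empty list is a valid
    outcome.  The default minimum of 2 samples reflects that a one-sample
    excerpt cannot be shown to a comparison rater as a clip.
    """
    if min_len_samples < 1:
        raise ShapeError("min_len_samples must be >= 1")
    iszero = np.concatenate([[0], (merged.codes == 0).view(np.int8), [0]])
    edges = np.flatnonzero(np.diff(iszero))
    regions = []
    for k, (a, b) in enumerate(zip(edges[::2], edges[1::2])):
        if b - a >= min_len_samples:
            regions.append(
                FlatRegion(f"{id_prefix}{len(regions)}", stimulus_id, int(a), int(b))
            )
    return regions


def sample_pairs(
    regions: Sequence[FlatRegion],
    n_pairs: int,
    seed: int = 0,
    already_asked: set[frozenset] | None = None,
) -> list[tuple[FlatRegion, FlatRegion]]:
    """Uniform draw of unordered region pairs without replacement.

    ``already_asked`` holds frozensets of region-id pairs from earlier
    batches; raises :class:`ExhaustedPairsError` when fewer than ``n_pairs``
    unasked pairs remain.
    """
    already_asked = already_asked or set()
    by_id = {r.region_id: r for r in regions}
    pool = [
        frozenset((a.region_id, b.region_id))
        for a, b in combinations(regions, 2)
        if frozenset((a.region_id, b.region_id)) not in already_asked
    ]
    if n_pairs > len(pool):
        raise ExhaustedPairsError(
            f"asked for {n_pairs} pairs but only {len(pool)} remain"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_pairs, replace=False)
    out = []
    for idx in sorted(int(i) for i in chosen):
        a_id, b_id = sorted(pool[idx])
        out.append((by_id[a_id], by_id[b_id]))
    return out


def pairs_to_triplets(
    comparisons: Sequence[PairwiseComparison],
    dummy_id: Hashable = DUMMY_ID,
) -> list[Triplet]:
    """Convert pairwise lower-judgements to dummy-reference triplets.

    A comparison judging ``j`` lower than ``k`` becomes the triplet
    ``(r, j, k)``: ``j`` is more similar to the hypothetical lowest excerpt
    ``r`` than ``k`` is.  No extra comparisons are needed since ``r`` is
    lower than everything by construction.  Contradictory duplicates are both
    emitted; the embedder absorbs the noise.
    """
    out = []
    for c in comparisons:
        if dummy_id in (c.region_a, c.region_b):
            raise ShapeError("dummy id collides with a region id")
        lower = c.choice
        higher = c.region_b if lower == c.region_a else c.region_a
        out.append(Triplet(dummy_id, lower, higher))
    return out


def _tste_loss_grad(
    z: np.ndarray, trips: np.ndarray, alpha: float, lam: float
) -> tuple[float, np.ndarray]:
    a, nr, fr = trips[:, 0], trips[:, 1], trips[:, 2]
    dan = z[a] - z[nr]
    daf = z[a] - z[fr]
    kan = (1.0 + dan**2 / alpha) ** (-(alpha + 1.0) / 2.0)
    kaf = (1.0 + daf**2 / alpha) ** (-(alpha + 1.0) / 2.0)
    p = kan / (kan + kaf)
    p = np.clip(p, 1e-300, 1.0)
    loss = -np.log(p).sum()
    # d log K_ij / d z_i = -(alpha+1) (z_i - z_j) / (alpha + d_ij^2)
    gan = -(alpha + 1.0) * dan / (alpha + dan**2)
    gaf = -(alpha + 1.0) * daf / (alpha + daf**2)
    w = 1.0 - p
    grad = np.zeros_like(z)
    np.add.at(grad, a, -w * (gan - gaf))
    np.add.at(grad, nr, -w * (-gan))
    np.add.at(grad, fr, -w * gaf)
    if lam > 0:
        loss += lam * float(z @ z)
        grad = grad + 2.0 * lam * z
    return float(loss), grad


def tste_embed(
    triplets: Sequence[Triplet],
    items: Sequence[Hashable],
    dummy_id: Hashable = DUMMY_ID,
    alpha: float = 1.0,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-7,
    lam: float = 0.01,
    d: int = 1,
) -> Embedding:
    """Place items on the line by maximizing the t-STE triplet likelihood.

    The best of ``restarts`` seeded initializations is kept.  ``alpha`` is the
    Student-t degrees of freedom of the similarity kernel (the conventional
    ``d - 1`` degenerates at ``d = 1``, hence the default 1).  ``lam`` is the
    solver's standard L2 penalty on item positions; with perfectly consistent
    triplets the unpenalized heavy-tailed likelihood keeps growing as groups
    of items separate without bound, so a small penalty pins the scale while
    leaving the ordering (and any rank-based use of the values) untouched.

    Dummy-anchored triplets constrain only each item's *distance* to the
    dummy, leaving the side of the line each item falls on unidentified.  When
    every anchor is the dummy the embedding is therefore canonicalized —
    likelihood-invariantly — by folding all items onto one side of the dummy
    before orientation.  Finally the embedding is reversed if needed so the
    dummy is minimal, and the dummy is dropped from the returned values.
    """
    if d != 1:
        raise NotImplementedError("only 1-D embeddings (a single construct) are supported")
    if not triplets:
        raise NoInformationError("no triplets; embedding unconstrained")
    items = list(items)
    if dummy_id not in items:
        items = items + [dummy_id]
    index = {it: i for i, it in enumerate(items)}
    trips = np.array(
        [[index[t.anchor], index[t.near], index[t.far]] for t in triplets], dtype=int
    )
    n = len(items)
    used = np.zeros(n, dtype=bool)
    used[trips.ravel()] = True
    isolated = [items[i] for i in range(n) if not used[i]]

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        z0 = rng.standard_normal(n) * 0.1
        res = minimize(
            _tste_loss_grad,
            z0,
            args=(trips, alpha, lam),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    z = best.x.copy()
    z[~used] = z[index[dummy_id]] if used[index[dummy_id]] else 0.0

    r = index[dummy_id]
    if np.all(trips[:, 0] == r):
        z = z[r] + np.abs(z - z[r])  # fold: sides are unidentified, loss unchanged
    if z[r] > np.median(np.delete(z, r)):
        z = -z  # reverse so the dummy sits at the low end
    z = z - z[r]
    values = {it: float(z[i]) for it, i in index.items() if it != dummy_id}
    return Embedding(values, bool(best.success), float(best.fun), isolated)


def reconstruct(
    regions: Sequence[FlatRegion],
    embedding: Embedding,
    grid_len: int,
) -> GroundTruth:
    """Write embedded region values back onto the grid as a trapezoidal signal.

    Constant over each flat region; linear ramps between the last sample of
    one region and the first sample of the next; the nearest region's value is
    held before the first and after the last region.
    """
    regions = sorted(regions, key=lambda r: r.start)
    if not regions:
        raise ReconstructionImpossibleError("no flat regions to anchor the signal")
    for a, b in zip(regions, regions[1:]):
        if b.start < a.end:
            raise ShapeError(f"regions {a.region_id} and {b.region_id} overlap")
    missing = [r.region_id for r in regions if r.region_id not in embedding.values]
    if missing:
        raise ShapeError(f"regions without an embedded value: {missing}")
    stim = regions[0].stimulus_id
    out = np.empty(grid_len)
    xs: list[int] = []
    ys: list[float] = []
    for r in regions:
        v = embedding.values[r.region_id]
        xs.extend([r.start, r.end - 1])
        ys.extend([v, v])
    out[:] = np.interp(np.arange(grid_len), xs, ys)
    return GroundTruth(
        stim, out, provenance={r.region_id: (r.start, r.end) for r in regions}
    )


def baseline_average(aligned_inliers: Sequence[Annotation]) -> GroundTruth:
    """Sample-wise mean of aligned annotations; all-missing samples stay missing."""
    if not aligned_inliers:
        raise ShapeError("need at least one annotation")
    lens = {len(a) for a in aligned_inliers}
    if len(lens) != 1:
        raise ShapeError(f"annotation lengths differ: {sorted(lens)}")
    stack = np.stack([a.values for a in aligned_inliers])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return GroundTruth(aligned_inliers[0].stimulus_id, mean)


def _candidate_rho(curr: np.ndarray, prev: np.ndarray) -> float:
    if np.array_equal(curr, prev):
        return 1.0
    rho = stats.spearmanr(curr, prev).statistic
    return float(rho) if np.isfinite(rho) else -np.inf


def run_comparison_loop(
    regions: Sequence[FlatRegion],
    comparison_source: Callable[[FlatRegion, FlatRegion], PairwiseComparison],
    grid_lens: Mapping[str, int] | int,
    batch_size: int = 5000,
    rho_stop: float = 0.8,
    seed: int = 0,
    embed_kwargs: dict | None = None,
) -> tuple[GroundTruth | dict[str, GroundTruth], list[dict]]:
    """Collect comparisons in batches until successive candidates stabilize.

    After each batch of (at most) ``batch_size`` fresh unordered pairs, all
    comparisons gathered so far are embedded jointly and a candidate ground
    truth is reconstructed per stimulus.  The loop stops when the Spearman
    correlation between the current and previous candidate reaches
    ``rho_stop`` for every stimulus, or when the pairs are exhausted (a final
    partial batch is used).  ``history`` records, per batch, the cumulative
    comparison count and the per-stimulus correlations.

    Returns a single :class:`GroundTruth` when all regions share one stimulus,
    else a dict keyed by stimulus id.
    """
    if isinstance(grid_lens, int):
        stims = {r.stimulus_id for r in regions}
        if len(stims) != 1:
            raise ShapeError("an int grid_lens requires a single stimulus")
        grid_lens = {next(iter(stims)): grid_lens}
    by_stim: dict[str, list[FlatRegion]] = {}
    for r in regions:
        by_stim.setdefault(r.stimulus_id, []).append(r)

    embed_kwargs = dict(embed_kwargs or {})
    asked: set[frozenset] = set()
    comparisons: list[PairwiseComparison] = []
    total_pairs = len(regions) * (len(regions) - 1) // 2
    prev: dict[str, GroundTruth] | None = None
    history: list[dict] = []
    batch_no = 0
    ids = [r.region_id for r in regions]

    while True:
        remaining = total_pairs - len(asked)
        if remaining == 0:
            break
        take = min(batch_size, remaining)
        batch = sample_pairs(regions, take, seed=seed + batch_no, already_asked=asked)
        for a, b in batch:
            asked.add(frozenset((a.region_id, b.region_id)))
            comparisons.append(comparison_source(a, b))
        triplets = pairs_to_triplets(comparisons)
        emb = tste_embed(triplets, ids, seed=seed, **embed_kwargs)
        current = {
            s: reconstruct(rs, emb, grid_lens[s]) for s, rs in by_stim.items()
        }
        record: dict = {
            "batch": batch_no,
            "n_comparisons": len(comparisons),
            "rho": {},
        }
        stable = prev is not None
        if prev is not None:
            for s in current:
                rho = _candidate_rho(current[s].values, prev[s].values)
                record["rho"][s] = rho
                stable = stable and rho >= rho_stop
        history.append(record)
        prev = current
        batch_no += 1
        if stable:
            break

    if prev is None:
        raise ExhaustedPairsError("no pairs available to compare")
    if len(by_stim) == 1:
        return next(iter(prev.values())), history
    return prev, history
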