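"""Temporal alignment of annotation sets and trend-based inlier selection.

Raters react to the same stimulus with different (and drifting) lags, so
before agreement is measured each pair of traces is aligned by dynamic time
warping with the symmetric step pattern (diagonal, vertical, horizontal moves)
under a Sakoe-Chiba band that caps temporal distortion at ``band_s`` seconds.
Local cost is the squared value difference; samples missing on either side
contribute zero cost so gaps do not attract or repel the warp path.

Selection treats "who belongs to the consensus" as a binary clustering
problem: pairwise SDA (on DTW-aligned pairs) fills an affinity matrix, a
two-class spectral clustering bipartitions it, and the cluster with the
highest mean internal SDA is kept as the inlier group.  A uniform-shift
aligner driven by pairwise mutual information is provided as an alternative;
on signals with long flat stretches it legitimately fails to find a useful
shift and says so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.cluster import SpectralClustering

from .agreement import AgreementMatrix, sda, sda_matrix
from .annotation_io import Annotation
from .errors import (
    AlignmentInfeasibleError,
    SelectionImpossibleError,
    ShapeError,
    UndefinedAgreementError,
)

__all__ = [
    "AlignmentResult",
    "SelectionResult",
    "dtw_align_pair",
    "select_inliers",
    "align_inliers",
    "uniform_shift_align",
]


@dataclass
class AlignmentResult:
    """A set of annotations warped onto one reference grid."""

    reference_id: str
    warped: list[Annotation]
    warp_paths: dict[str, np.ndarray]
    band_s: float
    shifts: dict[str, int] = field(default_factory=dict)


@dataclass
class SelectionResult:
    """Inlier/outlier split of an annotation set with per-cluster mean SDA."""

    inlier_ids: list[str]
    outlier_ids: list[str]
    cluster_mean_sda: dict[str, float]
    sda: AgreementMatrix | None = None


def _dtw_path(
    ref: np.ndarray, query: np.ndarray, band: int
) -> np.ndarray:
    """Optimal warp path (pairs of indices into ref, query) under a band.

    Symmetric step pattern — moves (1,1), (1,0), (0,1) — with squared local
    cost; a NaN on either side makes the local cost zero.  Raises
    :class:`AlignmentInfeasibleError` when the band cannot bridge the length
    difference.
    """
    n, m = ref.size, query.size
    if abs(n - m) > band:
        raise AlignmentInfeasibleError(
            f"length difference {abs(n - m)} samples exceeds band of {band}"
        )
    diff = ref[:, None] - query[None, :]
    local = np.where(np.isnan(diff), 0.0, diff) ** 2
    inf = np.inf
    acc = np.full((n, m), inf)
    inside = np.abs(np.arange(n)[:, None] - np.arange(m)[None, :]) <= band
    acc[0, 0] = local[0, 0]
    for i in range(n):
        row_ok = inside[i]
        for j in range(m):
            if not row_ok[j] or (i == 0 and j == 0):
                continue
            best = inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0 and acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if j > 0 and acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + local[i, j]
    if not np.isfinite(acc[n - 1, m - 1]):
        raise AlignmentInfeasibleError("no warp path inside the band")
    # Traceback
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            cands.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            cands.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
        path.append((i, j))
    return np.array(path[::-1], dtype=int)


def _warp_onto(ref: Annotation, other: Annotation, band: int) -> tuple[Annotation, np.ndarray]:
    """Warp ``other`` onto ``ref``'s grid; multi-matched samples are averaged."""
    for a in (ref, other):
        frac = np.mean(np.isnan(a.values))
        if frac > 0.20:
            warnings.warn(
                f"annotation {a.annotator_id!r} is {frac:.0%} missing; "
                "DTW treats missing samples as zero-cost and the warp may be unreliable",
                stacklevel=3,
            )
    path = _dtw_path(ref.values, other.values, band)
    n = ref.values.size
    sums = np.zeros(n)
    counts = np.zeros(n)
    for i, j in path:
        v = other.values[j]
        if not np.isnan(v):
            sums[i] += v
            counts[i] += 1
    out = np.full(n, np.nan)
    got = counts > 0
    out[got] = sums[got] / counts[got]
    warped = Annotation(
        other.annotator_id,
        other.stimulus_id,
        ref.rate_hz,
        out,
        t0=ref.t0,
        v_min=other.v_min,
        v_max=other.v_max,
    )
    return warped, path


def dtw_align_pair(
    x: Annotation,
    y: Annotation,
    band_s: float = 5.0,
    seed: int = 0,
) -> tuple[Annotation, Annotation]:
    """Align a pair by DTW, choosing the reference uniformly at random.

    Returns ``(x_aligned, y_aligned)`` in argument order, both on the chosen
    reference's grid.
    """
    if x.stimulus_id != y.stimulus_id:
        raise ShapeError("annotations must be of the same stimulus")
    if band_s < x.delta:
        raise AlignmentInfeasibleError("band_s must be at least one sample period")
    band = int(round(band_s * x.rate_hz))
    rng = np.random.default_rng(seed)
    if rng.integers(2) == 0:
        ref, other = x, y
        warped, path = _warp_onto(ref, other, band)
        return ref, warped
    ref, other = y, x
    warped, path = _warp_onto(ref, other, band)
    return warped, ref


def select_inliers(
    annotations: Sequence[Annotation],
    band_s: float = 5.0,
    seed: int = 0,
) -> SelectionResult:
    """Split annotations into the consensus (inlier) group and outliers.

    Affinity is ``(SDA + 1) / 2`` on DTW-pair-aligned pairs (undefined pairs
    impute affinity 0); a two-class spectral clustering (normalized Laplacian,
    seeded k-means) bipartitions it and the cluster with the highest mean
    internal pairwise SDA wins.  With three or fewer annotations a bipartition
    is meaningless and everything is kept.
    """
    n = len(annotations)
    if n < 3:
        raise ShapeError("need at least 3 annotations to select inliers")
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.generate_state(n * (n - 1) // 2 + 1)[1:])

    def aligner(a: Annotation, b: Annotation) -> tuple[Annotation, Annotation]:
        return dtw_align_pair(a, b, band_s=band_s, seed=int(next(pair_seeds)) % (2**31))

    mat = sda_matrix(annotations, pair_aligner=aligner)
    off = mat.values[~np.eye(n, dtype=bool)]
    if np.all(np.isnan(off)):
        raise SelectionImpossibleError("every pairwise SDA is undefined")
    ids = mat.ids

    if n <= 3:
        return SelectionResult(list(ids), [], {"inliers": float(np.nanmean(off))}, sda=mat)

    affinity = (np.where(np.isnan(mat.values), -1.0, mat.values) + 1.0) / 2.0
    np.fill_diagonal(affinity, 1.0)
    labels = SpectralClustering(
        n_clusters=2,
        affinity="precomputed",
        random_state=seed,
        n_init=10,
        assign_labels="kmeans",
    ).fit_predict(affinity)

    def cluster_mean(members: np.ndarray) -> float:
        # Mean over every pair involving a member (within-cluster and crossing
        # pairs alike).  A within-only mean would crown any tiny internally
        # coherent clique — e.g. two raters sharing an inverted percept — over
        # the majority; counting crossing pairs makes the consensus cluster win
        # exactly when its members agree with the panel at large.
        if members.sum() < 1:
            return -np.inf
        mask = members[:, None] | members[None, :]
        mask &= ~np.eye(n, dtype=bool)
        vals = mat.values[mask]
        return float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else -np.inf

    means = {c: cluster_mean(labels == c) for c in (0, 1)}
    if not np.isfinite(max(means.values())):
        raise SelectionImpossibleError("no cluster has a defined mean SDA")
    best = max(means, key=lambda c: means[c])
    if (labels == (1 - best)).sum() == 0:
        inliers = list(range(n))
    else:
        inliers = [i for i in range(n) if labels[i] == best]
    outliers = [i for i in range(n) if i not in inliers]
    return SelectionResult(
        [ids[i] for i in inliers],
        [ids[i] for i in outliers],
        {
            "inliers": means[best],
            "outliers": means[1 - best] if outliers else np.nan,
        },
        sda=mat,
    )


def align_inliers(
    inliers: Sequence[Annotation],
    band_s: float = 5.0,
    seed: int = 0,
) -> AlignmentResult:
    """Warp every inlier onto the one with the largest mean agreement.

    The reference is the inlier whose mean pairwise SDA (on DTW-aligned
    pairs) to the others is maximal; everyone else is DTW-warped onto its
    grid within ``band_s``.
    """
    if len(inliers) < 2:
        raise ShapeError("need at least 2 inliers")
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.generate_state(len(inliers) ** 2 + 1)[1:])

    def aligner(a: Annotation, b: Annotation) -> tuple[Annotation, Annotation]:
        return dtw_align_pair(a, b, band_s=band_s, seed=int(next(pair_seeds)) % (2**31))

    mat = sda_matrix(inliers, pair_aligner=aligner)
    means = [mat.mean_offdiagonal(i) for i in range(len(inliers))]
    ref_idx = int(np.nanargmax(means))
    ref = inliers[ref_idx]
    band = int(round(band_s * ref.rate_hz))

    warped = []
    paths: dict[str, np.ndarray] = {}
    for i, ann in enumerate(inliers):
        if i == ref_idx:
            warped.append(ann)
            ident = np.arange(len(ann))
            paths[ann.annotator_id] = np.stack([ident, ident], axis=1)
            continue
        w, path = _warp_onto(ref, ann, band)
        warped.append(w)
        paths[ann.annotator_id] = path
    return AlignmentResult(ref.annotator_id, warped, paths, band_s)


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    joint, _, _ = np.histogram2d(x[ok], y[ok], bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def _shifted(values: np.ndarray, s: int) -> np.ndarray:
    """Shift right by ``s`` samples (left for negative), NaN-padding the edge."""
    out = np.full_like(values, np.nan)
    if s >= 0:
        out[s:] = values[: values.size - s] if s else values
    else:
        out[:s] = values[-s:]
    return out


def uniform_shift_align(
    annotations: Sequence[Annotation],
    max_shift_s: float = 5.0,
) -> AlignmentResult | None:
    """Per-annotation integer shifts maximizing mean pairwise mutual information.

    Values are discretized into 16 equal-width bins; shifts are optimized by
    coordinate ascent from zero.  Returns ``None`` (a legitimate outcome, not
    an error) when no shift within ``max_shift_s`` improves on zero shift —
    which is what happens on flat or otherwise MI-degenerate signals.
    """
    if len(annotations) < 2:
        raise ShapeError("need at least 2 annotations")
    rate = annotations[0].rate_hz
    max_shift = int(round(max_shift_s * rate))
    vals = [a.values for a in annotations]
    n = len(vals)

    def total_mi(shifts: list[int]) -> float:
        sigs = [_shifted(v, s) for v, s in zip(vals, shifts)]
        return sum(
            _mutual_information(sigs[i], sigs[j]) for i, j in combinations(range(n), 2)
        )

    shifts = [0] * n
    baseline = total_mi(shifts)
    best = baseline
    for _ in range(10):  # coordinate ascent rounds
        changed = False
        for i in range(n):
            cand_scores = []
            for s in range(-max_shift, max_shift + 1):
                trial = list(shifts)
                trial[i] = s
                cand_scores.append((total_mi(trial), s))
            score, s = max(cand_scores, key=lambda c: (c[0], -abs(c[1])))
            if score > best + 1e-12:
                best, shifts[i], changed = score, s, True
        if not changed:
            break
    if best <= baseline + 1e-12:
        return None
    ref = annotations[0]
    warped = []
    paths: dict[str, np.ndarray] = {}
    for a, s in zip(annotations, shifts):
        out = _shifted(a.values, s)
        warped.append(
            Annotation(a.annotator_id, a.stimulus_id, a.rate_hz, out, t0=ref.t0,
                       v_min=a.v_min, v_max=a.v_max)
        )
        ident = np.arange(len(a))
        paths[a.annotator_id] = np.stack([ident, np.clip(ident - s, 0, len(a) - 1)], axis=1)
    return AlignmentResult(
        ref.annotator_id, warped, paths, band_s=max_shift_s,
        shifts={a.annotator_id: s for a, s in zip(annotations, shifts)},
    )
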