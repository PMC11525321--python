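"""End-to-end orchestration: annotations in, ground truth out.

Wires the stages together in the canonical order — inlier selection on
DTW-aligned SDA affinities, inlier re-alignment, per-annotation trapezoidal
segmentation, trend voting, flat-region extraction, then either the ordinal
comparison/embedding fusion or the sample-wise averaging baseline.  Regions
from several stimuli can be pooled into one joint embedding, which is what
makes the resulting values comparable across stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .align_select import AlignmentResult, SelectionResult, align_inliers, select_inliers
from .annotation_io import Annotation
from .errors import ShapeError
from .ordinal_fusion import (
    FlatRegion,
    GroundTruth,
    MergedTSS,
    PairwiseComparison,
    baseline_average,
    extract_flat_regions,
    run_comparison_loop,
    trend_vote,
)
from .simulator import TrueSignal
from .tsr import annotation_tss

__all__ = [
    "ConsensusStage",
    "consensus_regions",
    "ordinal_ground_truth",
    "baseline_ground_truth",
    "region_true_levels",
]


@dataclass
class ConsensusStage:
    """Everything the per-stimulus half of the pipeline produces."""

    stimulus_id: str
    selection: SelectionResult
    alignment: AlignmentResult
    merged: MergedTSS
    regions: list[FlatRegion]
    grid_len: int

    @property
    def aligned(self) -> list[Annotation]:
        return self.alignment.warped


def consensus_regions(
    annotations: Sequence[Annotation],
    band_s: float = 5.0,
    seed: int = 0,
    min_len_samples: int = 2,
    t_hat: int | None = None,
    smooth_w: int = 5,
) -> ConsensusStage:
    """Select inliers, align them, segment trends, vote, and extract flats.

    One call per stimulus.  Region ids are prefixed with the stimulus id so
    regions from several stimuli can safely share one joint embedding.
    """
    stims = {a.stimulus_id for a in annotations}
    if len(stims) != 1:
        raise ShapeError(f"annotations span multiple stimuli: {sorted(stims)}")
    stim = next(iter(stims))
    selection = select_inliers(annotations, band_s=band_s, seed=seed)
    inliers = [a for a in annotations if a.annotator_id in selection.inlier_ids]
    alignment = align_inliers(inliers, band_s=band_s, seed=seed)
    tss_list = [
        annotation_tss(a.values, t_hat=t_hat, smooth_w=smooth_w,
                       source_id=a.annotator_id)[0]
        for a in alignment.warped
    ]
    merged = trend_vote(tss_list)
    regions = extract_flat_regions(
        merged, min_len_samples=min_len_samples, stimulus_id=stim,
        id_prefix=f"{stim}/r" if stim else "r",
    )
    return ConsensusStage(
        stim, selection, alignment, merged, regions, grid_len=len(merged.codes)
    )


def ordinal_ground_truth(
    stages: Sequence[ConsensusStage] | ConsensusStage,
    comparison_source: Callable[[FlatRegion, FlatRegion], PairwiseComparison],
    batch_size: int = 5000,
    rho_stop: float = 0.8,
    seed: int = 0,
    embed_kwargs: dict | None = None,
) -> tuple[GroundTruth | dict[str, GroundTruth], list[dict]]:
    """Fuse one or more stimuli's regions through the ordinal machinery.

    Pools all stages' flat regions into the batched comparison loop with one
    joint embedding, so values are comparable across the pooled stimuli.
    Returns the per-stimulus ground truth(s) and the loop history.
    """
    if isinstance(stages, ConsensusStage):
        stages = [stages]
    regions = [r for st in stages for r in st.regions]
    grid_lens = {st.stimulus_id: st.grid_len for st in stages}
    return run_comparison_loop(
        regions,
        comparison_source,
        grid_lens,
        batch_size=batch_size,
        rho_stop=rho_stop,
        seed=seed,
        embed_kwargs=embed_kwargs,
    )


def baseline_ground_truth(stage: ConsensusStage) -> GroundTruth:
    """Sample-wise average of the stage's aligned inliers."""
    return baseline_average(stage.aligned)


def region_true_levels(
    regions: Sequence[FlatRegion],
    truths: Mapping[str, TrueSignal] | TrueSignal,
) -> dict[str, float]:
    """Mean latent construct level over each region's window.

    The comparison oracle judges regions by these levels; using the mean over
    the *extracted* window (rather than the planted flat level) reflects that
    a human judges the excerpt actually shown.
    """
    out: dict[str, float] = {}
    for r in regions:
        truth = truths if isinstance(truths, TrueSignal) else truths[r.stimulus_id]
        out[r.region_id] = float(np.mean(truth.values[r.start : r.end]))
    return out
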