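# Methods

## Measurement model

A latent construct signal T(t) evolves over a stimulus.  Annotator *i*
reports P_i[T(t − lag_i)] + errors, where P_i is a personal, strictly
increasing (approximately monotone) perception map.  Two consequences drive
the whole design:

* values are not comparable across raters (each P_i differs), but
* the **sign** of every change survives any monotone P_i, so trends are the
  reliable channel.

Signed differential agreement (SDA) operationalizes this: the mean over grid
steps of ±1 according to whether two signals' difference signs match.  It is
symmetric, bounded in [−1, 1], equal to 1 for any pair related by a strictly
increasing transform, and invariant to affine rescaling of either input.
Differences with magnitude ≤ `zero_tol` (default 1e−9, an absolute float
guard) count as "no change"; a step enters the average only when all four
involved samples are present, and the normalizer shrinks accordingly.
Note that δ(0, 0) = +1: on signals dominated by holds, SDA of even an
*inverted* pair is pulled toward +1 by the shared flat stretches.  Selection
therefore relies on contrast between pairs, not on absolute SDA values.

## Resampling and the gap rule

Event logs are changes-only: a silent logger means either "nothing changed"
(endpoints equal — a valid constant hold) or "data lost while something
changed" (endpoints differ).  Annotations are resampled to a uniform grid
(default 1 Hz) by linear interpolation, and grid points strictly inside a
silent span longer than `gap_tol_s` with unequal endpoints are set to NaN
instead of being invented.  `gap_tol_s` defaults to two grid periods:
a changes-only logger running at normal cadence produces inter-event spans
shorter than that, so only genuine lapses fire the rule.  An optional
`max_const_hold` flags the interior of suspiciously long equal-valued holds
as well (off by default: holds are trusted, because the logger records only
changes).  The grid starts at the first event — how pre-first-event time
should be treated is not defined by the logs, so it is simply not
represented.

## Alignment and selection

Pairs are aligned by dynamic time warping with the symmetric step pattern
(moves (1,1), (1,0), (0,1)), squared local cost, and a Sakoe–Chiba band of
`band_s` seconds (default 5 s).  Missing samples get zero local cost so gaps
neither attract nor repel the path; a signal more than 20 % missing triggers
a warning.  The reference of a pair is chosen uniformly at random under the
seed; multi-matched samples are averaged when a signal is warped onto the
reference grid.

Selection is a binary clustering of the affinity matrix (SDA + 1)/2
(undefined pairs impute 0) with scikit-learn's spectral clustering
(normalized Laplacian, seeded k-means, 10 restarts).  The inlier cluster is
the one with the higher mean SDA **over all pairs involving its members**,
within-cluster and crossing pairs alike.  A within-cluster-only mean was
rejected during development: two adversaries sharing an inverted percept
agree perfectly with each other and would beat any realistically noisy
majority cluster; counting crossing pairs makes the cluster that agrees with
the panel at large win, which is what "majority consensus" means.  With
three or fewer annotations a bipartition is meaningless and everything is
kept.  Inliers are then re-aligned to the inlier with the highest mean SDA.

The uniform-shift aligner (integer shifts maximizing mean pairwise mutual
information over 16 equal-width value bins, coordinate ascent from zero)
is provided as an alternative; returning "no useful shift" on flat-heavy
signals is an expected outcome, not an error.

## Trapezoidal segmented regression

The fit is pinned to a finite, exactly solvable contract:

* breakpoints at sample indices;
* breakpoint values on the *level grid* = unique sample values ∪ {mean}
  (the mean guarantees the T = 1 fit is the exact least-squares constant;
  sample values guarantee zero error on any grid-realizable trapezoid);
* "flat" segments have exactly zero slope; "sloped" segments are free linear
  pieces (they may degenerate to zero slope — a hard slope ≠ 0 constraint on
  a finite grid would break the monotonicity of error in the budget);
* both parities (flat-first / sloped-first) are searched; ties prefer
  flat-first; T counts all segments.

Within this space a dynamic program over (breakpoint, level) states returns
the global least-squares optimum for **every** budget up to T in one pass
(O(N²·V²·T) work, V = level-grid size), which the budget heuristic reuses.
Consequences worth knowing: the sum of squared errors is non-increasing
along T, T+2 chains (two extra segments can replicate any fit containing a
flat of length ≥ 3) but adjacent budgets change parity and need not be
nested; and the optimal T = 1 fit is usually the free line, not the constant
— the constant is optimal only when the best line is horizontal.

T̂ estimation (the stand-in for eyeballing the trace) counts maximal
equal-sign runs of the smoothed first difference (moving average of
`smooth_w` = 5 samples; signs quantized at 15 % of the largest smoothed
step).  Budget selection fits all candidates ⌊4T̂/5⌋…⌈6T̂/5⌉ (floored at 1,
capped at N−1), profiles SDA and Kendall τ-b between each fitted signal and
the annotation, and scans upward to the first local maximum of SDA, then
onward to the next local maximum of τ; a monotone profile peaks at its end.
Missing data: the fit covers the longest contiguous non-missing block, and
samples outside it receive trend code 0.

## Ordinal correction

Per-sample slope signs of each inlier's fit are merged by plurality vote
(ties → 0: under disagreement the conservative claim is "no trend", and
flats are exactly what the ordinal machinery can correct).  Maximal zero
runs of length ≥ 2 samples become flat regions — one-sample excerpts cannot
be shown to a comparison rater.

Pairwise judgements (a, b, "a is lower") become triplets (r, a, b) against a
hypothetical lowest excerpt r, and t-STE places all items on the line by
maximizing Σ log p with p = k(d_an)/(k(d_an) + k(d_af)),
k(d) = (1 + d²/α)^−(α+1)/2.  Numerical choices:

* α = 1 (the conventional d − 1 degenerates at d = 1);
* L-BFGS with analytic gradients, 10 seeded restarts, 2000 iterations,
  gradient tolerance 1e−7;
* an L2 penalty λ‖z‖² with λ = 0.01.  With perfectly consistent triplets
  the heavy-tailed likelihood grows without bound as groups separate, so an
  unpenalized optimum has arbitrary scale; λ pins the scale.  It is kept
  small because a strong penalty measurably distorts noisy embeddings.
* **Folding.**  Dummy-anchored triplets constrain only each item's distance
  to r, leaving its side of the line unidentified — mirror images of any
  subset are equally likely.  When every anchor is the dummy, the embedding
  is canonicalized (likelihood-invariantly) by folding all items onto one
  side of r before the global orientation step.  Orientation then reverses
  the line if needed so r sits at the low end, and r is dropped.

Reconstruction writes each region's embedded value as a constant over its
window, joins consecutive regions by linear ramps, and holds the nearest
region's value before the first and after the last region.  The result is
ordinal: any strictly increasing transform of the embedded values transforms
flat-region samples exactly and preserves every ramp's direction, but
interpolated ramp samples do not commute with nonlinear transforms — rank
comparisons between a ramp sample and a flat of intermediate level depend on
embedding spacing, which ordinal data only loosely determines.  This is the
main accuracy limit of the reconstruction, and the reason region-level
summaries (max, min, …) are more trustworthy than sample-level values.

Comparisons are collected in uniform random batches without replacement
(default 5000 pairs); after each batch everything gathered so far is
re-embedded and candidates are reconstructed; the loop stops when successive
candidates reach Spearman ρ ≥ 0.8 for every stimulus in scope or the pairs
run out.  Regions of several stimuli may be pooled into one joint embedding,
which is what makes values comparable across stimuli; per-stimulus
embeddings are available when cross-stimulus comparability is not needed.

## Simulator

`generate_true_signal` builds alternating flat/trend runs (each ≥ 2 samples;
consecutive flat levels differ by ≥ ¼ of the level range so every trend is
real) and records the flat windows and levels.  `simulate_annotation`
composes, on the annotation scale −100..100:

| component | default | meaning |
| --- | --- | --- |
| perception P_i | 4 random interior knots, piece slopes U(0.05, 1) | personal monotone value mapping |
| lag | U(0.5, 2.0) s per rater | perceptuo-motor delay |
| overshoot | gain 0.5 × perceived step, 3-sample exponential decay at each trend onset | systematic over-adjustment; identical gain across raters, so it does **not** average out |
| drift | sd 20, low-pass 0.02 Hz walk **sampled at run onsets**, half shared across the panel, half individual | inconsistent revaluation of equal-construct moments |
| noise | sd 2 white | motor jitter |
| dead zone | 5 units | the slider moves only when the intended position differs enough, so holds are exact — as in real changes-only logs |

Two modeling points deserve emphasis.  First, drift is *held constant within
each run* and re-drawn (from the slow walk) at run onsets: raters re-anchor
their value scale when they act, not while the slider is parked.  A
continuously applied walk would paint slow trends over genuinely flat spans
— contradicting the premise that trends are captured reliably — and at
realistic amplitudes it drags clipped traces across the whole scale.
Second, half of the drift is shared across the panel (seeded by the
stimulus): valuation errors are documented to be structured and consistent
across raters, and a purely individual drift would vanish under sample-wise
averaging, making the baseline look better than it is in practice.
Adversarial raters (`invert=True`) use a strictly decreasing perception.

The comparison oracle picks the truly lower region with probability
1/(1 + e^(−β·|Δlevel|)); β → ∞ is noiseless, β = 0 a coin flip; equal levels
draw uniformly and are flagged.  Regions are judged by the mean latent level
over the *extracted* window, as a human judges the excerpt actually shown.

## Study conditions used by the end-to-end tests

Desk-scale analogues of a crowd-sourced study, chosen once: stimuli of 60
samples at 1 Hz with 5 runs (flats long relative to ramps, as in real
clips); panels of 8 structured-error raters plus 2 inverted adversaries;
noiseless oracle; 10 seeds.  The five-stimulus experiment rescales five such
signals so their peak levels are exactly 1…5 and pools all regions into one
joint embedding.  Smaller, trend-dense signals (7 runs in 60 samples, runs ≥
3) are used for the selection-recovery property, where sharper trend
contrast in SDA is the point.  What passing shows: the pipeline's ordinal
correction recovers latent structure its averaging baseline cannot, under
the stated error model.  What it does not show: performance on real crowd
data, constructs with weak inter-rater consensus, or multi-dimensional
annotation.

## Known limitations

* SDA's δ(0,0) = +1 compresses contrast on hold-dominated signals; absolute
  SDA values are not comparable across stimuli with different flat fractions.
* The TSR level grid is a discretization; off-grid breakpoint values are not
  searched (the cited continuous-breakpoint formulation would require a
  different optimizer and would break the exact-oracle property).
* Embedding spacing — hence sample-level ramp ranking — is only loosely
  identified by ordinal data; region-level summaries are the reliable output.
* The batched loop re-embeds from scratch each round; at very large region
  counts an incremental scheme would be preferable.
* Ground-truth values are unanchored: comparable within one embedding, not
  across methods or to any external scale.
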