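import numpy as np
import pytest
from scipy import stats

from ogt.errors import (
    ExhaustedPairsError,
    NoInformationError,
    ReconstructionImpossibleError,
    ShapeError,
)
from ogt.ordinal_fusion import (
    DUMMY_ID,
    Embedding,
    FlatRegion,
    GroundTruth,
    MergedTSS,
    PairwiseComparison,
    Triplet,
    baseline_average,
    extract_flat_regions,
    pairs_to_triplets,
    reconstruct,
    run_comparison_loop,
    sample_pairs,
    trend_vote,
    tste_embed,
)
from ogt.simulator import ComparisonOracle
from ogt.tsr import TSS
from conftest import make_annotation


def regions_from(windows, stim="stim"):
    return [FlatRegion(f"r{i}", stim, a, b) for i, (a, b) in enumerate(windows)]


class TestTrendVote:
    def test_plurality_with_margin(self):
        merged = trend_vote([TSS([1]), TSS([1]), TSS([0])])
        assert merged.codes[0] == 1
        assert merged.vote_margins[0] == 1

    def test_single_tss_is_identity(self):
        codes = np.array([1, 0, -1, 0, 1], dtype=np.int8)
        merged = trend_vote([TSS(codes)])
        np.testing.assert_array_equal(merged.codes, codes)

    def test_tie_resolves_to_flat(self):
        merged = trend_vote([TSS([1]), TSS([-1])])
        assert merged.codes[0] == 0
        assert merged.vote_margins[0] == 0

    def test_idempotent_on_identical_inputs(self, rng):
        codes = rng.choice([-1, 0, 1], 30)
        merged = trend_vote([TSS(codes)] * 5)
        np.testing.assert_array_equal(merged.codes, codes)

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            trend_vote([TSS([1, 0]), TSS([1])])


class TestExtractFlatRegions:
    def test_two_runs_meet_min_len(self):
        merged = trend_vote([TSS([0, 0, 1, 0, 0, 0, -1, 0])])
        regions = extract_flat_regions(merged, min_len_samples=2)
        assert [(r.start, r.end) for r in regions] == [(0, 2), (3, 6)]

    def test_all_zero_codes_single_region(self):
        merged = trend_vote([TSS(np.zeros(10, dtype=np.int8))])
        regions = extract_flat_regions(merged)
        assert [(r.start, r.end) for r in regions] == [(0, 10)]

    def test_runs_below_min_len_dropped(self):
        merged = trend_vote([TSS([0, 0, 1, 0, 0])])
        assert extract_flat_regions(merged, min_len_samples=3) == []


class TestSamplePairs:
    def test_exhaustive_draw_covers_all_pairs(self):
        regions = regions_from([(0, 2), (3, 5), (6, 8), (9, 11)])
        pairs = sample_pairs(regions, 6, seed=1)
        assert len({frozenset((a.region_id, b.region_id)) for a, b in pairs}) == 6

    def test_overdraw_raises(self):
        regions = regions_from([(0, 2), (3, 5), (6, 8), (9, 11)])
        with pytest.raises(ExhaustedPairsError):
            sample_pairs(regions, 7, seed=1)

    def test_batches_never_repeat_pairs(self):
        regions = regions_from([(i * 3, i * 3 + 2) for i in range(6)])
        asked = set()
        seen = set()
        for batch in range(3):
            pairs = sample_pairs(regions, 5, seed=batch, already_asked=asked)
            keys = {frozenset((a.region_id, b.region_id)) for a, b in pairs}
            assert not (keys & seen)
            seen |= keys
            asked |= keys


class TestPairsToTriplets:
    def test_lower_choice_becomes_near_item(self):
        c = PairwiseComparison("j", "k", choice="j")
        (t,) = pairs_to_triplets([c])
        assert (t.anchor, t.near, t.far) == (DUMMY_ID, "j", "k")

    def test_count_conservation_and_contradictions_kept(self):
        cs = [
            PairwiseComparison("a", "b", "a"),
            PairwiseComparison("a", "b", "b"),
        ]
        trips = pairs_to_triplets(cs)
        assert len(trips) == 2
        assert {(t.near, t.far) for t in trips} == {("a", "b"), ("b", "a")}

    def test_empty_input_empty_output(self):
        assert pairs_to_triplets([]) == []


class TestTSTEEmbed:
    @staticmethod
    def all_pair_comparisons(order):
        from itertools import combinations

        rank = {x: i for i, x in enumerate(order)}
        return [
            PairwiseComparison(a, b, a if rank[a] < rank[b] else b)
            for a, b in combinations(order, 2)
        ]

    def test_consistent_triplets_fully_recovered(self):
        order = [f"i{k}" for k in range(10)]
        trips = pairs_to_triplets(self.all_pair_comparisons(order))
        emb = tste_embed(trips, order, seed=3)
        z = np.array([emb.values[i] for i in order])
        assert stats.spearmanr(z, np.arange(10)).statistic == pytest.approx(1.0)
        # every triplet satisfied relative to the dummy at 0
        full = dict(emb.values, **{DUMMY_ID: 0.0})
        assert all(
            abs(full[t.near] - full[t.anchor]) < abs(full[t.far] - full[t.anchor])
            for t in trips
        )

    def test_single_comparison_orients_pair(self):
        trips = pairs_to_triplets([PairwiseComparison("j", "k", "j")])
        emb = tste_embed(trips, ["j", "k"], seed=0)
        assert emb.values["j"] < emb.values["k"]

    def test_no_triplets_raises(self):
        with pytest.raises(NoInformationError):
            tste_embed([], ["a", "b"])

    def test_isolated_items_flagged(self):
        trips = pairs_to_triplets([PairwiseComparison("a", "b", "a")])
        emb = tste_embed(trips, ["a", "b", "lonely"], seed=0)
        assert emb.isolated == ["lonely"]

    def test_contradictory_duplicates_resolved_by_majority(self):
        # two raters say a < b, one says b < a: the embedding follows the majority
        comps = [
            PairwiseComparison("a", "b", "a"),
            PairwiseComparison("a", "b", "a"),
            PairwiseComparison("a", "b", "b"),
            PairwiseComparison("b", "c", "b"),
            PairwiseComparison("a", "c", "a"),
        ]
        emb = tste_embed(pairs_to_triplets(comps), ["a", "b", "c"], seed=2)
        assert emb.values["a"] < emb.values["b"] < emb.values["c"]


class TestReconstruct:
    def test_interpolation_arithmetic(self):
        regions = regions_from([(0, 3), (5, 8)])
        emb = Embedding({"r0": 0.1, "r1": 0.9}, True, 0.0)
        gt = reconstruct(regions, emb, 8)
        np.testing.assert_allclose(gt.values[:3], 0.1)
        np.testing.assert_allclose(gt.values[5:], 0.9)
        ramp = np.interp([3, 4], [2, 5], [0.1, 0.9])
        np.testing.assert_allclose(gt.values[3:5], ramp)

    def test_single_region_constant_signal(self):
        gt = reconstruct(regions_from([(0, 10)]), Embedding({"r0": 0.4}, True, 0.0), 10)
        np.testing.assert_allclose(gt.values, 0.4)

    def test_edges_hold_nearest_region_value(self):
        gt = reconstruct(regions_from([(3, 5)]), Embedding({"r0": 2.0}, True, 0.0), 9)
        np.testing.assert_allclose(gt.values, 2.0)

    def test_no_regions_raises(self):
        with pytest.raises(ReconstructionImpossibleError):
            reconstruct([], Embedding({}, True, 0.0), 5)

    def test_monotone_transform_of_embedding_commutes_on_flats(self):
        # ordinal semantics: region samples transform exactly with the values,
        # and every ramp keeps its direction (interpolated ramp samples are not
        # claimed to commute with nonlinear transforms)
        regions = regions_from([(0, 3), (5, 8), (10, 13)])
        vals = {"r0": 0.2, "r1": 1.4, "r2": 0.7}
        gt1 = reconstruct(regions, Embedding(vals, True, 0.0), 13)
        gt2 = reconstruct(
            regions, Embedding({k: np.exp(v) for k, v in vals.items()}, True, 0.0), 13
        )
        for r in regions:
            np.testing.assert_allclose(gt2.values[r.start : r.end],
                                       np.exp(gt1.values[r.start : r.end]))
        for a, b in ((2, 5), (7, 10)):  # ramps between consecutive regions
            np.testing.assert_array_equal(
                np.sign(np.diff(gt1.values[a : b + 1])),
                np.sign(np.diff(gt2.values[a : b + 1])),
            )


class TestBaselineAverage:
    def test_sample_wise_mean(self):
        gt = baseline_average(
            [make_annotation([0.0, 2.0]), make_annotation([2.0, 0.0])]
        )
        np.testing.assert_allclose(gt.values, [1.0, 1.0])

    def test_single_annotation_identity(self, wiggly_signal):
        gt = baseline_average([make_annotation(wiggly_signal)])
        np.testing.assert_allclose(gt.values, wiggly_signal)

    def test_missing_values_excluded_from_mean(self):
        rows = [
            [1.0, np.nan, 3.0],
            [3.0, 4.0, np.nan],
            [5.0, 6.0, np.nan],
        ]
        gt = baseline_average([make_annotation(r) for r in rows])
        np.testing.assert_allclose(gt.values, [3.0, 5.0, 3.0])


class TestComparisonLoop:
    def test_noiseless_oracle_stops_at_stable_candidate(self, rng):
        regions = regions_from([(i * 5, i * 5 + 3) for i in range(12)])
        levels = {f"r{i}": float(v) for i, v in enumerate(rng.permutation(12))}
        gt, hist = run_comparison_loop(
            regions, ComparisonOracle(levels, seed=1), 60,
            batch_size=20, rho_stop=0.8, seed=3,
        )
        assert isinstance(gt, GroundTruth)
        final = hist[-1]["rho"]["stim"]
        assert final >= 0.8
        assert hist[-1]["n_comparisons"] < 66  # stopped before exhausting pairs

    def test_unattainable_threshold_runs_to_exhaustion(self, rng):
        regions = regions_from([(i * 5, i * 5 + 3) for i in range(8)])
        levels = {f"r{i}": float(i) for i in range(8)}
        gt, hist = run_comparison_loop(
            regions, ComparisonOracle(levels, seed=1), 40,
            batch_size=10, rho_stop=1.01, seed=3,
        )
        assert hist[-1]["n_comparisons"] == 28  # all C(8,2) pairs

    def test_final_partial_batch_used(self, rng):
        regions = regions_from([(i * 5, i * 5 + 3) for i in range(6)])
        levels = {f"r{i}": float(i) for i in range(6)}
        gt, hist = run_comparison_loop(
            regions, ComparisonOracle(levels, seed=1), 30,
            batch_size=10, rho_stop=1.01, seed=3,
        )
        assert [h["n_comparisons"] for h in hist] == [10, 15]
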