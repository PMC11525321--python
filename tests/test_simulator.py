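import numpy as np
import pytest

from ogt.agreement import sda
from ogt.annotation_io import resample
from ogt.errors import DegenerateInputError
from ogt.ordinal_fusion import FlatRegion
from ogt.simulator import (
    AnnotatorModel,
    ComparisonOracle,
    annotation_to_event_log,
    generate_true_signal,
    make_annotator_pool,
    oracle_compare,
    simulate_annotation,
)


def identity_annotator(**kw):
    return AnnotatorModel(
        "id0",
        perception_x=np.array([0.0, 1.0]),
        perception_y=np.array([0.0, 1.0]),
        lag_s=0.0,
        overshoot_gain=0.0,
        drift_sd=0.0,
        noise_sd=0.0,
        move_threshold=0.0,
        v_min=-100,
        v_max=100,
        **kw,
    )


class TestGenerateTrueSignal:
    def test_single_run_is_constant(self):
        ts = generate_true_signal(1, 20, seed=0)
        assert np.ptp(ts.values) == 0
        assert len(ts.flat_windows) == 1

    def test_recorded_flats_match_zero_slope_scan(self):
        ts = generate_true_signal(4, 40, seed=2)
        d = np.diff(ts.values)
        scanned = set()
        for s, e, _ in ts.flat_windows:
            scanned.add((s, e))
            assert np.allclose(d[s : e - 1], 0.0)
        # every zero-diff sample lies inside a recorded flat window
        for t in np.flatnonzero(np.abs(d) < 1e-12):
            assert any(s <= t < e for s, e, _ in ts.flat_windows)

    def test_deterministic_under_seed(self):
        a = generate_true_signal(5, 50, seed=9)
        b = generate_true_signal(5, 50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.flat_windows == b.flat_windows

    def test_infeasible_run_count_rejected(self):
        with pytest.raises(DegenerateInputError):
            generate_true_signal(10, 12, seed=0)


class TestSimulateAnnotation:
    def test_identity_limit_reproduces_truth(self):
        ts = generate_true_signal(5, 50, seed=1)
        ann = simulate_annotation(ts, identity_annotator())
        np.testing.assert_allclose(ann.values, ts.values)

    def test_noiseless_monotone_perception_preserves_every_trend(self):
        ts = generate_true_signal(5, 60, seed=4)
        model = AnnotatorModel(
            "m",
            perception_x=np.linspace(0, 1, 5),
            perception_y=np.array([-90.0, -20.0, 10.0, 15.0, 80.0]),
            lag_s=0.0, overshoot_gain=0.0, drift_sd=0.0, noise_sd=0.0,
            move_threshold=0.0,
        )
        ann = simulate_annotation(ts, model)
        assert sda(ann.values, ts.values) == 1.0

    def test_overshoot_peaks_inside_post_onset_window(self):
        ts = generate_true_signal(3, 40, seed=3)  # flat-trend-flat
        model = identity_annotator()
        model.overshoot_gain = 0.5
        ann = simulate_annotation(ts, model)
        dev = np.abs(ann.values - ts.values)
        onset = ts.flat_windows[0][1]  # trend starts where the first flat ends
        assert dev.max() > 0
        assert onset <= int(dev.argmax()) <= onset + 5

    def test_deterministic_under_seed(self):
        ts = generate_true_signal(5, 50, seed=1)
        pool_a = make_annotator_pool(3, seed=8)
        pool_b = make_annotator_pool(3, seed=8)
        for ma, mb in zip(pool_a, pool_b):
            va = simulate_annotation(ts, ma).values
            vb = simulate_annotation(ts, mb).values
            np.testing.assert_array_equal(va, vb)

    def test_drift_degrades_values_but_not_trends(self):
        # the package's core premise, made checkable by construction: a
        # continuous slider with headroom so drift shifts values without
        # saturating at the scale bounds (saturation flattens real trends)
        ts = generate_true_signal(5, 300, seed=6)
        pearson, sda_means = [], []
        for drift in (0.0, 8.0, 16.0):
            pool = make_annotator_pool(
                6, seed=17, drift_sd=drift, noise_sd=1.0, overshoot_gain=0.0,
                perception_inc_range=(0.3, 1.0), v_min=-60, v_max=60,
            )
            for m in pool:
                m.move_threshold = 0.0
                m.v_min, m.v_max = -100.0, 100.0
            anns = [simulate_annotation(ts, m) for m in pool]
            ps, ss = [], []
            for i in range(6):
                for j in range(i + 1, 6):
                    ps.append(np.corrcoef(anns[i].values, anns[j].values)[0, 1])
                    ss.append(sda(anns[i].values, anns[j].values))
            pearson.append(np.mean(ps))
            sda_means.append(np.mean(ss))
        assert pearson[0] > pearson[1] > pearson[2]
        assert abs(sda_means[1] - sda_means[0]) <= 0.05
        assert abs(sda_means[2] - sda_means[0]) <= 0.05


class TestComparisonOracle:
    def setup_method(self):
        self.a = FlatRegion("a", "s", 0, 2)
        self.b = FlatRegion("b", "s", 4, 6)

    def test_noiseless_limit_always_correct(self):
        oracle = ComparisonOracle({"a": 0.2, "b": 0.7}, seed=9)
        assert all(oracle(self.a, self.b).choice == "a" for _ in range(100))

    def test_beta_zero_is_a_coin_flip(self):
        oracle = ComparisonOracle({"a": 0.2, "b": 0.7}, beta=0.0, seed=9)
        freq = np.mean([oracle(self.a, self.b).choice == "a" for _ in range(1000)])
        assert abs(freq - 0.5) <= 0.05

    def test_equal_levels_flagged_random(self):
        cmp = oracle_compare((self.a, self.b), {"a": 0.5, "b": 0.5}, seed=0)
        assert cmp.flagged

    def test_deterministic_stream_under_seed(self):
        seqs = []
        for _ in range(2):
            oracle = ComparisonOracle({"a": 0.4, "b": 0.6}, beta=2.0, seed=5)
            seqs.append([oracle(self.a, self.b).choice for _ in range(50)])
        assert seqs[0] == seqs[1]


class TestEventLogExport:
    def test_round_trip_through_pagan_dialect(self, tmp_path):
        from ogt.annotation_io import load_event_log, write_event_log

        ts = generate_true_signal(5, 60, seed=2)
        (model,) = make_annotator_pool(1, seed=3)
        ann = simulate_annotation(ts, model)
        log = annotation_to_event_log(ann)
        p = tmp_path / "log.csv"
        write_event_log(log, p, "pagan_csv")
        back = load_event_log(p, "pagan_csv")
        assert back.events == log.events

    def test_changes_only_log_resamples_to_original(self):
        ts = generate_true_signal(5, 60, seed=2)
        (model,) = make_annotator_pool(1, seed=3)
        ann = simulate_annotation(ts, model)
        log = annotation_to_event_log(ann)
        back = resample(log, ann.rate_hz, gap_tol_s=np.inf)
        np.testing.assert_allclose(back.values, ann.values, atol=1e-9)

    def test_injected_gaps_flag_missing_downstream(self):
        ts = generate_true_signal(7, 80, seed=5)
        (model,) = make_annotator_pool(1, seed=6)
        ann = simulate_annotation(ts, model)
        log = annotation_to_event_log(ann, seed=1, n_gaps=2, gap_len_s=6.0)
        back = resample(log, 1.0)
        assert np.isnan(back.values).any()
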