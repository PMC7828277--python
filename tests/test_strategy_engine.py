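"""Update-strategy semantics: baselines, warm chains, pseudo-labels, slopes."""

import numpy as np
import pytest

from cuffdrift import strategy_engine as se
from cuffdrift.classifier import build_classifier, predict_proba, train
from cuffdrift.dataset_builder import build_dataset
from cuffdrift.strategy_engine import (
    StrategyRun,
    TimepointSequence,
    build_initial_levels,
    build_self_labelled,
    compute_slope_difference,
    evaluate_frozen,
    run_baseline_calibration,
    run_frequency_experiment,
    run_periodic_recalibration,
    run_self_learning,
    run_slope_analysis,
    train_base_states,
)

SEED = 21


@pytest.fixture(scope="module")
def drift_free_seq(small_encap_seq):
    """Same dataset at every time point: no drift at all."""
    _, ds = small_encap_seq.timepoints[0]
    return TimepointSequence([("T0", ds), ("T1", ds), ("T2", ds)], scenario="encapsulation", snr_db=-5.0)


@pytest.fixture(scope="module")
def base_states(small_encap_seq):
    return train_base_states(small_encap_seq, "linear_baseline", SEED)


class TestBaselineCalibration:
    def test_first_timepoint_is_plain_cross_validation(self, small_encap_seq, base_states):
        run = run_baseline_calibration(small_encap_seq, seed=SEED, base_states=base_states)
        tp0, ds0 = small_encap_seq.timepoints[0]
        for fold in range(5):
            state = train(
                build_classifier("linear_baseline", seed=SEED + fold, input_shape=ds0.matrices.shape[1:]),
                ds0, [f for f in range(5) if f != fold], seed=SEED + fold,
            )
            mask = ds0.fold_mask(fold)
            expected = se.macro_f1(predict_proba(state, ds0.matrices[mask]), ds0.labels[mask])
            got = [r["f1"] for r in run.records if r["timepoint"] == tp0 and r["fold"] == fold]
            assert got == [expected]

    def test_constant_trajectory_without_drift(self, drift_free_seq):
        run = run_baseline_calibration(drift_free_seq, seed=SEED)
        f1s = [run.mean_f1(tp) for tp in drift_free_seq.ids]
        assert f1s[0] == f1s[1] == f1s[2]  # identical data, frozen model


class TestPeriodicRecalibration:
    def test_non_decreasing_without_drift(self, drift_free_seq):
        run = run_periodic_recalibration(drift_free_seq, seed=SEED)
        f1s = [run.mean_f1(tp) for tp in drift_free_seq.ids]
        assert f1s[1] >= f1s[0] - 0.02 and f1s[2] >= f1s[0] - 0.02

    def test_not_worse_than_baseline_under_drift(self, small_encap_seq, base_states):
        rb = run_baseline_calibration(small_encap_seq, seed=SEED, base_states=base_states)
        rp = run_periodic_recalibration(small_encap_seq, seed=SEED, base_states=base_states)
        for tp in small_encap_seq.ids:
            assert rp.mean_f1(tp) >= rb.mean_f1(tp) - 0.02


class TestSelfLabelled:
    def test_threshold_rule(self, small_encap_seq, base_states):
        _, ds = small_encap_seq.timepoints[1]
        X, pseudo, counts, conf = build_self_labelled(base_states[0], ds, [1, 2, 3, 4], 0.95)
        assert np.all(conf >= 0.95)
        assert counts.sum() == len(pseudo) == X.shape[0]
        # pseudo-labels are the argmax predictions of the kept samples
        pred = predict_proba(base_states[0], X)
        assert np.array_equal(pred.labels, pseudo)

    def test_threshold_near_zero_keeps_whole_pool(self, small_encap_seq, base_states):
        _, ds = small_encap_seq.timepoints[1]
        X, _, counts, _ = build_self_labelled(base_states[0], ds, [1, 2, 3, 4], 1e-9)
        assert X.shape[0] == counts.sum() == ds.fold_mask([1, 2, 3, 4]).sum()

    def test_invalid_threshold_rejected(self, small_encap_seq, base_states):
        _, ds = small_encap_seq.timepoints[1]
        with pytest.raises(ValueError):
            build_self_labelled(base_states[0], ds, [1], threshold=1.0)


class TestSelfLearning:
    def test_counts_logged_and_confident(self, small_encap_seq, base_states):
        run = run_self_learning(
            small_encap_seq, seed=SEED, base_states=base_states, min_per_class=5
        )
        counts = run.counts_frame()
        assert len(counts) > 0
        n_cols = [c for c in counts.columns if c.startswith("n_")]
        assert (counts[n_cols] >= 0).all().all()

    def test_stop_rule_fires_on_unconfident_model(self, small_encap_seq):
        """A time point of pure noise yields low-confidence predictions and
        halts the run with no retrained results afterwards."""
        tp0, ds0 = small_encap_seq.timepoints[0]
        rng = np.random.default_rng(0)
        noise = build_dataset(
            rng.normal(0, 0.2, ds0.matrices.shape).astype(np.float32),
            ds0.labels.copy(), seed=1,
        )
        seq = TimepointSequence([(tp0, ds0), ("TX", noise), ("TY", ds0)], snr_db=-5.0)
        run = run_self_learning(seq, seed=SEED, threshold=0.9999, min_per_class=200)
        assert run.stopped_at == "TX"
        assert all(r["timepoint"] == tp0 for r in run.records)

    def test_stop_monotone_no_later_records(self, small_encap_seq, base_states):
        run = run_self_learning(
            small_encap_seq, seed=SEED, base_states=base_states, min_per_class=10**6
        )
        assert run.stopped_at == small_encap_seq.ids[1]
        recorded = {r["timepoint"] for r in run.records}
        assert recorded == {small_encap_seq.ids[0]}


class TestFrequencyExperiment:
    def test_m1_equals_plain_self_learning_step(self, small_encap_seq, base_states):
        sub = TimepointSequence(small_encap_seq.timepoints[:2], snr_db=-5.0)
        plain = run_self_learning(sub, seed=SEED, base_states=base_states, min_per_class=5)
        freq = run_frequency_experiment(sub, 1, base_states, min_per_class=5, seed=SEED)
        tp1 = sub.ids[1]
        for fold in range(5):
            a = [r["f1"] for r in plain.records if r["timepoint"] == tp1 and r["fold"] == fold]
            b = [r["f1"] for r in freq.records if r["timepoint"] == tp1 and r["fold"] == fold]
            assert a == b  # identical retrained result, bit for bit

    def test_m2_inserts_one_interpolated_step(self, small_encap_seq, base_states):
        sub = TimepointSequence(small_encap_seq.timepoints[:2], snr_db=-5.0)
        run = run_frequency_experiment(sub, 2, base_states, min_per_class=5, seed=SEED)
        tps = set(run.counts_frame()["timepoint"])
        tp1 = sub.ids[1]
        assert tps == {f"{tp1}@0.5", f"{tp1}@1"}

    def test_invalid_frequency_rejected(self, small_encap_seq, base_states):
        sub = TimepointSequence(small_encap_seq.timepoints[:2], snr_db=-5.0)
        with pytest.raises(ValueError):
            run_frequency_experiment(sub, 3, base_states, seed=SEED)
        run = run_frequency_experiment(
            sub, 3, base_states, min_per_class=5, seed=SEED, allow_any_frequency=True
        )
        assert len(run.records) > 0

    def test_drift_free_frequencies_agree(self, drift_free_seq):
        states = train_base_states(drift_free_seq, "linear_baseline", SEED)
        f1s = {}
        for m in (1, 2):
            run = run_frequency_experiment(drift_free_seq, m, states, min_per_class=5, seed=SEED)
            f1s[m] = run.mean_f1(drift_free_seq.ids[-1])
        assert f1s[1] == pytest.approx(f1s[2], abs=0.05)


class TestInitialLevelsAndSlopes:
    def test_levels_share_base_lineage_and_order(self, small_encap_seq, base_states):
        levels = build_initial_levels(
            TimepointSequence(small_encap_seq.timepoints[:2], snr_db=-5.0),
            seed=SEED, base_states=base_states,
        )
        assert set(levels) == {"HP", "LP"}
        assert levels["HP"]["f1"] >= levels["LP"]["f1"] - 0.02
        for lv in levels.values():
            assert len(lv["states"]) == 5

    def test_slope_difference_arithmetic(self):
        strat, ctrl = StrategyRun("s"), StrategyRun("c")
        for fold in range(2):
            strat.add("ET1", fold, 0.9)
            strat.add("ET2", fold, 0.8)
            ctrl.add("ET1", fold, 0.9)
            ctrl.add("ET2", fold, 0.7)
        assert compute_slope_difference(strat, ctrl, "ET1", "ET2") == pytest.approx(0.1)
        assert compute_slope_difference(ctrl, ctrl, "ET1", "ET2") == 0.0
        harmful = StrategyRun("h")
        for fold in range(2):
            harmful.add("ET1", fold, 0.9)
            harmful.add("ET2", fold, 0.6)
        assert compute_slope_difference(harmful, ctrl, "ET1", "ET2") == pytest.approx(-0.1)

    def test_control_equals_baseline_calibration_from_start(self, small_encap_seq, base_states):
        rb = run_baseline_calibration(small_encap_seq, seed=SEED, base_states=base_states)
        ctrl = evaluate_frozen(base_states, small_encap_seq)
        for tp in small_encap_seq.ids:
            assert ctrl.mean_f1(tp) == rb.mean_f1(tp)

    def test_slope_analysis_grid(self, small_encap_seq):
        analysis = run_slope_analysis(
            small_encap_seq, frequencies=(1, 2), min_per_class=5, seed=SEED
        )
        df = analysis.to_frame()
        assert len(df) == 4  # 2 levels x 2 frequencies
        assert set(df["initial_level"]) == {"HP", "LP"}
        assert np.isfinite(df["slope_difference"]).all()
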