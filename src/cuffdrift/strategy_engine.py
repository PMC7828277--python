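"""Classifier update strategies across simulated time points.

Three strategies are compared on a sequence of signature datasets that share
one generator seed (identical fold assignments and event order, only the
leadfield drifts), so per-fold differences are attributable to the update
rule alone:

``baseline_calibration``
    Train once at the first time point, evaluate on every later one.

``periodic_recalibration``
    Warm-start retrain at every time point on its four training folds with
    true labels.

``self_learning``
    At each new time point, label the training pool with the previous
    model, keep only predictions with confidence (max softmax probability)
    above a threshold, warm-start retrain on the pseudo-labelled subset, and
    stop once any class's pseudo-labelled count falls below a minimum.

The module also runs the training-frequency / initial-performance analysis:
self-learning applied at ``m`` interpolated sub-steps between real time
points, started from a high- (supervised) or low- (self-learned) performance
state, summarized as the strategy-minus-control F1 slope between the first
two encapsulation time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierState,
    build_classifier,
    macro_f1,
    predict_proba,
    train,
    train_on_arrays,
)
from .dataset_builder import CLASS_LABELS, SignatureDataset, interpolate_datasets

__all__ = [
    "TimepointSequence",
    "StrategyRun",
    "SlopeAnalysis",
    "train_base_states",
    "run_baseline_calibration",
    "run_periodic_recalibration",
    "build_self_labelled",
    "run_self_learning",
    "run_frequency_experiment",
    "build_initial_levels",
    "evaluate_frozen",
    "compute_slope_difference",
    "run_slope_analysis",
    "VALID_FREQUENCIES",
]

VALID_FREQUENCIES = (1, 2, 4, 8)


@dataclass
class TimepointSequence:
    """Ordered (timepoint_id, dataset) pairs for one drift scenario/SNR."""

    timepoints: list[tuple[str, SignatureDataset]]
    scenario: str = "encapsulation"
    snr_db: float | None = None

    def __post_init__(self):
        if len(self.timepoints) < 1:
            raise ValueError("sequence needs at least one time point")
        n_folds = {ds.n_folds for _, ds in self.timepoints}
        if len(n_folds) != 1:
            raise ValueError("all time points must share the fold count")

    @property
    def ids(self) -> list[str]:
        return [tp for tp, _ in self.timepoints]

    @property
    def n_folds(self) -> int:
        return self.timepoints[0][1].n_folds

    def __len__(self) -> int:
        return len(self.timepoints)


@dataclass
class StrategyRun:
    """Per-(timepoint, fold) macro-F1 trajectory of one update strategy."""

    strategy: str
    records: list[dict] = field(default_factory=list)
    self_label_counts: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    stopped_at: str | None = None

    def add(self, timepoint: str, fold: int, f1: float):
        if not 0.0 <= f1 <= 1.0:
            raise ValueError("macro F1 must lie in [0, 1]")
        self.records.append({"timepoint": timepoint, "fold": fold, "f1": f1})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["timepoint", "fold", "f1"])
        df.insert(0, "strategy", self.strategy)
        return df

    def counts_frame(self) -> pd.DataFrame:
        cols = ["timepoint", "fold", *[f"n_{c}" for c in CLASS_LABELS]]
        df = pd.DataFrame(self.self_label_counts, columns=cols)
        df.insert(0, "strategy", self.strategy)
        return df

    def mean_f1(self, timepoint: str) -> float:
        vals = [r["f1"] for r in self.records if r["timepoint"] == timepoint]
        if not vals:
            raise ValueError(f"no F1 recorded at {timepoint!r}")
        return float(np.mean(vals))


def _eval_fold(state: ClassifierState, ds: SignatureDataset, fold: int) -> float:
    mask = ds.fold_mask(fold)
    pred = predict_proba(state, ds.matrices[mask])
    return macro_f1(pred, ds.labels[mask])


def _train_folds(ds: SignatureDataset, held_out: int) -> list[int]:
    return [f for f in range(ds.n_folds) if f != held_out]


def train_base_states(
    seq: TimepointSequence,
    classifier_spec: str,
    seed: int,
    epochs: int | None = None,
    **spec_overrides,
) -> list[ClassifierState]:
    """One classifier per fold, trained on the first time point's four
    training folds.  Shared across strategies for paired comparisons."""
    _, ds0 = seq.timepoints[0]
    states = []
    for fold in range(seq.n_folds):
        state = build_classifier(
            classifier_spec, seed=seed + fold, input_shape=ds0.matrices.shape[1:], **spec_overrides
        )
        states.append(train(state, ds0, _train_folds(ds0, fold), epochs=epochs, seed=seed + fold))
    return states


def run_baseline_calibration(
    seq: TimepointSequence,
    classifier_spec: str = "linear_baseline",
    seed: int = 0,
    base_states: list[ClassifierState] | None = None,
    epochs: int | None = None,
) -> StrategyRun:
    """Train once at the first time point; evaluate everywhere, no retraining."""
    if base_states is None:
        base_states = train_base_states(seq, classifier_spec, seed, epochs=epochs)
    run = StrategyRun("baseline_calibration", config={"classifier_spec": classifier_spec, "seed": seed})
    for tp, ds in seq.timepoints:
        for fold, state in enumerate(base_states):
            run.add(tp, fold, _eval_fold(state, ds, fold))
    return run


def run_periodic_recalibration(
    seq: TimepointSequence,
    classifier_spec: str = "linear_baseline",
    seed: int = 0,
    base_states: list[ClassifierState] | None = None,
    epochs: int | None = None,
) -> StrategyRun:
    """Warm-start supervised retraining at every time point."""
    if base_states is None:
        base_states = train_base_states(seq, classifier_spec, seed, epochs=epochs)
    run = StrategyRun("periodic_recalibration", config={"classifier_spec": classifier_spec, "seed": seed})
    states = [s.copy() for s in base_states]
    for t, (tp, ds) in enumerate(seq.timepoints):
        for fold in range(seq.n_folds):
            if t > 0:
                states[fold] = train(
                    states[fold], ds, _train_folds(ds, fold), epochs=epochs, seed=seed + 1000 * t + fold
                )
            run.add(tp, fold, _eval_fold(states[fold], ds, fold))
    return run


def build_self_labelled(
    state: ClassifierState,
    dataset: SignatureDataset,
    train_folds,
    threshold: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-label the training pool with the current model.

    Returns (X, pseudo_labels, per_class_counts, confidences of the kept
    samples).  Only samples whose maximum softmax probability reaches the
    threshold are kept; true labels are discarded.  An empty subset is legal.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = dataset.fold_mask(train_folds)
    pred = predict_proba(state, dataset.matrices[mask])
    keep = pred.confidences >= threshold
    pseudo = pred.labels[keep]
    counts = np.bincount(pseudo, minlength=len(CLASS_LABELS))
    return dataset.matrices[mask][keep], pseudo, counts, pred.confidences[keep]


def run_self_learning(
    seq: TimepointSequence,
    classifier_spec: str = "linear_baseline",
    threshold: float = 0.95,
    min_per_class: int = 200,
    seed: int = 0,
    base_states: list[ClassifierState] | None = None,
    epochs: int | None = None,
) -> StrategyRun:
    """Confidence-thresholded pseudo-label retraining with a stopping rule.

    At each new time point every fold's model labels that fold's training
    pool; it retrains on the confident subset and is tested on the held-out
    fold with true labels.  When any class's pseudo-labelled count drops
    below ``min_per_class`` in any fold, the run records ``stopped_at`` and
    neither retrains nor evaluates from that time point on.
    """
    if base_states is None:
        base_states = train_base_states(seq, classifier_spec, seed, epochs=epochs)
    run = StrategyRun(
        "self_learning",
        config={
            "classifier_spec": classifier_spec,
            "seed": seed,
            "threshold": threshold,
            "min_per_class": min_per_class,
        },
    )
    states = [s.copy() for s in base_states]
    for t, (tp, ds) in enumerate(seq.timepoints):
        if t == 0:
            for fold in range(seq.n_folds):
                run.add(tp, fold, _eval_fold(states[fold], ds, fold))
            continue
        stop_here = False
        fold_sets = []
        for fold in range(seq.n_folds):
            X, pseudo, counts, _ = build_self_labelled(
                states[fold], ds, _train_folds(ds, fold), threshold
            )
            run.self_label_counts.append(
                {"timepoint": tp, "fold": fold, **{f"n_{c}": int(n) for c, n in zip(CLASS_LABELS, counts)}}
            )
            fold_sets.append((X, pseudo))
            if np.any(counts < min_per_class):
                stop_here = True
        if stop_here:
            run.stopped_at = tp
            break
        for fold, (X, pseudo) in enumerate(fold_sets):
            states[fold] = train_on_arrays(
                states[fold], X, pseudo, epochs=epochs, seed=seed + 1000 * t + fold
            )
            run.add(tp, fold, _eval_fold(states[fold], ds, fold))
    return run


def _self_learning_step(
    state: ClassifierState,
    ds: SignatureDataset,
    fold: int,
    threshold: float,
    min_per_class: int,
    seed: int,
    epochs: int | None,
) -> tuple[ClassifierState | None, np.ndarray]:
    """One per-fold self-learning update; None state signals the stop rule."""
    X, pseudo, counts, _ = build_self_labelled(state, ds, _train_folds(ds, fold), threshold)
    if np.any(counts < min_per_class):
        return None, counts
    return train_on_arrays(state, X, pseudo, epochs=epochs, seed=seed), counts


def run_frequency_experiment(
    seq: TimepointSequence,
    frequency: int,
    initial_states: list[ClassifierState],
    threshold: float = 0.95,
    min_per_class: int = 200,
    seed: int = 0,
    epochs: int | None = None,
    allow_any_frequency: bool = False,
) -> StrategyRun:
    """Self-learning with ``frequency`` retraining sub-steps per time point.

    Between consecutive real time points, ``frequency - 1`` linearly
    interpolated datasets are inserted (alphas k/m); the model self-learns at
    every sub-step and at the endpoint, but F1 is reported only at the real
    time points.  The first sequence entry is the starting time point of the
    given per-fold states and is evaluated without retraining.
    """
    if frequency not in VALID_FREQUENCIES and not allow_any_frequency:
        raise ValueError(f"frequency must be one of {VALID_FREQUENCIES}")
    if len(seq) < 2:
        raise ValueError("need at least two time points")
    run = StrategyRun(
        "self_learning_freq",
        config={"frequency": frequency, "threshold": threshold, "min_per_class": min_per_class, "seed": seed},
    )
    n_folds = seq.n_folds
    states: list[ClassifierState | None] = [s.copy() for s in initial_states]
    tp0, ds0 = seq.timepoints[0]
    for fold in range(n_folds):
        run.add(tp0, fold, _eval_fold(states[fold], ds0, fold))
    for t in range(1, len(seq)):
        tp_a, ds_a = seq.timepoints[t - 1]
        tp_b, ds_b = seq.timepoints[t]
        for k in range(1, frequency + 1):
            alpha = k / frequency
            ds = ds_b if k == frequency else interpolate_datasets(ds_a, ds_b, alpha)
            stop = False
            for fold in range(n_folds):
                if states[fold] is None:
                    continue
                # endpoint sub-steps reuse the plain self-learning seeds so
                # frequency 1 reproduces run_self_learning bit for bit
                step_seed = (
                    seed + 1000 * t + fold
                    if k == frequency
                    else seed + 10_000 * t + 100 * k + fold
                )
                new_state, counts = _self_learning_step(
                    states[fold], ds, fold, threshold, min_per_class, step_seed, epochs
                )
                run.self_label_counts.append(
                    {"timepoint": f"{tp_b}@{alpha:g}", "fold": fold,
                     **{f"n_{c}": int(n) for c, n in zip(CLASS_LABELS, counts)}}
                )
                if new_state is None:
                    stop = True
                else:
                    states[fold] = new_state
            if stop:
                run.stopped_at = tp_b
                return run
        for fold in range(n_folds):
            run.add(tp_b, fold, _eval_fold(states[fold], ds_b, fold))
    return run


def build_initial_levels(
    seq_base_to_first: TimepointSequence,
    classifier_spec: str = "linear_baseline",
    threshold: float = 0.95,
    seed: int = 0,
    epochs: int | None = None,
    base_states: list[ClassifierState] | None = None,
    min_per_class: int = 1,
) -> dict[str, dict]:
    """High- and low-performance starting states at the second time point.

    HP applies one supervised (periodic-recalibration) step from the first
    time point to the second; LP applies one self-learning step.  Both share
    the same first-time-point lineage.  Returns
    {"HP": {"states": [...], "f1": ...}, "LP": {...}}.
    """
    if len(seq_base_to_first) < 2:
        raise ValueError("need the first two time points")
    if base_states is None:
        base_states = train_base_states(seq_base_to_first, classifier_spec, seed, epochs=epochs)
    _, ds1 = seq_base_to_first.timepoints[1]
    out: dict[str, dict] = {}
    hp_states, lp_states = [], []
    for fold in range(seq_base_to_first.n_folds):
        hp_states.append(
            train(base_states[fold], ds1, _train_folds(ds1, fold), epochs=epochs, seed=seed + 500 + fold)
        )
        X, pseudo, counts, _ = build_self_labelled(base_states[fold], ds1, _train_folds(ds1, fold), threshold)
        if np.all(counts >= max(min_per_class, 1)):
            lp_states.append(
                train_on_arrays(base_states[fold], X, pseudo, epochs=epochs, seed=seed + 600 + fold)
            )
        else:  # self-learning step impossible: LP stays at the base model
            lp_states.append(base_states[fold].copy())
    for name, states in (("HP", hp_states), ("LP", lp_states)):
        f1 = float(np.mean([_eval_fold(s, ds1, f) for f, s in enumerate(states)]))
        out[name] = {"states": states, "f1": f1}
    return out


def evaluate_frozen(
    states: list[ClassifierState], seq: TimepointSequence, strategy_name: str = "control"
) -> StrategyRun:
    """Evaluate fixed per-fold states at every time point without retraining
    (the control for the slope analysis)."""
    run = StrategyRun(strategy_name)
    for tp, ds in seq.timepoints:
        for fold, state in enumerate(states):
            run.add(tp, fold, _eval_fold(state, ds, fold))
    return run


def compute_slope_difference(
    strategy_run: StrategyRun,
    control_run: StrategyRun,
    tp_start: str,
    tp_end: str,
) -> float:
    """(strategy F1 slope) - (control F1 slope) between two time points.

    Positive values mean the strategy declined more slowly than a model
    frozen at ``tp_start``.
    """
    s = strategy_run.mean_f1(tp_end) - strategy_run.mean_f1(tp_start)
    c = control_run.mean_f1(tp_end) - control_run.mean_f1(tp_start)
    return float(s - c)


@dataclass
class SlopeAnalysis:
    """Grid of slope differences over initial level x frequency x SNR."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["snr_db", "initial_level", "initial_f1", "frequency", "slope_difference"],
        )


def run_slope_analysis(
    seq: TimepointSequence,
    classifier_spec: str = "linear_baseline",
    frequencies=VALID_FREQUENCIES,
    threshold: float = 0.95,
    min_per_class: int = 200,
    seed: int = 0,
    epochs: int | None = None,
    base_states: list[ClassifierState] | None = None,
) -> SlopeAnalysis:
    """Frequency / initial-performance sweep on one encapsulation sequence.

    ``seq`` must contain at least the first three time points (start, +1,
    +2); the slope is measured between the second and third (the first drift
    step after the starting level was established).
    """
    if len(seq) < 3:
        raise ValueError("need at least three time points for the slope analysis")
    levels = build_initial_levels(
        TimepointSequence(seq.timepoints[:2], seq.scenario, seq.snr_db),
        classifier_spec, threshold, seed, epochs, base_states,
        min_per_class=min_per_class,
    )
    tp1, tp2 = seq.ids[1], seq.ids[2]
    sub = TimepointSequence(seq.timepoints[1:3], seq.scenario, seq.snr_db)
    analysis = SlopeAnalysis()
    for level_name, level in levels.items():
        control = evaluate_frozen(level["states"], sub)
        for m in frequencies:
            strat = run_frequency_experiment(
                sub, m, level["states"], threshold, min_per_class,
                seed + 10 * m, epochs,
            )
            try:
                diff = compute_slope_difference(strat, control, tp1, tp2)
            except ValueError:  # stopped before tp2: no retrained result to compare
                diff = float("nan")
            analysis.rows.append(
                {
                    "snr_db": seq.snr_db,
                    "initial_level": level_name,
                    "initial_f1": level["f1"],
                    "frequency": m,
                    "slope_difference": diff,
                }
            )
    return analysis
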