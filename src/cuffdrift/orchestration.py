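"""End-to-end study orchestration: configuration, seeding, dataset
synthesis, strategy sweeps, slope analysis, artifacts and reports.

Every stochastic stage derives its seed deterministically from one master
seed plus a stage name, so re-running a configuration reproduces identical
results and all strategies on one sequence consume identical datasets and
initializations.  Noise and fold seeds are shared across the time points of
a sequence (only the leadfield drifts), which makes signatures correspond
one-to-one across time points — the property the cross-time-point
interpolation of the frequency analysis relies on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import strategy_engine as se
from .cap_simulator import (
    CapBank,
    PathwaySpec,
    SourceTemplate,
    build_cap_bank,
    default_pathway,
    series_noise_sigma,
    PATHWAY_LABELS,
)
from .dataset_builder import (
    CLASS_LABELS,
    WINDOW_LEN,
    SignatureDataset,
    build_dataset,
)
from .volume_conductor import (
    ENCAPSULATION_LEVELS,
    CuffGeometry,
    TissueModel,
    apply_encapsulation,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "StudyInputs",
    "derive_seed",
    "build_study_inputs",
    "scenario_timepoints",
    "make_timepoint_dataset",
    "build_sequence",
    "run_full_study",
    "make_report",
    "ReportError",
]

ROTATION_ANGLES = tuple(range(0, 50, 5))  # 0..45 deg in 5 deg increments


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}/{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Complete study configuration (scaled-down desk profile by default).

    ``n_per_class`` is the number of signatures per pathway per time point
    (full-study scale 10,000; desk-scale 1000 -> 3000 CAPs per time point).
    """

    scenarios: tuple[str, ...] = ("encapsulation", "rotation")
    snr_grid: tuple[float, ...] = (-5.0, -10.0, -15.0)
    n_per_class: int = 1000
    n_folds: int = 5
    n_offsets: int = 20
    classifier_spec: str = "linear_baseline"
    epochs: int | None = None
    threshold: float = 0.95
    min_per_class: int = 200
    frequencies: tuple[int, ...] = (1, 2, 4, 8)
    slope_snr_grid: tuple[float, ...] = (-5.0, -10.0, -15.0)
    run_slopes: bool = True
    n_events_nominal: int = 10_000
    duration_s_nominal: float = 53.333
    master_seed: int = 0
    output_root: str = "results"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for k in ("scenarios", "snr_grid", "frequencies", "slope_snr_grid"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def __post_init__(self):
        for sc in self.scenarios:
            if sc not in ("encapsulation", "rotation"):
                raise ValueError(f"unknown scenario {sc!r}")


@dataclass
class StudyInputs:
    """Fixed study geometry: cuff, tissue, pathways and source template."""

    geometry: CuffGeometry
    tissue: TissueModel
    pathways: dict[str, PathwaySpec]
    template: SourceTemplate


def build_study_inputs(config: RunConfig) -> StudyInputs:
    geometry = CuffGeometry()
    tissue = TissueModel()
    pathways = {
        label: default_pathway(
            label, tissue, n_offsets=config.n_offsets,
            seed=derive_seed(config.master_seed, f"pathway/{label}"),
        )
        for label in PATHWAY_LABELS
    }
    return StudyInputs(geometry, tissue, pathways, SourceTemplate())


def scenario_timepoints(scenario: str) -> list[tuple[str, dict]]:
    """(timepoint_id, leadfield perturbation) pairs for one drift scenario."""
    if scenario == "encapsulation":
        return [(name, {"fill": fill, "rotation_deg": 0.0}) for name, fill in ENCAPSULATION_LEVELS.items()]
    if scenario == "rotation":
        return [(f"R{a}", {"fill": 0.0, "rotation_deg": float(a)}) for a in ROTATION_ANGLES]
    raise ValueError(f"unknown scenario {scenario!r}")


def _timepoint_banks(inputs: StudyInputs, fill: float, rotation_deg: float) -> dict[str, CapBank]:
    tissue = apply_encapsulation(inputs.tissue, fill)
    return {
        label: build_cap_bank(inputs.geometry, tissue, pw, inputs.template, rotation_deg)
        for label, pw in inputs.pathways.items()
    }


def make_timepoint_dataset(
    inputs: StudyInputs,
    snr_db: float,
    n_per_class: int,
    seed: int,
    fill: float = 0.0,
    rotation_deg: float = 0.0,
    timepoint_id: str = "Base",
    n_folds: int = 5,
    n_events_nominal: int = 10_000,
    duration_s_nominal: float = 53.333,
) -> SignatureDataset:
    """Synthesize one time point's labeled, normalized signature dataset.

    Per pathway, CAP clips cycle through the bank of lateral source offsets
    exactly as events do in the assembled series; the white-noise standard
    deviation is the one implied by that pathway's nominal full-length
    series at the requested SNR, so per-window noise is statistically
    identical to extracting windows from the noisy series.  The same
    ``seed`` reused at another time point yields one-to-one corresponding
    signatures (same event order, same noise draws, same folds).
    """
    banks = _timepoint_banks(inputs, fill, rotation_deg)
    mats, labels = [], []
    for ci, label in enumerate(CLASS_LABELS):
        bank = banks[label]
        sigma = series_noise_sigma(bank, snr_db, n_events_nominal, duration_s_nominal)
        rng = np.random.default_rng(derive_seed(seed, f"noise/{label}"))
        idx = np.arange(n_per_class) % bank.n_entries
        clean = bank.clips[idx]
        noisy = clean + rng.normal(0.0, sigma, clean.shape)
        mats.append(noisy.astype(np.float32))
        labels.append(np.full(n_per_class, ci))
    matrices = np.concatenate(mats, axis=0)
    labels = np.concatenate(labels)
    return build_dataset(
        matrices, labels, n_folds=n_folds, seed=derive_seed(seed, "folds") % (2**31),
        snr_db=snr_db, timepoint_id=timepoint_id,
    )


def build_sequence(
    config: RunConfig, inputs: StudyInputs, scenario: str, snr_db: float
) -> se.TimepointSequence:
    """All time points of one scenario at one SNR, with shared seeds."""
    seq_seed = derive_seed(config.master_seed, f"sequence/{scenario}/{snr_db}")
    tps = []
    for tp_id, pert in scenario_timepoints(scenario):
        tps.append(
            (
                tp_id,
                make_timepoint_dataset(
                    inputs, snr_db, config.n_per_class, seq_seed,
                    fill=pert["fill"], rotation_deg=pert["rotation_deg"],
                    timepoint_id=tp_id, n_folds=config.n_folds,
                    n_events_nominal=config.n_events_nominal,
                    duration_s_nominal=config.duration_s_nominal,
                ),
            )
        )
    return se.TimepointSequence(tps, scenario=scenario, snr_db=snr_db)


@dataclass
class RunManifest:
    """Record of one full study run: config hash, artifacts, wall times."""

    config_hash: str
    output_root: str
    artifacts: list[str] = field(default_factory=list)
    wall_times_s: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_full_study(config: RunConfig) -> RunManifest:
    """Simulate, build datasets, run all strategies (and optionally the
    slope analysis), and write tidy CSV results under the output root."""
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), output_root=str(root))
    inputs = build_study_inputs(config)
    strat_frames, count_frames = [], []
    t_start = time.perf_counter()
    for scenario in config.scenarios:
        for snr_db in config.snr_grid:
            t0 = time.perf_counter()
            seq = build_sequence(config, inputs, scenario, snr_db)
            seed = derive_seed(config.master_seed, f"train/{scenario}/{snr_db}")
            base_states = se.train_base_states(
                seq, config.classifier_spec, seed, epochs=config.epochs
            )
            runs = [
                se.run_baseline_calibration(seq, config.classifier_spec, seed, base_states, config.epochs),
                se.run_periodic_recalibration(seq, config.classifier_spec, seed, base_states, config.epochs),
                se.run_self_learning(
                    seq, config.classifier_spec, config.threshold, config.min_per_class,
                    seed, base_states, config.epochs,
                ),
            ]
            for run in runs:
                df = run.to_frame()
                df.insert(1, "scenario", scenario)
                df.insert(2, "snr_db", snr_db)
                strat_frames.append(df)
                cdf = run.counts_frame()
                if len(cdf):
                    cdf.insert(1, "scenario", scenario)
                    cdf.insert(2, "snr_db", snr_db)
                    count_frames.append(cdf)
            manifest.wall_times_s[f"{scenario}/{snr_db}"] = round(time.perf_counter() - t0, 2)
    strategies_csv = root / "strategies.csv"
    pd.concat(strat_frames, ignore_index=True).to_csv(strategies_csv, index=False)
    manifest.artifacts.append(str(strategies_csv))
    if count_frames:
        counts_csv = root / "self_label_counts.csv"
        pd.concat(count_frames, ignore_index=True).to_csv(counts_csv, index=False)
        manifest.artifacts.append(str(counts_csv))

    if config.run_slopes and "encapsulation" in config.scenarios:
        slope_frames = []
        for snr_db in config.slope_snr_grid:
            t0 = time.perf_counter()
            seq = build_sequence(config, inputs, "encapsulation", snr_db)
            seed = derive_seed(config.master_seed, f"slopes/{snr_db}")
            analysis = se.run_slope_analysis(
                seq, config.classifier_spec, config.frequencies,
                config.threshold, config.min_per_class, seed, config.epochs,
            )
            slope_frames.append(analysis.to_frame())
            manifest.wall_times_s[f"slopes/{snr_db}"] = round(time.perf_counter() - t0, 2)
        slopes_csv = root / "slopes.csv"
        pd.concat(slope_frames, ignore_index=True).to_csv(slopes_csv, index=False)
        manifest.artifacts.append(str(slopes_csv))

    manifest.wall_times_s["total"] = round(time.perf_counter() - t_start, 2)
    config.to_yaml(root / "config.yaml")
    manifest.artifacts.append(str(root / "config.yaml"))
    manifest.save(root / "manifest.json")
    return manifest


class ReportError(RuntimeError):
    """Raised when a manifest holds nothing to report."""


def make_report(manifest: RunManifest) -> list[str]:
    """Render F1-trajectory panels and slope-difference tables from a run.

    Returns the list of files written.  An empty manifest raises
    ``ReportError`` so callers can exit distinctly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    root = Path(manifest.output_root)
    strategies_csv = root / "strategies.csv"
    if not manifest.artifacts or not strategies_csv.exists():
        raise ReportError("manifest lists no strategy results")
    written = []
    df = pd.read_csv(strategies_csv)
    for (scenario, snr_db), grp in df.groupby(["scenario", "snr_db"]):
        fig, ax = plt.subplots(figsize=(6, 4))
        tp_order = list(dict.fromkeys(grp["timepoint"]))
        for strategy, sgrp in grp.groupby("strategy"):
            agg = sgrp.groupby("timepoint")["f1"].agg(["mean", "std"]).reindex(tp_order)
            ax.errorbar(agg.index, agg["mean"], yerr=agg["std"], marker="o", capsize=3, label=strategy)
        ax.set_xlabel("time point")
        ax.set_ylabel("macro F1")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{scenario}, SNR {snr_db:g} dB")
        ax.legend(fontsize=8)
        fig.tight_layout()
        out = root / f"f1_{scenario}_snr{snr_db:g}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(str(out))
    slopes_csv = root / "slopes.csv"
    if slopes_csv.exists():
        sdf = pd.read_csv(slopes_csv)
        pivot = sdf.pivot_table(
            index=["snr_db", "initial_level"], columns="frequency", values="slope_difference"
        )
        out = root / "slope_differences.csv"
        pivot.to_csv(out)
        written.append(str(out))
    return written
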