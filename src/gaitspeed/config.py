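"""Experiment configuration and the end-to-end orchestration entry point."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import inventory
from .evaluation import evaluate_all_combinations, results_table, walk_table, window_sweep
from .features import DEFAULT_ENTROPY_BINS, build_feature_table, feature_columns
from .importance import build_ledger, run_importance
from .model import MAX_TERMS_DEFAULT
from .preprocess import FilterParams, WindowSpec, load_cohort
from .synthetic import generate_cohort

log = logging.getLogger("gaitspeed")


@dataclass
class ExperimentConfig:
    """Resolved parameters of one experiment run; YAML round-trippable."""

    seed: int = 42
    n_subjects: int = 20
    duration_s: float = 360.0
    data_dir: str | None = None  # load recordings instead of simulating
    window_length_s: float = 5.0
    window_hop_s: float = 1.0
    filter_lp_cutoff_hz: float = 10.0
    filter_bp_band_hz: tuple[float, float] = (0.1, 10.0)
    filter_order: int = 4
    entropy_bins: int = DEFAULT_ENTROPY_BINS
    combinations: list[str] = field(
        default_factory=lambda: list(inventory.COMBINATIONS))
    max_terms: int = MAX_TERMS_DEFAULT
    both_shoes: bool = True
    target_mode: str = "mean"
    r2_method: str = "pearson"
    importance_alpha: float = 0.001
    importance_combo_rule: str = "strict"
    sweep_lengths: list[float] | None = None  # e.g. [2.5, 5, 10, 20]
    out_dir: str = "gaitspeed_run"

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_length_s, self.window_hop_s)

    def filter_params(self) -> FilterParams:
        return FilterParams(self.filter_lp_cutoff_hz,
                            tuple(self.filter_bp_band_hz), self.filter_order)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["filter_bp_band_hz"] = list(d["filter_bp_band_hz"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "filter_bp_band_hz" in d:
            d["filter_bp_band_hz"] = tuple(d["filter_bp_band_hz"])
        return cls(**d)


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the full workflow and write all artifacts to the output dir.

    Stages: simulate (or load) -> filter/window/featurise -> per-combination
    leave-one-subject-out evaluation -> optional window-size sweep ->
    feature-importance funnel.  The resolved configuration and a JSON
    summary of headline metrics are written next to the outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    try:
        if config.data_dir is not None:
            trials = load_cohort(config.data_dir)
            log.info("loaded %d trials from %s", len(trials), config.data_dir)
        else:
            trials = generate_cohort(config.n_subjects, config.seed, config.duration_s)
            log.info("simulated %d trials (%d subjects, seed %d)",
                     len(trials), config.n_subjects, config.seed)

        table = build_feature_table(
            trials, spec=config.window_spec(), params=config.filter_params(),
            bins=config.entropy_bins, target_mode=config.target_mode)
        n_feats = len(feature_columns(table))
        log.info("feature table: %d windows x %d features", len(table), n_feats)
        table.to_csv(out / "features.csv", index=False)

        results = evaluate_all_combinations(
            table, config.combinations, max_terms=config.max_terms,
            both_shoes=config.both_shoes, r2_method=config.r2_method)
        for name, res in results.items():
            log.info("combination %-12s pooled RMSE %.3f m/s  R2 %.3f",
                     name, res.report.rmse, res.report.r2)
        results_table(results).to_csv(out / "gs_agreement.csv", index=False)
        walk_table(results).to_csv(out / "walk_error.csv", index=False)

        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for name, res in results.items():
            for fold in res.folds:
                fold.model.save(
                    models_dir / f"{name.replace('+', '_')}_{fold.subject_id}.json",
                    stats=fold.stats)

        ledger = build_ledger(results)
        ledger.to_csv(out / "selection_ledger.csv", index=False)
        imp = run_importance(ledger, alpha=config.importance_alpha,
                             combo_rule=config.importance_combo_rule)
        imp.summary.to_csv(out / "importance.csv", index=False)
        log.info("importance funnel: %d -> %d -> %d features",
                 len(imp.stage1), len(imp.stage2_union), len(imp.stage3_union))

        sweep_df = None
        if config.sweep_lengths:
            sweep_df = window_sweep(
                trials, tuple(config.sweep_lengths), config.combinations,
                hop_s=config.window_hop_s, params=config.filter_params(),
                max_terms=config.max_terms, both_shoes=config.both_shoes)
            sweep_df.to_csv(out / "window_sweep.csv", index=False)

        summary = {
            "n_trials": len(trials),
            "n_windows": int(len(table)),
            "n_features": n_feats,
            "combinations": {
                name: {
                    "rmse_pooled": res.report.rmse,
                    "rmse_mean": res.rmse_mean,
                    "rmse_sd": res.rmse_sd,
                    "bias": res.report.bias,
                    "loa_low": res.report.loa_low,
                    "loa_high": res.report.loa_high,
                    "r2": res.report.r2,
                    "abs_eps_r_mean": res.abs_eps_r_mean,
                    "abs_eps_r_sd": res.abs_eps_r_sd,
                }
                for name, res in results.items()
            },
            "importance": {
                "stage1": sorted(imp.stage1),
                "stage2": {k: sorted(v) for k, v in imp.stage2.items()},
                "stage3": {k: sorted(v) for k, v in imp.stage3.items()},
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    except Exception:
        (out / "FAILED").write_text("run did not complete; partial outputs retained\n")
        raise
    return out
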