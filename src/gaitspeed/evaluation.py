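"""Leave-one-subject-out evaluation, agreement statistics and walk distance.

For every device combination, each subject in turn is held out: feature
normalization and stepwise selection are re-run on the remaining subjects
and the resulting model predicts the held-out subject's windows.  Reported
quantities follow the conventions of agreement analysis:

* RMSE of windowed speed, pooled over all held-out pairs and also
  mean +- SD across subjects (folds);
* Bland-Altman bias and limits of agreement on differences
  (estimate - reference), limits at bias +- 1.96 * sample SD;
* R^2 as the squared Pearson correlation of reference and estimate
  (the correlation-plot reading; 1 - SSE/SST is available as an option);
* six-minute walking distance per trial, ``mean(yhat) * 360 s``, with its
  signed relative percentage error ``(true - est) / true * 100``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inventory
from .features import build_feature_table, feature_columns
from .model import (
    MAX_TERMS_DEFAULT,
    NormalizationStats,
    SpeedModel,
    fit_speed_model,
    predict,
)
from .preprocess import FilterParams, WindowSpec
from .synthetic import TrialRecording

SIX_MINUTES_S = 360.0


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error, m/s."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between reference and estimate")
    if y.size < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def bland_altman(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """(bias, lower, upper) limits of agreement of estimate - reference.

    Limits are bias +- 1.96 * sample SD (denominator n - 1) of the
    differences.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need >= 2 equal-length pairs")
    diff = yhat - y
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def r_squared(y: np.ndarray, yhat: np.ndarray, method: str = "pearson") -> float:
    """Coefficient of determination.

    ``pearson`` (default): squared Pearson correlation between reference and
    estimate, as read off a correlation plot.  ``residual``: 1 - SSE/SST.
    Undefined (NaN) when the reference has zero variance.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ValueError("need >= 3 equal-length pairs")
    if np.var(y) == 0:
        return float("nan")
    if method == "pearson":
        if np.var(yhat) == 0:
            return float("nan")
        r = np.corrcoef(y, yhat)[0, 1]
        return float(r * r)
    if method == "residual":
        sse = float(np.sum((y - yhat) ** 2))
        sst = float(np.sum((y - np.mean(y)) ** 2))
        return 1.0 - sse / sst
    raise ValueError(f"unknown R^2 method {method!r}")


def six_mwd(yhat: np.ndarray) -> float:
    """Estimated six-minute walking distance: mean windowed speed x 360 s."""
    yhat = np.asarray(yhat, dtype=float)
    if yhat.size < 1:
        raise ValueError("need at least one window")
    return float(np.mean(yhat) * SIX_MINUTES_S)


def relative_error(true_dist: float, est_dist: float) -> float:
    """Signed relative percentage error (true - estimate) / true * 100."""
    if true_dist <= 0:
        raise ValueError("true distance must be positive")
    return (true_dist - est_dist) / true_dist * 100.0


@dataclass
class AgreementReport:
    """Pooled agreement between reference and estimated speeds."""

    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    r2: float
    n_pairs: int


def agreement_report(y: np.ndarray, yhat: np.ndarray,
                     r2_method: str = "pearson") -> AgreementReport:
    bias, lo, hi = bland_altman(y, yhat)
    return AgreementReport(
        rmse=rmse(y, yhat), bias=bias, loa_low=lo, loa_high=hi,
        r2=r_squared(y, yhat, r2_method), n_pairs=int(np.size(y)),
    )


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Held-out predictions and the model fitted on the remaining subjects."""

    subject_id: str
    frame: pd.DataFrame  # columns: trial_id, y, yhat
    model: SpeedModel
    stats: NormalizationStats


@dataclass
class LosoResult:
    """All folds of one combination plus pooled and per-fold summaries."""

    combination: str
    folds: list[FoldResult]
    report: AgreementReport
    fold_rmse: dict[str, float]
    walks: pd.DataFrame  # trial_id, true_6mwd, est_6mwd, eps_r
    walk_report: AgreementReport | None = None

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(list(self.fold_rmse.values())))

    @property
    def rmse_sd(self) -> float:
        return float(np.std(list(self.fold_rmse.values()), ddof=1))

    @property
    def abs_eps_r_mean(self) -> float:
        return float(np.mean(np.abs(self.walks["eps_r"])))

    @property
    def abs_eps_r_sd(self) -> float:
        return float(np.std(np.abs(self.walks["eps_r"]), ddof=1))


def loso_evaluate(
    features: pd.DataFrame,
    combination: str,
    max_terms: int = MAX_TERMS_DEFAULT,
    both_shoes: bool = True,
    r2_method: str = "pearson",
) -> LosoResult:
    """Leave-one-subject-out evaluation of one device combination.

    Feature normalization and stepwise selection run inside each fold on
    training subjects only.  The pooled agreement report aggregates the
    held-out pairs of all subjects; per-fold RMSEs are retained for
    mean +- SD summaries.
    """
    pool_all = inventory.pool_feature_names(combination, both_shoes=both_shoes)
    pool = [c for c in pool_all if c in features.columns]
    if not pool:
        raise ValueError(f"no features of combination {combination!r} in table")
    subjects = list(pd.unique(features["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")

    folds: list[FoldResult] = []
    for subject in subjects:
        mask = features["subject_id"] == subject
        test = features[mask]
        train = features[~mask]
        if len(test) == 0:
            warnings.warn(f"subject {subject} has no windows; excluded")
            continue
        stats, model = fit_speed_model(
            train, pool, combination=combination,
            max_terms=max_terms, fold_id=str(subject))
        yhat = predict(model, stats, test)
        frame = pd.DataFrame({
            "trial_id": test["trial_id"].to_numpy(),
            "y": test["y"].to_numpy(dtype=float),
            "yhat": yhat,
        })
        folds.append(FoldResult(subject_id=str(subject), frame=frame,
                                model=model, stats=stats))

    pooled = pd.concat([f.frame for f in folds], ignore_index=True)
    report = agreement_report(pooled["y"], pooled["yhat"], r2_method)
    fold_rmse = {f.subject_id: rmse(f.frame["y"], f.frame["yhat"]) for f in folds}

    rows = []
    for trial_id, grp in pooled.groupby("trial_id", sort=True):
        true_d = six_mwd(grp["y"].to_numpy())
        est_d = six_mwd(grp["yhat"].to_numpy())
        rows.append({
            "trial_id": trial_id, "true_6mwd": true_d, "est_6mwd": est_d,
            "eps_r": relative_error(true_d, est_d),
        })
    walks = pd.DataFrame(rows)
    walk_report = None
    if len(walks) >= 3:
        walk_report = agreement_report(
            walks["true_6mwd"].to_numpy(), walks["est_6mwd"].to_numpy(), r2_method)
    return LosoResult(combination=combination, folds=folds, report=report,
                      fold_rmse=fold_rmse, walks=walks, walk_report=walk_report)


def evaluate_all_combinations(
    features: pd.DataFrame,
    combinations: list[str] | None = None,
    max_terms: int = MAX_TERMS_DEFAULT,
    both_shoes: bool = True,
    r2_method: str = "pearson",
) -> dict[str, LosoResult]:
    """LOSO evaluation of every requested combination (default: all 7)."""
    if combinations is None:
        combinations = list(inventory.COMBINATIONS)
    return {
        name: loso_evaluate(features, name, max_terms=max_terms,
                            both_shoes=both_shoes, r2_method=r2_method)
        for name in combinations
    }


def results_table(results: dict[str, LosoResult]) -> pd.DataFrame:
    """Speed-agreement summary, one row per combination."""
    rows = []
    for name, res in results.items():
        rows.append({
            "combination": name,
            "rmse_mean": res.rmse_mean,
            "rmse_sd": res.rmse_sd,
            "rmse_pooled": res.report.rmse,
            "loa_low": res.report.loa_low,
            "loa_high": res.report.loa_high,
            "bias": res.report.bias,
            "r2": res.report.r2,
            "n_pairs": res.report.n_pairs,
        })
    return pd.DataFrame(rows)


def walk_table(results: dict[str, LosoResult]) -> pd.DataFrame:
    """Walk-distance summary (|eps_r| mean +- SD and agreement), per combination."""
    rows = []
    for name, res in results.items():
        row = {
            "combination": name,
            "abs_eps_r_mean": res.abs_eps_r_mean,
            "abs_eps_r_sd": res.abs_eps_r_sd,
            "eps_r_mean_signed": float(np.mean(res.walks["eps_r"])),
            "n_trials": len(res.walks),
        }
        if res.walk_report is not None:
            row.update({
                "loa_low": res.walk_report.loa_low,
                "loa_high": res.walk_report.loa_high,
                "bias": res.walk_report.bias,
                "r2": res.walk_report.r2,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def agreement_plots(result: LosoResult, out_dir: str | Path) -> list[Path]:
    """Write correlation and Bland-Altman scatter plots for one combination.

    Optional convenience; requires matplotlib.  Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pooled = pd.concat([f.frame for f in result.folds], ignore_index=True)
    y, yhat = pooled["y"].to_numpy(), pooled["yhat"].to_numpy()
    tag = result.combination.replace("+", "_")
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y, yhat, s=3, alpha=0.3)
    lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("reference speed [m/s]")
    ax.set_ylabel("estimated speed [m/s]")
    ax.set_title(f"{result.combination}: R$^2$ = {result.report.r2:.2f}")
    paths.append(out_dir / f"correlation_{tag}.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    mean_ = (y + yhat) / 2
    ax.scatter(mean_, yhat - y, s=3, alpha=0.3)
    for val, style in ((result.report.bias, "-"),
                       (result.report.loa_low, "--"),
                       (result.report.loa_high, "--")):
        ax.axhline(val, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of reference and estimate [m/s]")
    ax.set_ylabel("estimate - reference [m/s]")
    ax.set_title(f"{result.combination}: bias = {result.report.bias:.3f} m/s")
    paths.append(out_dir / f"bland_altman_{tag}.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return paths


def window_sweep(
    trials: list[TrialRecording],
    lengths: tuple[float, ...] = (2.5, 5.0, 10.0, 20.0),
    combinations: list[str] | None = None,
    hop_s: float = 1.0,
    params: FilterParams = FilterParams(),
    max_terms: int = MAX_TERMS_DEFAULT,
    both_shoes: bool = True,
) -> pd.DataFrame:
    """Re-run the full pipeline per (window length, combination).

    Returns a grid with one row per cell carrying the speed RMSE
    (mean +- SD across folds) and the walk-distance |eps_r| summary.
    """
    if combinations is None:
        combinations = list(inventory.COMBINATIONS)
    rows = []
    for length in lengths:
        spec = WindowSpec(length_s=length, hop_s=hop_s)
        table = build_feature_table(trials, spec=spec, params=params)
        results = evaluate_all_combinations(
            table, combinations, max_terms=max_terms, both_shoes=both_shoes)
        for name, res in results.items():
            rows.append({
                "window_s": length,
                "combination": name,
                "rmse_mean": res.rmse_mean,
                "rmse_sd": res.rmse_sd,
                "rmse_pooled": res.report.rmse,
                "abs_eps_r_mean": res.abs_eps_r_mean,
                "abs_eps_r_sd": res.abs_eps_r_sd,
            })
    return pd.DataFrame(rows)
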