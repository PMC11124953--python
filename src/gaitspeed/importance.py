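"""Three-stage most-important-feature selection over cross-validated models.

Because features are z-normalized, regression coefficients are directly
comparable, and a feature's importance can be judged from how consistently
the stepwise procedure selects it with a significant coefficient:

1. *Significance screen* — keep features selected in at least one fitted
   model with a coefficient p-value < 0.001 (uncorrected, by design).
2. *Fold drop-out* — within each device combination, keep features selected
   in at least half of the cross-validation folds (threshold ceil(n/2),
   re-derived from the actual fold count, never hard-coded).
3. *Combination drop-out* — each device takes part in 4 of the 7
   combinations; keep, per device, the features appearing in strictly more
   than half of those combinations (>= 3 of 4 under the default strict
   reading; a relaxed >= half option is provided).

Surviving features are summarised with the mean +- SD (population
denominator, so a single occurrence reports SD = 0) of their coefficient
and t-statistic over the occurrences that passed the screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inventory
from .evaluation import LosoResult

P_THRESHOLD = 0.001

LEDGER_COLUMNS = ("combination", "fold", "feature", "beta", "se", "tstat", "pvalue")


def build_ledger(results: dict[str, LosoResult]) -> pd.DataFrame:
    """Flatten per-(combination, fold) selections into a ledger table."""
    rows = []
    for name, res in results.items():
        for fold in res.folds:
            m = fold.model
            for i, feat in enumerate(m.features):
                rows.append({
                    "combination": name,
                    "fold": fold.subject_id,
                    "feature": feat,
                    "beta": float(m.coefs[i]),
                    "se": float(m.se[i]),
                    "tstat": float(m.tstats[i]),
                    "pvalue": float(m.pvalues[i]),
                })
    return pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))


def stage_significant(ledger: pd.DataFrame, alpha: float = P_THRESHOLD) -> set[str]:
    """Features selected with p < alpha in at least one fitted model."""
    hit = ledger[ledger["pvalue"] < alpha]
    return set(hit["feature"])


def fold_threshold(n_folds: int) -> int:
    """Keep threshold of the fold drop-out stage: at least half the folds."""
    return math.ceil(n_folds / 2)


def stage_fold_dropout(ledger: pd.DataFrame, survivors: set[str]) -> dict[str, set[str]]:
    """Per combination, survivors selected in >= ceil(n_folds / 2) folds."""
    out: dict[str, set[str]] = {}
    for comb, grp in ledger.groupby("combination", sort=True):
        n_folds = grp["fold"].nunique()
        thresh = fold_threshold(n_folds)
        counts = (
            grp[grp["feature"].isin(survivors)]
            .groupby("feature")["fold"].nunique()
        )
        out[comb] = set(counts[counts >= thresh].index)
    return out


def stage_combination_dropout(
    per_combination: dict[str, set[str]],
    rule: str = "strict",
) -> dict[str, set[str]]:
    """Per device, features present in more than half of its combinations.

    ``strict`` (default) keeps a feature appearing in strictly more than
    half of the device's combinations (3 of 4 in the full design);
    ``half`` relaxes the cut to at least half (2 of 4).
    """
    out: dict[str, set[str]] = {}
    for device, combos in inventory.DEVICE_COMBINATIONS.items():
        present = [c for c in combos if c in per_combination]
        if not present:
            out[device] = set()
            continue
        counts: dict[str, int] = {}
        for comb in present:
            for feat in per_combination[comb]:
                if inventory.device_of_feature(feat) == device:
                    counts[feat] = counts.get(feat, 0) + 1
        half = len(present) / 2
        if rule == "strict":
            out[device] = {f for f, c in counts.items() if c > half}
        elif rule == "half":
            out[device] = {f for f, c in counts.items() if c >= half}
        else:
            raise ValueError(f"unknown combination drop-out rule {rule!r}")
    return out


@dataclass
class ImportanceReport:
    """Funnel membership per stage and summary stats of the survivors."""

    stage1: set[str]
    stage2: dict[str, set[str]]
    stage3: dict[str, set[str]]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def stage2_union(self) -> set[str]:
        return set().union(*self.stage2.values()) if self.stage2 else set()

    @property
    def stage3_union(self) -> set[str]:
        return set().union(*self.stage3.values()) if self.stage3 else set()


def summarize(
    final: dict[str, set[str]],
    ledger: pd.DataFrame,
    per_combination: dict[str, set[str]],
    alpha: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Mean +- SD of beta and t-stat over the occurrences that passed.

    Occurrences counted are ledger rows where the feature met the
    significance screen, inside combinations where it survived the fold
    drop-out.  SD uses the population denominator (single occurrence -> 0).
    """
    rows = []
    for device, feats in final.items():
        for feat in sorted(feats):
            combos = [c for c, s in per_combination.items() if feat in s]
            occ = ledger[
                (ledger["feature"] == feat)
                & (ledger["pvalue"] < alpha)
                & (ledger["combination"].isin(combos))
            ]
            rows.append({
                "device": device,
                "feature": feat,
                "n_occurrences": len(occ),
                "beta_mean": float(np.mean(occ["beta"])) if len(occ) else float("nan"),
                "beta_sd": float(np.std(occ["beta"])) if len(occ) else float("nan"),
                "tstat_mean": float(np.mean(occ["tstat"])) if len(occ) else float("nan"),
                "tstat_sd": float(np.std(occ["tstat"])) if len(occ) else float("nan"),
            })
    return pd.DataFrame(
        rows, columns=["device", "feature", "n_occurrences",
                       "beta_mean", "beta_sd", "tstat_mean", "tstat_sd"])


def run_importance(
    ledger: pd.DataFrame,
    alpha: float = P_THRESHOLD,
    combo_rule: str = "strict",
) -> ImportanceReport:
    """Run the full three-stage funnel over a selection ledger."""
    s1 = stage_significant(ledger, alpha)
    s2 = stage_fold_dropout(ledger, s1)
    s3 = stage_combination_dropout(s2, rule=combo_rule)
    if not any(s3.values()):
        warnings.warn("no feature survived the combination drop-out stage")
    summary = summarize(s3, ledger, s2, alpha)
    return ImportanceReport(stage1=s1, stage2=s2, stage3=s3, summary=summary)
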