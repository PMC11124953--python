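"""Combination-specific gait-speed estimator.

The estimator is a multiple linear regression

    yhat = b0 + b1*f1 + ... + b10*f10

over z-normalized features.  Regressors are chosen by greedy forward
stepwise selection under the Gaussian-likelihood BIC

    BIC = n * ln(RSS / n) + k * ln(n)

(constant terms omitted; k counts the intercept plus regressors), starting
from the intercept-only model and always continuing to the 10-term cap —
the selection never stops early, even if a step worsens the BIC.  Candidate
ties are broken deterministically by feature-name order.  The final model
is refit by OLS to obtain coefficient standard errors, t-statistics and
p-values, which downstream interpretability relies on.

Normalization statistics are estimated on training rows only and applied
unchanged to held-out rows, so cross-validated evaluation is leakage-free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

MAX_TERMS_DEFAULT = 10
_ZERO_VAR_TOL = 1e-12


@dataclass
class NormalizationStats:
    """Per-feature training mean and (population) standard deviation."""

    means: "pd.Series[float]"
    stds: "pd.Series[float]"
    kept: list[str]
    dropped: list[str] = field(default_factory=list)


def znorm_fit(train: pd.DataFrame, columns: list[str] | None = None) -> NormalizationStats:
    """Estimate normalization statistics on training rows.

    Zero-variance columns are flagged and excluded from the candidate pool
    (they carry no information and make the z-score undefined).
    """
    if columns is None:
        columns = list(train.columns)
    if len(train) == 0:
        raise ValueError("empty training table")
    X = train[columns]
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=0)
    kept = [c for c in columns if stds[c] > _ZERO_VAR_TOL]
    dropped = [c for c in columns if c not in kept]
    return NormalizationStats(means=means[kept], stds=stds[kept],
                              kept=kept, dropped=dropped)


def znorm_apply(stats: NormalizationStats, table: pd.DataFrame) -> pd.DataFrame:
    """Apply training normalization to a table (kept columns only)."""
    return (table[stats.kept] - stats.means) / stats.stds


def bic_score(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood BIC up to an additive constant.

    ``k`` counts the intercept plus regressors.  A perfect fit (rss == 0)
    returns -inf with a warning.
    """
    if not n > k >= 1:
        raise ValueError("require n > k >= 1")
    if rss < 0:
        raise ValueError("negative residual sum of squares")
    if rss == 0:
        warnings.warn("perfect fit: BIC is -inf")
        return float("-inf")
    return n * np.log(rss / n) + k * np.log(n)


@dataclass
class SpeedModel:
    """Fitted gait-speed regression for one device combination / fold."""

    combination: str
    features: list[str]          # selection order
    intercept: float
    coefs: np.ndarray
    se: np.ndarray
    tstats: np.ndarray
    pvalues: np.ndarray
    intercept_se: float
    n_train: int
    fold_id: str | None = None
    bic_path: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "combination": self.combination,
            "fold_id": self.fold_id,
            "n_train": self.n_train,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "features": list(self.features),
            "coefs": [float(v) for v in self.coefs],
            "se": [float(v) for v in self.se],
            "tstats": [float(v) for v in self.tstats],
            "pvalues": [float(v) for v in self.pvalues],
            "bic_path": [float(v) for v in self.bic_path],
        }

    def save(self, path: str | Path, stats: NormalizationStats | None = None) -> None:
        payload = self.to_dict()
        if stats is not None:
            payload["normalization"] = {
                "means": {k: float(v) for k, v in stats.means.items()},
                "stds": {k: float(v) for k, v in stats.stds.items()},
            }
        Path(path).write_text(json.dumps(payload, indent=1))


def forward_stepwise(
    table: pd.DataFrame,
    pool: list[str],
    max_terms: int = MAX_TERMS_DEFAULT,
    combination: str = "custom",
    fold_id: str | None = None,
    y_column: str = "y",
) -> SpeedModel:
    """Greedy forward selection under BIC, forced to the term cap.

    ``table`` must hold z-normalized feature columns plus the target column.
    At every step the candidate minimizing the BIC of the augmented OLS fit
    is added; selection continues to exactly ``min(max_terms, |pool|)``
    regressors even when the BIC worsens.  Candidates whose addition makes
    the normal equations singular (collinearity) are skipped.
    """
    pool = sorted(pool)
    if not pool:
        raise ValueError("empty candidate pool")
    y = table[y_column].to_numpy(dtype=float)
    n = len(y)
    if n < 10 * min(max_terms, len(pool)):
        warnings.warn(
            f"only {n} rows for up to {min(max_terms, len(pool))} regressors")
    X = table[pool].to_numpy(dtype=float)
    A = np.column_stack([np.ones(n), X])  # col 0 = intercept, col j+1 = pool[j]
    G = A.T @ A
    g = A.T @ y
    yy = float(y @ y)

    selected: list[int] = []       # indices into ``pool``
    remaining = list(range(len(pool)))
    bic_path: list[float] = []
    target = min(max_terms, len(pool))
    while len(selected) < target:
        best_bic = np.inf
        best_j = None
        base = [0] + [j + 1 for j in selected]
        for j in remaining:
            idx = base + [j + 1]
            Gs = G[np.ix_(idx, idx)]
            gs = g[idx]
            try:
                c = linalg.cho_factor(Gs, check_finite=False)
            except linalg.LinAlgError:
                continue
            # near-zero Cholesky pivot = candidate (numerically) collinear
            # with the already-selected columns
            if np.min(np.diag(c[0])) <= 1e-6 * np.sqrt(np.max(np.diag(Gs))):
                continue
            beta = linalg.cho_solve(c, gs, check_finite=False)
            rss = yy - float(gs @ beta)
            if rss <= 0:
                bic = float("-inf")
            else:
                bic = n * np.log(rss / n) + len(idx) * np.log(n)
            if bic < best_bic:
                best_bic = bic
                best_j = j
        if best_j is None:
            warnings.warn("no non-singular candidate left; stopping early")
            break
        selected.append(best_j)
        remaining.remove(best_j)
        bic_path.append(float(best_bic))

    chosen = [pool[j] for j in selected]
    Xs = sm.add_constant(table[chosen].to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(y, Xs).fit()
    return SpeedModel(
        combination=combination,
        features=chosen,
        intercept=float(fit.params[0]),
        coefs=np.asarray(fit.params[1:], dtype=float),
        se=np.asarray(fit.bse[1:], dtype=float),
        tstats=np.asarray(fit.tvalues[1:], dtype=float),
        pvalues=np.asarray(fit.pvalues[1:], dtype=float),
        intercept_se=float(fit.bse[0]),
        n_train=n,
        fold_id=fold_id,
        bic_path=bic_path,
    )


def predict(model: SpeedModel, stats: NormalizationStats, table: pd.DataFrame) -> np.ndarray:
    """Estimated gait speed per window; no clipping (negatives reported)."""
    missing = [f for f in model.features if f not in table.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    Z = (table[model.features] - stats.means[model.features]) / stats.stds[model.features]
    return model.intercept + Z.to_numpy(dtype=float) @ model.coefs


def fit_speed_model(
    train: pd.DataFrame,
    pool: list[str],
    combination: str = "custom",
    max_terms: int = MAX_TERMS_DEFAULT,
    fold_id: str | None = None,
) -> tuple[NormalizationStats, SpeedModel]:
    """Convenience: z-normalize a training table and run the stepwise fit."""
    stats = znorm_fit(train, [c for c in pool if c in train.columns])
    z = znorm_apply(stats, train)
    z["y"] = train["y"].to_numpy(dtype=float)
    model = forward_stepwise(z, stats.kept, max_terms=max_terms,
                             combination=combination, fold_id=fold_id)
    return stats, model
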