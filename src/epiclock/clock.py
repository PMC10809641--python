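"""Ridge-regression clocks for the three aging outcomes.

Conventions
-----------
Features are standardized to mean 0, population SD 1 before fitting. The
intercept is unpenalized (it equals the outcome mean on standardized
features). Coefficients solve the penalized normal equations

    (X'X + lambda * n * I) beta = X' (y - ybar)

on the standardized design; the factor ``n`` ties the printed lambda scale
to the per-sample loss. Lambda selection is by minimum mean CV MAE (ties go
to the larger, i.e. more regularized, lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ModelError
from .preprocess import BetaMatrix

OUTCOME_KINDS = ("wrinkle_grade", "visual_age", "progression")


@dataclass
class ClockModel:
    outcome_kind: str
    feature_level: str
    feature_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    alpha: float = 0.0
    lam: float = 0.0
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome_kind not in OUTCOME_KINDS:
            raise ConfigurationError(f"unknown outcome kind: {self.outcome_kind}")
        if self.alpha != 0.0:
            raise ConfigurationError("only ridge (alpha = 0) is supported")
        if len(self.coefficients) != len(self.feature_ids):
            raise ModelError("coefficient / feature_id length mismatch")
        if np.any(np.asarray(self.feature_sds) <= 0):
            raise ModelError("retained features must have positive SD")

    def to_dict(self) -> dict:
        return {
            "outcome_kind": self.outcome_kind,
            "feature_level": self.feature_level,
            "feature_ids": list(self.feature_ids),
            "intercept": float(self.intercept),
            "coefficients": np.asarray(self.coefficients).tolist(),
            "feature_means": np.asarray(self.feature_means).tolist(),
            "feature_sds": np.asarray(self.feature_sds).tolist(),
            "alpha": float(self.alpha),
            "lambda": float(self.lam),
            "dropped_features": list(self.dropped_features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(
            outcome_kind=d["outcome_kind"],
            feature_level=d["feature_level"],
            feature_ids=list(d["feature_ids"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            alpha=float(d.get("alpha", 0.0)),
            lam=float(d["lambda"]),
            dropped_features=list(d.get("dropped_features", [])),
        )


@dataclass
class CVResult:
    lambda_grid: np.ndarray
    fold_mae: np.ndarray  # n_lambda x k
    mean_mae: np.ndarray
    sd_mae: np.ndarray
    selected_lambda: float
    fold_assignments: pd.Series  # sample id -> fold

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.fold_mae,
            columns=[f"fold{j}" for j in range(self.fold_mae.shape[1])],
        )
        df.insert(0, "lambda", self.lambda_grid)
        df["mean_mae"] = self.mean_mae
        df["sd_mae"] = self.sd_mae
        return df


@dataclass
class Partition:
    train_ids: list
    test_ids: list
    p: float
    n_bins: int
    seed: int


def stratified_partition(
    outcome: pd.Series | np.ndarray,
    p: float = 0.8,
    n_bins: int = 10,
    seed: int = 0,
) -> Partition:
    """Outcome-stratified train/test split with |train| = floor(p * n) exactly.

    Samples are binned into ``n_bins`` quantile (rank-based) groups; each bin
    contributes floor(p * bin size) training samples, and the remaining slots
    (to reach floor(p * n) in total) are assigned by a seed-determined draw
    over bins with a fractional remainder, so no bin deviates from fraction
    ``p`` by more than one sample.
    """
    if not 0 < p < 1:
        raise ConfigurationError("train fraction p must be in (0, 1)")
    if isinstance(outcome, pd.Series):
        ids = outcome.index.to_numpy()
        values = outcome.to_numpy(dtype=float)
    else:
        values = np.asarray(outcome, dtype=float)
        ids = np.arange(values.size)
    n = values.size
    if not 1 <= n_bins <= n:
        raise ConfigurationError(f"need 1 <= n_bins <= n, got n_bins={n_bins}, n={n}")

    rng = np.random.default_rng(seed)
    # rank-based quantile binning: robust to ties, bins of near-equal size
    ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    bins = (ranks * n_bins) // n

    n_train_total = int(np.floor(p * n))
    bin_members = [np.flatnonzero(bins == b) for b in range(n_bins)]
    base = [int(np.floor(p * len(m))) for m in bin_members]
    frac = [p * len(m) - b for m, b in zip(bin_members, base)]
    deficit = n_train_total - sum(base)
    eligible = [b for b in range(n_bins) if frac[b] > 0 and base[b] < len(bin_members[b])]
    if deficit > 0:
        extra = rng.choice(eligible, size=deficit, replace=False)
    else:
        extra = np.array([], dtype=int)
    take = np.array(base)
    take[extra] += 1

    train_idx = []
    for b in range(n_bins):
        members = bin_members[b]
        chosen = rng.choice(members, size=take[b], replace=False)
        train_idx.extend(chosen.tolist())
    train_idx = np.sort(np.array(train_idx, dtype=int))
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return Partition(
        train_ids=ids[train_idx].tolist(),
        test_ids=ids[test_idx].tolist(),
        p=p,
        n_bins=n_bins,
        seed=seed,
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Population-SD standardization; returns (Xs, mean, sd, zero-var mask)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD (ddof=0)
    nonzero = sd > 0
    Xs = (X[:, nonzero] - mean[nonzero]) / sd[nonzero]
    return Xs, mean, sd, nonzero


def _ridge_solve(Xs: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    n = Xs.shape[0]
    ybar = float(y.mean())
    yc = y - ybar
    gram = Xs.T @ Xs + lam * n * np.eye(Xs.shape[1])
    beta = np.linalg.solve(gram, Xs.T @ yc)
    return beta, ybar


class _RidgePath:
    """SVD factorization of a standardized design for cheap per-lambda solves.

    For lam > 0 the coefficients agree with the penalized normal equations;
    components orthogonal to the row space carry zero weight.
    """

    def __init__(self, Xs: np.ndarray, y: np.ndarray):
        self.n = Xs.shape[0]
        self.ybar = float(y.mean())
        self.U, self.d, self.Vt = np.linalg.svd(Xs, full_matrices=False)
        self.Uty = self.U.T @ (y - self.ybar)

    def coefficients(self, lam: float) -> np.ndarray:
        shrink = self.d / (self.d**2 + lam * self.n)
        return self.Vt.T @ (shrink * self.Uty)


def ridge_fit(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    lam: float,
    outcome_kind: str = "progression",
    feature_level: str = "lmr",
) -> ClockModel:
    """Fit a ridge clock at a fixed penalty.

    ``X`` is samples x features. Zero-variance features are dropped and
    recorded on the model; the intercept is the training outcome mean.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise DataError("X and y sample counts differ")
    if X.shape[0] < 2:
        raise ModelError("need at least 2 samples")
    arr = X.to_numpy(dtype=float)
    if np.isnan(arr).any() or np.isnan(y).any():
        raise DataError("missing values are not permitted")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")

    Xs, mean, sd, nonzero = _standardize(arr)
    if Xs.shape[1] == 0:
        raise ModelError("all features have zero variance")
    beta, ybar = _ridge_solve(Xs, y, lam)
    kept = np.asarray(X.columns)[nonzero]
    dropped = np.asarray(X.columns)[~nonzero]
    return ClockModel(
        outcome_kind=outcome_kind,
        feature_level=feature_level,
        feature_ids=kept.tolist(),
        intercept=ybar,
        coefficients=beta,
        feature_means=mean[nonzero],
        feature_sds=sd[nonzero],
        lam=float(lam),
        dropped_features=dropped.tolist(),
    )


def lambda_path(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_lambda: int = 100,
    ratio: float = 1e-6,
) -> np.ndarray:
    """Geometric penalty sequence from lambda_max down to lambda_max * ratio.

    lambda_max is grown (by doubling) until the largest standardized
    coefficient magnitude falls below 1e-3 of its unpenalized value, so the
    path starts in the effectively-null regime.
    """
    if n_lambda < 2:
        raise ConfigurationError("n_lambda must be >= 2")
    if not 0 < ratio < 1:
        raise ConfigurationError("ratio must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]):
        raise ModelError("constant outcome: lambda path undefined")
    arr = X.to_numpy(dtype=float)
    Xs, _, _, nonzero = _standardize(arr)
    if Xs.shape[1] == 0:
        raise ModelError("all features have zero variance")
    n = Xs.shape[0]
    path = _RidgePath(Xs, y)
    beta0, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
    target = 1e-3 * np.abs(beta0).max()
    lam = max(np.abs(Xs.T @ (y - y.mean())).max() / n, 1e-8)
    for _ in range(200):
        if np.abs(path.coefficients(lam)).max() < target:
            break
        lam *= 2.0
    return lam * np.power(ratio, np.linspace(0.0, 1.0, n_lambda))


def _fold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded fold labels with sizes differing by at most one."""
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(k), n // k + 1)[:n]
    return labels[rng.permutation(n)]


def cv_train(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    k: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    outcome_kind: str = "progression",
    feature_level: str = "lmr",
) -> tuple[ClockModel, CVResult]:
    """k-fold cross-validated lambda selection, then refit on all data.

    For each lambda on the grid the per-fold held-out MAE is recorded; the
    selected lambda minimizes the mean MAE (ties to the larger lambda).
    """
    yv = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds n={n}")
    if lambda_grid is None:
        lambda_grid = lambda_path(X, yv)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    folds = _fold_assignments(n, k, seed)
    fold_mae = np.empty((lambda_grid.size, k))
    for j in range(k):
        test = folds == j
        Xtr, ytr = X.loc[~test], yv[~test]
        Xte, yte = X.loc[test], yv[test]
        arr_tr = Xtr.to_numpy(dtype=float)
        Xs, mean, sd, nonzero = _standardize(arr_tr)
        if Xs.shape[1] == 0:
            raise ModelError("all features zero-variance within a CV fold")
        Xte_s = (Xte.to_numpy(dtype=float)[:, nonzero] - mean[nonzero]) / sd[nonzero]
        path = _RidgePath(Xs, ytr)
        proj = Xte_s @ path.Vt.T  # test samples in the right-singular basis
        for i, lam in enumerate(lambda_grid):
            shrink = path.d / (path.d**2 + lam * path.n)
            pred = path.ybar + proj @ (shrink * path.Uty)
            fold_mae[i, j] = np.abs(pred - yte).mean()

    mean_mae = fold_mae.mean(axis=1)
    sd_mae = fold_mae.std(axis=1, ddof=1) if k > 1 else np.zeros_like(mean_mae)
    best = np.min(mean_mae)
    candidates = np.flatnonzero(mean_mae == best)
    selected = float(lambda_grid[candidates].max())

    model = ridge_fit(X, yv, selected, outcome_kind=outcome_kind, feature_level=feature_level)
    sample_index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    result = CVResult(
        lambda_grid=lambda_grid,
        fold_mae=fold_mae,
        mean_mae=mean_mae,
        sd_mae=sd_mae,
        selected_lambda=selected,
        fold_assignments=pd.Series(folds, index=sample_index),
    )
    return model, result


def make_outcome(phenotypes: pd.DataFrame, kind: str) -> pd.Series:
    """Derive the training outcome from the phenotype table.

    progression = panel-mean visual age minus chronological age.
    """
    if kind not in OUTCOME_KINDS:
        raise ConfigurationError(f"unknown outcome kind: {kind}")
    required = {
        "wrinkle_grade": ["wrinkle_grade"],
        "visual_age": ["visual_age"],
        "progression": ["visual_age", "chronological_age"],
    }[kind]
    missing = [c for c in required if c not in phenotypes.columns]
    if missing:
        raise DataError(f"phenotype table lacks columns: {missing}")
    if kind == "progression":
        return (phenotypes["visual_age"] - phenotypes["chronological_age"]).rename("progression")
    return phenotypes[kind].astype(float)


def predict(model: ClockModel, beta: BetaMatrix) -> pd.Series:
    """Apply a clock: intercept + sum(coef * standardized beta) per sample.

    Missing model features raise (listing the ids); no silent imputation.
    """
    if beta.feature_level != model.feature_level:
        raise DataError(
            f"model expects {model.feature_level}-level features, got {beta.feature_level}"
        )
    missing = [f for f in model.feature_ids if f not in beta.values.index]
    if missing:
        raise DataError(
            f"{len(missing)} model features missing from beta matrix "
            f"(e.g. {missing[:5]})"
        )
    sub = beta.values.loc[model.feature_ids].to_numpy(dtype=float)
    Xs = (sub - model.feature_means[:, None]) / model.feature_sds[:, None]
    pred = model.intercept + model.coefficients @ Xs
    return pd.Series(pred, index=beta.values.columns, name="prediction")
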