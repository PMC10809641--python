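"""Validation statistics: error, correlation, and group discrimination."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ClockModel, make_outcome, predict
from .errors import DataError
from .preprocess import BetaMatrix

EXACT_THRESHOLD_DEFAULT = 25


@dataclass
class ValidationReport:
    n: int
    mae: float
    pearson_r: float | None
    p_value: float | None
    outcome_kind: str
    dataset_label: str
    r_vs_chronological_age: float | None = None
    p_vs_chronological_age: float | None = None
    constant_prediction: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "outcome_kind": self.outcome_kind,
            "dataset_label": self.dataset_label,
            "r_vs_chronological_age": self.r_vs_chronological_age,
            "p_vs_chronological_age": self.p_vs_chronological_age,
            "constant_prediction": self.constant_prediction,
        }


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    rank_sum_statistic: float
    p_value: float
    method: str  # 'exact' | 'normal_approx'

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "n_per_group": list(self.n_per_group),
            "rank_sum_statistic": self.rank_sum_statistic,
            "p_value": self.p_value,
            "method": self.method,
        }


def mae(pred, obs) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise DataError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise DataError("need at least one observation")
    return float(np.abs(pred - obs).mean())


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("length mismatch")
    n = x.size
    if n < 3:
        raise DataError("need n >= 3 for the correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def _rank_sum_counts(n_total: int, n_a: int) -> np.ndarray:
    """counts[s] = number of size-n_a subsets of ranks {1..n_total} summing to s."""
    max_sum = n_total * (n_total + 1) // 2
    # dp[j][s]: subsets of size j with sum s, built rank by rank
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=object)
    dp[0][0] = 1
    for rank in range(1, n_total + 1):
        for j in range(min(rank, n_a), 0, -1):
            dp[j][rank:] = dp[j][rank:] + dp[j - 1][:-rank or None]
    return dp[n_a]


def wilcoxon_rank_sum(
    a, b, exact_threshold: int = EXACT_THRESHOLD_DEFAULT,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided rank-sum test on pooled mid-ranks.

    Exact p (full enumeration of rank assignments via a subset-sum count) is
    used when both groups have <= ``exact_threshold`` members and the pooled
    data are tie-free; otherwise the normal approximation with tie and
    continuity corrections. Two-sided p = min(1, 2 x smaller tail).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    w = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    has_ties = np.unique(pooled).size < n

    if not has_ties and n_a <= exact_threshold and n_b <= exact_threshold:
        counts = _rank_sum_counts(n, n_a)
        total = counts.sum()
        wi = int(round(w))
        p_low = sum(counts[: wi + 1]) / total
        p_high = sum(counts[wi:]) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mean_w = n_a * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
        var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:  # all values identical
            return GroupComparison(labels, (n_a, n_b), w, 1.0, "normal_approx")
        z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
        method = "normal_approx"
    p = max(p, np.nextafter(0, 1))
    return GroupComparison(labels, (n_a, n_b), w, float(p), method)


def progression_from_predictions(predicted_visual_age, chronological_age):
    """Predicted progression = predicted visual age - chronological age."""
    pred = np.asarray(predicted_visual_age, dtype=float)
    chron = np.asarray(chronological_age, dtype=float)
    if pred.shape != chron.shape:
        raise DataError("length mismatch")
    return pred - chron


def validate_clock(
    model: ClockModel,
    beta: BetaMatrix,
    phenotypes: pd.DataFrame,
    dataset_label: str = "test",
) -> ValidationReport:
    """MAE + Pearson test of predictions against the observed outcome.

    For progression clocks, the correlation of predictions with
    chronological age is reported as a secondary diagnostic. A constant
    prediction vector is flagged instead of raising.
    """
    missing = beta.values.columns.difference(phenotypes.index)
    if len(missing):
        raise DataError(f"phenotypes missing for samples: {missing[:5].tolist()}")
    obs = make_outcome(phenotypes, model.outcome_kind).loc[beta.values.columns]
    pred = predict(model, beta)

    err = mae(pred.to_numpy(), obs.to_numpy())
    constant = bool(np.ptp(pred.to_numpy()) == 0)
    if constant or np.ptp(obs.to_numpy()) == 0:
        r, p = None, None
        constant = True
    else:
        r, p = pearson_test(pred.to_numpy(), obs.to_numpy())

    r_age = p_age = None
    if model.outcome_kind == "progression" and "chronological_age" in phenotypes.columns:
        age = phenotypes.loc[beta.values.columns, "chronological_age"].to_numpy(dtype=float)
        if not constant and np.ptp(age) > 0:
            r_age, p_age = pearson_test(pred.to_numpy(), age)
    return ValidationReport(
        n=int(len(pred)),
        mae=err,
        pearson_r=r,
        p_value=p,
        outcome_kind=model.outcome_kind,
        dataset_label=dataset_label,
        r_vs_chronological_age=r_age,
        p_vs_chronological_age=p_age,
        constant_prediction=constant,
    )
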