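"""Evaluation statistics for affinity regression: concordance index, MSE, Pearson R.

The concordance index (CI) is the probability that a randomly chosen pair of
measurements with distinct true affinities is ranked in the same order by the
predictions as by the ground truth.  Tied predictions score 1/2; pairs tied on
the ground truth are excluded.  This is the standard c-index used throughout
the drug-target-affinity literature, so CI values here are directly comparable
to published benchmark tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["concordance_index", "mse", "pearson_r", "ExperimentReport"]


def concordance_index(truth, pred) -> float:
    """Concordance index over all pairs with distinct true values.

    For every pair (i, j) with truth_i > truth_j the pair scores 1 if
    pred_i > pred_j, 0.5 if pred_i == pred_j and 0 otherwise; the CI is the
    mean score.  Returns NaN (with a warning) when all truths are tied, since
    no ordering information exists.
    """
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and pred must be 1-D arrays of equal length")
    if t.size < 2:
        raise ValueError("need at least two observations")
    # pairwise sign matrices; only the upper triangle of distinct-truth pairs counts
    dt = t[:, None] - t[None, :]
    dp = p[:, None] - p[None, :]
    iu = np.triu_indices(t.size, k=1)
    dt = dt[iu]
    dp = dp[iu]
    usable = dt != 0
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        warnings.warn("concordance index undefined: all true values tied")
        return float("nan")
    # orient every pair so that truth increases, then score the prediction order
    s = np.sign(dt[usable]) * dp[usable]
    score = np.where(s > 0, 1.0, np.where(s == 0, 0.5, 0.0))
    return float(score.sum() / n_pairs)


def mse(truth, pred) -> float:
    """Mean squared error."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and pred must be 1-D arrays of equal length")
    if t.size == 0:
        raise ValueError("mse of empty vectors is undefined")
    return float(np.mean((t - p) ** 2))


def pearson_r(truth, pred) -> float:
    """Product-moment correlation; NaN (with a warning) if either input is constant."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and pred must be 1-D arrays of equal length")
    if t.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        warnings.warn("pearson correlation undefined for a constant vector")
        return float("nan")
    return float(np.corrcoef(t, p)[0, 1])


@dataclass
class ExperimentReport:
    """Accumulates per-(dataset, scheme, model) evaluation rows, Table-style."""

    rows: list = field(default_factory=list)

    COLUMNS = ["dataset", "scheme", "model", "ci", "mse", "pearson_r", "n_test", "seed"]

    def add(self, dataset: str, scheme: str, model: str, truth, pred, seed: int,
            **extra) -> dict:
        truth = np.asarray(truth, dtype=float)
        pred = np.asarray(pred, dtype=float)
        row = {
            "dataset": dataset,
            "scheme": scheme,
            "model": model,
            "ci": concordance_index(truth, pred),
            "mse": mse(truth, pred),
            "pearson_r": pearson_r(truth, pred),
            "n_test": int(truth.size),
            "seed": int(seed),
        }
        row.update(extra)
        self.rows.append(row)
        return row

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        lead = [c for c in self.COLUMNS if c in df.columns]
        rest = [c for c in df.columns if c not in lead]
        return df[lead + rest] if len(df) else pd.DataFrame(columns=self.COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
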