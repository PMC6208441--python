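"""Validation statistics: RMSE/MBE, Nash-Sutcliffe efficiency, Welch t, kappa."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["validate_series", "yield_t_test", "ErrorMatrix", "error_matrix", "cohens_kappa"]


def validate_series(simulated, observed) -> dict:
    """Agreement statistics between simulated and observed paired series.

    Returns RMSE, MBE (sim minus obs), Nash-Sutcliffe model efficiency
    ME = 1 - sum((O-S)^2) / sum((O-Obar)^2), and the R^2 of the simple OLS
    fit of O on S. A constant observed series leaves ME undefined (NaN,
    flagged) because the mean-predictor baseline has zero variance.
    """
    s = np.asarray(simulated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if s.shape != o.shape or s.size < 2:
        raise ValueError("need paired series with n >= 2")
    if not (np.isfinite(s).all() and np.isfinite(o).all()):
        raise ValueError("series must be finite")
    err = s - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mbe = float(np.mean(err))
    ss_obs = float(np.sum((o - o.mean()) ** 2))
    flags = []
    if ss_obs > 0:
        me = float(1.0 - np.sum(err**2) / ss_obs)
    else:
        me, flags = float("nan"), ["constant_observed"]
    if np.std(s) > 0 and np.std(o) > 0:
        r2 = float(np.corrcoef(s, o)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return {"rmse": rmse, "mbe": mbe, "me": me, "r2": r2, "flags": flags}


def yield_t_test(sample_a, sample_b) -> dict:
    """Welch two-sample t test (two-sided).

    Degenerate case: both samples have zero variance. Equal means then give
    t = 0, p = 1; unequal means give p = 0 (infinitely separated under the
    zero-variance model).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0}
        return {"t": float(np.inf if a.mean() > b.mean() else -np.inf), "p": 0.0}
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p)}


@dataclass
class ErrorMatrix:
    """2x2 confusion counts (rows: reference, cols: predicted) with accuracy and kappa."""

    counts: np.ndarray
    overall_accuracy: float
    kappa: float

    @property
    def kappa_percent(self) -> float:
        return 100.0 * self.kappa


def cohens_kappa(counts) -> float:
    """Cohen's kappa from a square confusion matrix; 0 when chance agreement is total."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / n
    p_e = float(np.sum(c.sum(axis=0) * c.sum(axis=1)) / n**2)
    if 1.0 - p_e < 1e-12:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def error_matrix(predicted, reference) -> ErrorMatrix:
    """Binary classification error matrix with overall accuracy and kappa."""
    pred = np.asarray(predicted).ravel()
    ref = np.asarray(reference).ravel()
    if pred.size == 0 or pred.size != ref.size:
        raise ValueError("predicted and reference must be non-empty and equal-shape")
    counts = np.zeros((2, 2), dtype=int)
    for r in (0, 1):
        for p in (0, 1):
            counts[r, p] = int(np.sum((ref == r) & (pred == p)))
    acc = float(np.trace(counts) / counts.sum())
    return ErrorMatrix(counts, acc, cohens_kappa(counts))
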