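"""Statistical utilities for motif-level analysis.

Covers the power calculation for correlation-style effect sizes (the
Fisher-z approximation with small-sample bias correction, as implemented by
the classic ``pwr.r.test`` routine), partial correlation from the precision
matrix, variance-stabilizing transforms, FDR-controlled two-group
comparison of structure matrices, and export of model-ready long-format
tables for external estimating-equation (GEE) fitting.

Note on the power convention: regression effect sizes (marginal R^2) are
passed directly as the effect size ``r`` of the correlation power routine;
with median mR^2 = 0.45 this predicts 80% power at 36 samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PowerQuery",
    "correlation_power",
    "power_curve",
    "sample_size_for_power",
    "partial_correlation",
    "transform",
    "group_compare_fdr",
    "model_ready_table",
]


@dataclass(frozen=True)
class PowerQuery:
    r: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.r < 1):
            raise ValueError("effect size r must lie in (0, 1)")
        if self.n < 4:
            raise ValueError("sample size must be >= 4")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def correlation_power(q: PowerQuery | None = None, *, r: float | None = None,
                      n: int | None = None, alpha: float = 0.05) -> float:
    """Power of the two-sided test of a Pearson correlation.

    Fisher-z approximation with small-sample bias correction: the critical
    r comes from the t critical value at n-2 df, and

        power = Phi((z(r) + r / (2(n-1)) - z(r_crit)) * sqrt(n-3))

    where z is the Fisher transform (arctanh).
    """
    if q is None:
        q = PowerQuery(r=float(r), n=int(n), alpha=alpha)
    t_crit = scipy.stats.t.ppf(1 - q.alpha / 2, q.n - 2)
    r_crit = math.sqrt(t_crit**2 / (t_crit**2 + q.n - 2))
    zr = math.atanh(q.r) + q.r / (2 * (q.n - 1))
    zc = math.atanh(r_crit)
    return float(scipy.stats.norm.cdf((zr - zc) * math.sqrt(q.n - 3)))


def power_curve(r: float, ns, alpha: float = 0.05) -> pd.Series:
    """Predicted power over a range of sample sizes (e.g. n = 5..200)."""
    return pd.Series(
        {int(n): correlation_power(PowerQuery(r, int(n), alpha)) for n in ns}
    )


def sample_size_for_power(r: float, target: float, alpha: float = 0.05,
                          n_max: int = 10000) -> int:
    """Smallest n at which the predicted power reaches ``target``."""
    for n in range(4, n_max + 1):
        if correlation_power(PowerQuery(r, n, alpha)) >= target:
            return n
    raise ValueError(f"power {target} not reached by n = {n_max}")


def partial_correlation(
    matrix: pd.DataFrame, *, regularization: float = 0.0
) -> pd.DataFrame:
    """Partial correlations between columns from the precision matrix.

    ``matrix`` is samples x structures.  rho_ij = -P_ij / sqrt(P_ii P_jj)
    with P the inverse covariance; the diagonal is 1.  Ridge
    ``regularization`` (added to the covariance diagonal) handles
    rank-deficient inputs; without it a singular covariance is an error.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if regularization > 0:
        cov = cov + regularization * np.eye(p)
    elif n <= p or np.linalg.matrix_rank(cov) < p:
        raise np.linalg.LinAlgError(
            "singular covariance; enable regularization or add samples"
        )
    P = np.linalg.inv(cov)
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.columns, columns=matrix.columns)


def transform(
    values: pd.DataFrame | pd.Series,
    kind: str = "sqrt",
    pseudo_count: float | None = None,
) -> pd.DataFrame | pd.Series:
    """Variance-stabilizing transform then per-feature z-scoring.

    ``kind`` is ``'sqrt'`` or ``'log'``; features are rows of a DataFrame
    (samples are columns) or a single Series.  Zero-variance features map to
    0 with a warning; log of 0 without a pseudo-count is an error.
    """
    if kind not in ("sqrt", "log"):
        raise ValueError("kind must be 'sqrt' or 'log'")
    frame = values.to_frame().T if isinstance(values, pd.Series) else values
    arr = frame.to_numpy(dtype=float)
    if kind == "sqrt":
        if (arr < 0).any():
            raise ValueError("sqrt transform needs non-negative values")
        arr = np.sqrt(arr)
    else:
        if pseudo_count is not None:
            arr = arr + pseudo_count
        if (arr <= 0).any():
            raise ValueError("log of non-positive value; set a pseudo_count")
        arr = np.log(arr)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance feature(s) mapped to 0")
    sd = np.where(degenerate, 1.0, sd)
    out = (arr - mean) / sd
    out[np.broadcast_to(degenerate, out.shape)] = 0.0
    result = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return result.iloc[0] if isinstance(values, pd.Series) else result


def group_compare_fdr(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per structure with Benjamini-Hochberg FDR.

    ``matrix`` is structures x samples; ``groups`` maps sample -> one of two
    labels.  Returns a frame with t statistic, p, q (BH-adjusted), log2 fold
    change, and a significance flag at ``alpha``.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    a_cols = [c for c in matrix.columns if groups.get(c) == labels[0]]
    b_cols = [c for c in matrix.columns if groups.get(c) == labels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least two samples")
    A = matrix[a_cols].to_numpy(dtype=float)
    B = matrix[b_cols].to_numpy(dtype=float)
    t, p = scipy.stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    eps = 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        # undefined (NaN) when a group mean is negative, e.g. z-scored input
        lfc = np.log2((A.mean(axis=1) + eps) / (B.mean(axis=1) + eps))
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "log2fc": lfc,
            "significant": q < alpha,
        },
        index=matrix.index,
    )


def model_ready_table(
    profiles,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format (sample, structure, value) table joined with metadata,
    ready for external estimating-equation (GEE) model fitting."""
    rows = []
    for p in profiles:
        values = p.values if hasattr(p, "values") else p.abundances
        for key, v in values.items():
            rows.append({"sample": p.sample_id, "structure": key, "value": v})
    long = pd.DataFrame(rows)
    return long.merge(metadata, left_on="sample", right_index=True, how="left")
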