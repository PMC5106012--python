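"""Molecular-clock fit: closed-form least squares with times held fixed.

Under the clock model each site changes linearly with chronological age,

    ŝ_ij = s_i0 + r_i · t_j + ε_ij,      ε_ij ~ N(0, σ²) iid,

so maximizing the likelihood is the same as minimizing the residual sum of
squares RSS = Σ_ij ε_ij².  The full problem can be written as one
``mn × 2n`` linear system (see :func:`build_design_matrix`), but the system
is block-separable by site, so the production path solves ``n`` independent
simple regressions in O(n·m) — the design-matrix route is kept purely as a
testing oracle.
"""

from __future__ import annotations

import numpy as np

from .data import (
    InsufficientDataError,
    MCFit,
    MethylationDataset,
    SingularDesignError,
    ValidationError,
)

__all__ = ["fit_mc", "build_design_matrix", "rss_of"]


def _check_times(times: np.ndarray, m: int) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.shape != (m,):
        raise ValidationError(f"times vector has shape {times.shape}, expected ({m},)")
    if not np.all(np.isfinite(times)) or np.any(times <= 0):
        raise ValidationError("times must be finite and strictly positive")
    if np.ptp(times) == 0.0:
        raise SingularDesignError(
            "all times are equal: rate and start level are confounded"
        )
    return times


def fit_mc(ds: MethylationDataset, times: np.ndarray | None = None) -> MCFit:
    """Maximum-likelihood clock fit of per-site rates and start levels.

    Parameters
    ----------
    ds
        Validated dataset.
    times
        Length-``m`` strictly positive vector with at least two distinct
        values.  Defaults to the dataset's chronological ages.

    Returns
    -------
    MCFit
        Per-site ``(r_i, s_i0)`` minimizing the residual sum of squares,
        with the residual matrix and total RSS.
    """
    if ds.n < 1 or ds.m < 2:
        raise InsufficientDataError(
            f"clock fit needs n>=1 sites and m>=2 individuals, got {ds.n}x{ds.m}"
        )
    if times is None:
        if ds.ages is None:
            raise ValidationError("dataset has no ages and no times were given")
        times = ds.ages
    times = _check_times(times, ds.m)

    v = ds.values
    tbar = times.mean()
    dt = times - tbar
    sxx = float(dt @ dt)
    sbar = v.mean(axis=1)
    # Centered cross-product keeps the estimate well conditioned.
    rates = (v - sbar[:, None]) @ dt / sxx
    starts = sbar - rates * tbar
    residuals = v - np.outer(rates, times) - starts[:, None]
    rss = float(np.einsum("ij,ij->", residuals, residuals))
    return MCFit(rates=rates, starts=starts, rss=rss, residuals=residuals)


def build_design_matrix(
    ds: MethylationDataset, times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the full ``mn × 2n`` clock design (testing oracle).

    Row ``k = i·m + j`` corresponds to matrix entry ``(i, j)``: its only
    nonzeros are ``times[j]`` at column ``i`` and ``1`` at column ``n + i``,
    and ``y[k] = ŝ_ij``.  Solving the least-squares system gives
    ``β = (r_1..r_n, s_1^0..s_n^0)``.  O((2n)³) to solve — use
    :func:`fit_mc` for real work.
    """
    if times is None:
        times = ds.ages
    times = _check_times(np.asarray(times, dtype=float), ds.m)
    n, m = ds.n, ds.m
    X = np.zeros((n * m, 2 * n))
    y = np.empty(n * m)
    for i in range(n):
        rows = slice(i * m, (i + 1) * m)
        X[rows, i] = times
        X[rows, n + i] = 1.0
        y[rows] = ds.values[i, :]
    return X, y


def rss_of(
    ds: MethylationDataset,
    times: np.ndarray,
    rates: np.ndarray,
    starts: np.ndarray,
) -> float:
    """Residual sum of squares Σ_ij (ŝ_ij − r_i·t_j − s_i0)²."""
    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    starts = np.asarray(starts, dtype=float)
    if times.shape != (ds.m,) or rates.shape != (ds.n,) or starts.shape != (ds.n,):
        raise ValidationError(
            f"dimension mismatch: values {ds.values.shape}, times {times.shape}, "
            f"rates {rates.shape}, starts {starts.shape}"
        )
    resid = ds.values - np.outer(rates, times) - starts[:, None]
    return float(np.einsum("ij,ij->", resid, resid))
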