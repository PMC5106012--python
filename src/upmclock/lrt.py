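"""Likelihood-ratio test comparing the clock (null) to the pacemaker model.

With iid Gaussian noise and the variance profiled out, the log likelihood
of either model at its optimum is −(nm/2)·log(RSS) + const, so the LRT
statistic reduces to a ratio of residual sums of squares:

    χ² = n·m·log(RSS_clock / RSS_pacemaker) = −2·log Λ,

referred to a χ² distribution whose degrees of freedom default to m — the
number of free epigenetic ages gained by the pacemaker model.  Natural
logarithms throughout.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .data import FitError, LRTResult, MethylationDataset, ValidationError
from .mc import MCFit, fit_mc
from .upm import UPMFit, UPMSearchOptions, fit_upm

__all__ = [
    "lrt_statistic",
    "lrt_pvalue",
    "chi2_critical",
    "profile_loglikelihood",
    "compare_models",
]

#: Relative slack for rss_upm exceeding rss_mc from floating-point noise.
RSS_REL_TOL = 1e-8


def lrt_statistic(
    rss_mc: float,
    rss_upm: float,
    n: int,
    m: int,
    df: int | None = None,
    rss_floor: float = 0.0,
) -> LRTResult:
    """Build the χ² statistic from the two fitted RSS values (no p-value yet).

    Parameters
    ----------
    rss_mc, rss_upm
        Maximum-likelihood residual sums of squares of the clock and
        pacemaker fits on the same n×m dataset; ``rss_mc >= rss_upm`` must
        hold (the models are nested).
    df
        Degrees of freedom; defaults to ``m``.
    rss_floor
        Both RSS values are floored at this value before the ratio is
        taken.  Pipelines set it to ~1e-12 of the data's total sum of
        squares so that fits perfect to machine precision give χ² = 0
        instead of a log-ratio of rounding artifacts.

    Raises
    ------
    FitError
        If ``rss_upm`` exceeds ``rss_mc`` by more than floating-point slack
        (an upstream optimizer failure — never silently clipped), or if the
        floored ``rss_upm`` is zero (infinite statistic).
    """
    if n < 1 or m < 1:
        raise ValidationError("n and m must be positive")
    if rss_mc < 0 or rss_upm < 0:
        raise ValidationError("RSS values must be nonnegative")
    rss_mc_eff = max(rss_mc, rss_floor)
    rss_upm_eff = max(rss_upm, rss_floor)
    if rss_upm_eff == 0.0:
        raise FitError(
            "pacemaker RSS is zero: the statistic is infinite. The data are "
            "noise-free under the pacemaker model; a model comparison is not "
            "meaningful (consider rss_floor or adding replicates)."
        )
    if rss_upm_eff > rss_mc_eff:
        if rss_upm_eff - rss_mc_eff <= RSS_REL_TOL * rss_mc_eff:
            chi2 = 0.0
        else:
            raise FitError(
                f"pacemaker RSS ({rss_upm_eff:.6g}) exceeds clock RSS "
                f"({rss_mc_eff:.6g}) beyond numerical tolerance: the pacemaker "
                "optimizer failed to reach the nested optimum"
            )
    else:
        chi2 = float(n * m * np.log(rss_mc_eff / rss_upm_eff))
    return LRTResult(
        chi2=chi2,
        df=int(m if df is None else df),
        p_value=None,
        rss_mc=float(rss_mc),
        rss_upm=float(rss_upm),
        log_lambda=-chi2 / 2.0,
    )


def lrt_pvalue(result: LRTResult) -> LRTResult:
    """Attach the upper-tail χ²(df) probability at the observed statistic."""
    if result.chi2 < 0:
        raise ValidationError("chi2 must be nonnegative")
    if result.df < 1:
        raise ValidationError("df must be >= 1")
    p = float(stats.chi2.sf(result.chi2, result.df))
    return replace(result, p_value=p)


def chi2_critical(df: int, alpha: float) -> float:
    """The value with upper-tail probability ``alpha`` under χ²(df)."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValidationError("df must be >= 1")
    return float(stats.chi2.isf(alpha, df))


def profile_loglikelihood(rss: float, n: int, m: int) -> float:
    """Gaussian log likelihood at the fit with σ² profiled out.

    With σ̂² = rss/(nm), equals −(nm/2)·(log(2π·rss/nm) + 1): strictly
    decreasing in the RSS, which is why least squares is the
    maximum-likelihood solution.
    """
    if rss <= 0:
        raise ValidationError("rss must be positive")
    nm = n * m
    return float(-0.5 * nm * (np.log(2.0 * np.pi * rss / nm) + 1.0))


def compare_models(
    ds: MethylationDataset,
    opts: UPMSearchOptions | None = None,
    df: int | None = None,
) -> tuple[MCFit, UPMFit, LRTResult]:
    """Fit both models on one dataset and run the LRT.

    The RSS floor is set to 1e-12 of the data's total sum of squares, so a
    clock fit that is already perfect to machine precision yields χ² = 0
    (no evidence of a pacemaker) rather than an unstable log ratio.
    """
    mcfit = fit_mc(ds)
    upmfit = fit_upm(ds, opts)
    floor = 1e-12 * max(float(np.sum(ds.values**2)), 1e-300)
    result = lrt_statistic(
        mcfit.rss, upmfit.rss, ds.n, ds.m, df=df, rss_floor=floor
    )
    return mcfit, upmfit, lrt_pvalue(result)
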