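"""Universal-pacemaker fit: joint estimation of site trends and epigenetic ages.

Under the pacemaker model every site in an individual may speed up or slow
down, but all sites do so by the same proportion, so pairwise rate ratios
are preserved.  Equivalently, the model keeps the linear form

    ŝ_ij = s_i0 + r_i · t_j' + ε_ij

but replaces each chronological age t_j with a free "epigenetic age" t_j'.
The key structural fact is that the search can be confined to the
m-dimensional space of times: for any candidate time vector the remaining
2n site parameters have the same closed-form least-squares solution as the
clock model (:func:`conditional_site_fit`).  Two search strategies over the
time space are provided:

``alternating`` (default)
    Block coordinate descent on the bilinear RSS: closed-form site update
    (:func:`conditional_site_fit`) alternating with the closed-form
    per-individual time update (:func:`conditional_times_fit`).  Each step
    is exact, so the RSS decreases monotonically.

``direct-search``
    A bounded SLSQP search over the time vector with the closed-form site
    fit nested inside the objective — the sequential least-squares approach.

Both start from the chronological ages (guaranteeing the fitted RSS never
exceeds the clock RSS) plus random lognormal jitters of them, and keep the
best of ``n_starts`` restarts.

The likelihood is invariant under an affine gauge: replacing times by
a·t + b, rates by r/a and starts by s0 − (r/a)·b changes no fitted value,
so the epigenetic times are identified only up to an affine map.
:func:`fit_upm` therefore anchors the fitted times to the chronological
ages by the RSS-minimizing affine transform (a pure reporting convention),
and :func:`normalize_scale` separately exposes the scale part of the gauge
(mean epigenetic age anchored to mean chronological age).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .data import (
    FitError,
    InsufficientDataError,
    MethylationDataset,
    UPMFit,
    ValidationError,
)
from .mc import fit_mc, rss_of

__all__ = [
    "UPMSearchOptions",
    "fit_upm",
    "conditional_site_fit",
    "conditional_times_fit",
    "normalize_scale",
    "average_rates",
]

_STRATEGIES = ("alternating", "direct-search")


@dataclass
class UPMSearchOptions:
    """Tuning knobs for the pacemaker search.

    ``n_starts`` random restarts (the first is always the unjittered
    chronological ages); iteration stops when the relative RSS improvement
    drops below ``rel_tol`` or after ``max_outer_iters`` outer steps.
    Epigenetic times are constrained to be at least ``time_lower_bound``
    years: negative or zero times are biologically meaningless and break
    the average-rate definition.  All randomness is driven by ``seed``.
    """

    n_starts: int = 10
    max_outer_iters: int = 500
    rel_tol: float = 1e-9
    time_lower_bound: float = 1e-3
    seed: int = 0
    strategy: str = "alternating"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if self.rel_tol <= 0:
            raise ValidationError("rel_tol must be > 0")
        if self.time_lower_bound <= 0:
            raise ValidationError("time_lower_bound must be > 0")
        if self.strategy not in _STRATEGIES:
            raise ValidationError(
                f"unknown strategy {self.strategy!r}; expected one of {_STRATEGIES}"
            )


def conditional_site_fit(
    ds: MethylationDataset, candidate_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form site parameters given a fixed candidate time vector.

    Identical contract to the clock fit with ``times := candidate_times``;
    returns ``(rates, starts, rss)``.
    """
    fit = fit_mc(ds, candidate_times)
    return fit.rates, fit.starts, fit.rss


def conditional_times_fit(
    ds: MethylationDataset,
    rates: np.ndarray,
    starts: np.ndarray,
    lower_bound: float = 1e-3,
) -> np.ndarray:
    """Per-individual RSS-minimizing times given fixed site parameters.

    Setting the derivative of the column-``j`` RSS term to zero gives

        t_j = Σ_i r_i (ŝ_ij − s_i0) / Σ_i r_i²,

    clipped below at ``lower_bound``.
    """
    rates = np.asarray(rates, dtype=float)
    starts = np.asarray(starts, dtype=float)
    if rates.shape != (ds.n,) or starts.shape != (ds.n,):
        raise ValidationError("rates/starts length must equal the site count")
    rr = float(rates @ rates)
    if rr == 0.0:
        raise ValidationError("all rates are zero: times are unidentifiable")
    t = rates @ (ds.values - starts[:, None]) / rr
    return np.maximum(t, lower_bound)


def _run_alternating(
    ds: MethylationDataset, times0: np.ndarray, opts: UPMSearchOptions
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    lb = opts.time_lower_bound
    t = np.maximum(times0, lb)
    rates, starts, rss = conditional_site_fit(ds, t)
    for _ in range(opts.max_outer_iters):
        try:
            t_new = conditional_times_fit(ds, rates, starts, lb)
        except ValidationError:
            break  # all rates zero: flat data, nothing left to move
        if np.ptp(t_new) <= 1e-12 * max(1.0, float(np.abs(t_new).max())):
            break  # gauge collapsed; keep the previous iterate
        rates_new, starts_new, rss_new = conditional_site_fit(ds, t_new)
        improvement = rss - rss_new
        rates, starts, t, rss = rates_new, starts_new, t_new, rss_new
        if improvement <= opts.rel_tol * max(rss, 1e-300):
            break
    return rates, starts, t, rss


def _run_direct(
    ds: MethylationDataset, times0: np.ndarray, opts: UPMSearchOptions
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    lb = opts.time_lower_bound
    times0 = np.maximum(times0, lb)
    _, _, f0 = conditional_site_fit(ds, times0)
    penalty = 1e6 * max(f0, 1.0)

    def objective(t: np.ndarray) -> float:
        if np.ptp(t) <= 1e-12 * max(1.0, float(np.abs(t).max())):
            return penalty
        return conditional_site_fit(ds, t)[2]

    res = minimize(
        objective,
        x0=times0,
        method="SLSQP",
        bounds=[(lb, None)] * ds.m,
        options={
            "maxiter": opts.max_outer_iters,
            "ftol": max(opts.rel_tol * max(f0, 1e-12), 1e-15),
        },
    )
    t = np.maximum(np.asarray(res.x, dtype=float), lb)
    if objective(t) > f0:
        t = times0  # optimizer wandered off; keep the start point
    rates, starts, rss = conditional_site_fit(ds, t)
    return rates, starts, t, rss


def _affine_anchor(
    rates: np.ndarray,
    starts: np.ndarray,
    times: np.ndarray,
    ages: np.ndarray,
    lower_bound: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick the gauge-orbit representative calibrated to chronological age.

    The fitted times are regressed on the ages (t_fit ~ alpha*age + beta)
    and the inverse map is applied, so the anchored epigenetic ages are an
    unbiased linear readout of chronological age: their regression on age
    has slope 1 and intercept 0, while per-individual deviations — the
    pacemaker signal — are preserved at full scale.  A pure gauge transform,
    so the RSS is untouched.  Falls back to the identity when ill-posed
    (non-positive slope) or when it would violate time positivity.
    """
    tbar, abar = times.mean(), ages.mean()
    da = ages - abar
    sxx = float(da @ da)
    if sxx <= 0.0:
        return rates, starts, times
    alpha = float(da @ (times - tbar)) / sxx
    if alpha <= 0.0:
        return rates, starts, times
    # invert t_fit = alpha*age + beta:  anchored = (t_fit - beta)/alpha
    a = 1.0 / alpha
    b = -(tbar - alpha * abar) / alpha
    new_times = a * times + b
    if np.any(new_times < lower_bound):
        return rates, starts, times
    new_rates = rates / a
    new_starts = starts - new_rates * b
    return new_rates, new_starts, new_times


def fit_upm(ds: MethylationDataset, opts: UPMSearchOptions | None = None) -> UPMFit:
    """Maximum-likelihood pacemaker fit via multi-start search in time space.

    Returns the best fit over ``opts.n_starts`` restarts.  The first restart
    begins at the chronological ages, so the fitted RSS never exceeds the
    clock-model RSS.  The affine gauge is fixed by anchoring the fitted
    times to the chronological ages (see :func:`_affine_anchor`), then
    :func:`normalize_scale` records the scale convention.
    """
    opts = opts or UPMSearchOptions()
    ds.validate()
    if ds.n < 2 or ds.m < 3:
        raise InsufficientDataError(
            f"pacemaker fit needs n>=2 sites and m>=3 individuals, got {ds.n}x{ds.m}"
        )
    if np.allclose(ds.values, ds.values[:, [0]]):
        raise ValidationError(
            "degenerate data: all individuals have identical methylation columns"
        )
    runner = _run_alternating if opts.strategy == "alternating" else _run_direct
    rng = np.random.default_rng(opts.seed)
    ages = ds.ages

    best: tuple[np.ndarray, np.ndarray, np.ndarray, float] | None = None
    per_start: list[float] = []
    failures: list[str] = []
    for k in range(opts.n_starts):
        times0 = ages if k == 0 else ages * rng.lognormal(0.0, 0.2, ds.m)
        try:
            rates, starts, t, rss = runner(ds, times0, opts)
        except (ValidationError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(f"start {k}: {exc}")
            per_start.append(float("nan"))
            continue
        per_start.append(rss)
        if best is None or rss < best[3]:
            best = (rates, starts, t, rss)
    if best is None:
        raise FitError(
            "pacemaker optimization failed on every restart: " + "; ".join(failures)
        )
    rates, starts, t, rss = best
    rates, starts, t = _affine_anchor(rates, starts, t, ages, opts.time_lower_bound)
    fit = UPMFit(
        rates=rates,
        starts=starts,
        epigenetic_times=t,
        rss=rss,
        n_starts=opts.n_starts,
        converged_rss_per_start=per_start,
        normalization="none",
    )
    return normalize_scale(fit, ages)


def normalize_scale(fit: UPMFit, chronological_ages: np.ndarray) -> UPMFit:
    """Fix the scale gauge: anchor mean epigenetic age to mean chronological age.

    Times are multiplied and rates divided by
    ``c = mean(chronological_ages) / mean(epigenetic_times)``; the RSS is
    unchanged because only the products ``r_i · t_j`` enter the model.
    """
    ages = np.asarray(chronological_ages, dtype=float)
    mean_t = float(np.mean(fit.epigenetic_times))
    if mean_t <= 0:
        raise ValidationError("mean epigenetic time must be positive to normalize")
    c = float(np.mean(ages)) / mean_t
    return replace(
        fit,
        epigenetic_times=fit.epigenetic_times * c,
        rates=fit.rates / c,
        normalization="mean-age-anchored",
    )


def average_rates(
    ds: MethylationDataset, starts: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Measured average rates r_ij = (ŝ_ij − s_i0) / t_j as an (n, m) matrix.

    Under an exact pacemaker, r_ij factors as r_i · (t_j'/t_j): the ratio of
    average rates between two sites is the same for every individual.
    """
    starts = np.asarray(starts, dtype=float)
    times = np.asarray(times, dtype=float)
    if starts.shape != (ds.n,) or times.shape != (ds.m,):
        raise ValidationError("starts must be length n and times length m")
    if np.any(times == 0):
        raise ValidationError("times must be nonzero to compute average rates")
    return (ds.values - starts[:, None]) / times[None, :]


def upm_rss_check(ds: MethylationDataset, fit: UPMFit) -> float:
    """Recompute the RSS of a pacemaker fit from its parameters."""
    return rss_of(ds, fit.epigenetic_times, fit.rates, fit.starts)
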