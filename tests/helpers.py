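"""Independent oracles shared by the unit and acceptance tests.

Everything here deliberately avoids the package's production code paths:
per-site regressions go through numpy.polyfit, scalar minimizations through
scipy.optimize, and the tiny-instance pacemaker optimum through an
exhaustive grid plus coordinate descent.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def oracle_rss_at(times: np.ndarray, values: np.ndarray) -> float:
    """Total RSS of independent per-site linear fits at fixed times."""
    rss = 0.0
    for row in values:
        coef = np.polyfit(times, row, 1)
        rss += float(((row - np.polyval(coef, times)) ** 2).sum())
    return rss


def brute_force_upm_rss(
    values: np.ndarray,
    ages: np.ndarray,
    lower_bound: float = 1e-3,
    grid_points: int = 45,
) -> float:
    """Global pacemaker RSS on a 3-individual instance.

    Exploits the scale gauge: the time vector is anchored to
    sum(t) = 3·mean(age), leaving a 2-D search, swept on a dense grid and
    refined by bounded coordinate descent.
    """
    assert values.shape[1] == 3, "brute force oracle is for m=3 instances"
    mean_age = float(np.mean(ages))
    total = 3.0 * mean_age
    grid = np.linspace(lower_bound, total - 2 * lower_bound, grid_points)
    best, best_t = np.inf, None
    for t1 in grid:
        for t2 in grid:
            t3 = total - t1 - t2
            if t3 < lower_bound:
                continue
            t = np.array([t1, t2, t3])
            if np.ptp(t) < 1e-9:
                continue
            r = oracle_rss_at(t, values)
            if r < best:
                best, best_t = r, t
    t = best_t.copy()
    for _ in range(200):
        prev = best
        for j in range(3):

            def f(x, j=j):
                tt = t.copy()
                tt[j] = x
                if np.ptp(tt) < 1e-9:
                    return best * 10.0
                return oracle_rss_at(tt, values)

            res = minimize_scalar(
                f, bounds=(lower_bound, 3 * total), method="bounded",
                options={"xatol": 1e-12},
            )
            if res.fun < best:
                best, t[j] = float(res.fun), float(res.x)
        if prev - best < 1e-14 * max(best, 1e-300):
            break
    return best


def random_dataset(n: int, m: int, seed: int, sigma_t2: float = 0.1,
                   sigma_s2: float = 2.0):
    """A generic random validated dataset via the package's simulator."""
    from upmclock import SimulationParams, simulate_dataset

    params = SimulationParams(
        n_sites=n, n_individuals=m, sigma_t2=sigma_t2, sigma_s2=sigma_s2, seed=seed
    )
    return simulate_dataset(params).dataset
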