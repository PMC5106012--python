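"""Real-data analysis utilities: site selection and rate/age-ratio reports.

``select_top_variance_sites`` implements the usual pre-filter for array
data: keep the k sites whose methylation varies most across the cohort.
``rate_ratio_report`` compares per-site rates between the clock and
pacemaker fits (clock/pacemaker orientation); ``age_ratio_report`` compares
each individual's inferred epigenetic age to their chronological age
(pacemaker/chronological orientation) — a ratio below 1 is age
deceleration, above 1 acceleration.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .data import MCFit, MethylationDataset, UPMFit, ValidationError

__all__ = [
    "select_top_variance_sites",
    "rate_ratio_report",
    "age_ratio_report",
    "age_ratio_dispersion",
]


def select_top_variance_sites(ds: MethylationDataset, k: int = 300) -> MethylationDataset:
    """Keep the k sites with the largest across-individual sample variance.

    Variance uses divisor m−1; rows are returned in descending-variance
    order with ties broken by original site order.  Ages are preserved.
    """
    if not 1 <= k <= ds.n:
        raise ValidationError(f"k must lie in [1, {ds.n}], got {k}")
    variances = ds.values.var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")[:k]
    return ds.subset_sites(order.tolist())


def rate_ratio_report(
    mc: MCFit,
    upm: UPMFit,
    site_ids: list[str] | None = None,
    trim_fraction: float = 0.025,
) -> pd.DataFrame:
    """Per-site clock/pacemaker rate ratios, sorted ascending by ratio.

    Columns: site_id, mc_rate, upm_rate, ratio, same_sign, decelerating,
    extreme.  ``decelerating`` is ratio ≤ 1 among same-sign sites.  Sites
    with a zero pacemaker rate get a NaN ratio, are sorted last and are
    never flagged extreme.  The ``trim_fraction`` most extreme rows at each
    end are flagged (column ``extreme``) but not removed, so downstream
    plotting can drop them without losing the fitted values.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValidationError("trim_fraction must lie in [0, 0.5)")
    if mc.rates.shape != upm.rates.shape:
        raise ValidationError("fits have different site counts")
    n = mc.rates.shape[0]
    if site_ids is None:
        site_ids = [str(i) for i in range(n)]
    if len(site_ids) != n:
        raise ValidationError("site_ids length must match the fits")

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(upm.rates != 0.0, mc.rates / upm.rates, np.nan)
    same_sign = np.sign(mc.rates) == np.sign(upm.rates)
    decelerating = same_sign & (ratio <= 1.0)

    df = pd.DataFrame(
        {
            "site_id": site_ids,
            "mc_rate": mc.rates,
            "upm_rate": upm.rates,
            "ratio": ratio,
            "same_sign": same_sign,
            "decelerating": np.where(np.isnan(ratio), False, decelerating),
        }
    )
    df = df.sort_values("ratio", na_position="last", kind="stable").reset_index(
        drop=True
    )
    valid = df["ratio"].notna().to_numpy()
    n_valid = int(valid.sum())
    k = math.floor(trim_fraction * n_valid)
    extreme = np.zeros(len(df), dtype=bool)
    if k > 0:
        valid_pos = np.flatnonzero(valid)
        extreme[valid_pos[:k]] = True
        extreme[valid_pos[n_valid - k :]] = True
    df["extreme"] = extreme
    return df


def age_ratio_report(
    chronological: np.ndarray,
    upm: UPMFit,
    individual_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Epigenetic/chronological age ratios, sorted by ascending age.

    Expects a gauge-fixed fit (mean epigenetic age anchored to mean
    chronological age), so ratios scatter around 1 and a downward trend
    with age reads directly as age deceleration in older individuals.
    """
    ages = np.asarray(chronological, dtype=float)
    epi = np.asarray(upm.epigenetic_times, dtype=float)
    if ages.shape != epi.shape:
        raise ValidationError("age vector length must match the fit")
    if np.any(ages <= 0):
        raise ValidationError("chronological ages must be strictly positive")
    m = ages.shape[0]
    if individual_ids is None:
        individual_ids = [str(j) for j in range(m)]
    df = pd.DataFrame(
        {
            "individual_id": individual_ids,
            "age": ages,
            "epigenetic_age": epi,
            "ratio": epi / ages,
        }
    )
    return df.sort_values("age", kind="stable").reset_index(drop=True)


def age_ratio_dispersion(table: pd.DataFrame) -> dict[str, float]:
    """Variance of the age ratio in the youngest and oldest age terciles.

    Reported (not asserted) because it is a property of the dataset: on the
    published human cohort the spread is visibly larger among the young.
    """
    sorted_tab = table.sort_values("age", kind="stable")
    m = len(sorted_tab)
    third = max(m // 3, 1)
    young = sorted_tab["ratio"].iloc[:third]
    old = sorted_tab["ratio"].iloc[m - third :]
    return {
        "youngest_tercile_variance": float(young.var(ddof=1)) if third > 1 else float("nan"),
        "oldest_tercile_variance": float(old.var(ddof=1)) if third > 1 else float("nan"),
    }
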