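"""Data containers and delimited-text I/O for methylation aging analyses.

The central object is :class:`MethylationDataset`: an ``n × m`` matrix of
methylation levels (``n`` CpG sites in rows, ``m`` individuals in columns)
together with each individual's chronological age in years.  Fit results
(:class:`MCFit`, :class:`UPMFit`) and the model-comparison statistic
(:class:`LRTResult`) are plain dataclasses so they can be serialized with
:func:`write_table` and inspected interactively.

Conventions
-----------
* Sites are indexed by ``i`` (rows), individuals by ``j`` (columns).
* Ages are strictly positive: they appear as divisors in average-rate and
  age-ratio computations.
* Missing values are rejected at validation time — the models have no
  missing-data mechanism and silent imputation would bias the rate fits.
* Methylation levels are treated as unbounded reals.  Array beta values live
  in [0, 1], but both models (and the Gaussian noise they assume) are
  unbounded, so no clamping is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UpmClockError",
    "ParseError",
    "ValidationError",
    "InsufficientDataError",
    "SingularDesignError",
    "FitError",
    "MethylationDataset",
    "MCFit",
    "UPMFit",
    "LRTResult",
    "read_methylation_matrix",
    "read_ages",
    "attach_and_validate",
    "write_table",
]


class UpmClockError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(UpmClockError):
    """A delimited input file could not be parsed."""


class ValidationError(UpmClockError):
    """Input data violate a model precondition."""


class InsufficientDataError(ValidationError):
    """Too few sites or individuals for the requested fit."""


class SingularDesignError(ValidationError):
    """The regression design is singular (e.g. all ages identical)."""


class FitError(UpmClockError):
    """An optimization failed or produced an inconsistent result."""


@dataclass
class MethylationDataset:
    """Methylation matrix with row/column identifiers and optional ages.

    Parameters
    ----------
    site_ids
        ``n`` unique site labels (matrix rows).
    individual_ids
        ``m`` unique individual labels (matrix columns).
    values
        ``(n, m)`` float array of observed methylation levels ``ŝ_ij``.
    ages
        Optional length-``m`` vector of chronological ages ``t_j`` in years,
        aligned with ``individual_ids``.  Attach with
        :func:`attach_and_validate`.
    """

    site_ids: list[str]
    individual_ids: list[str]
    values: np.ndarray
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.individual_ids = [str(s) for s in self.individual_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"values must be a 2-D matrix, got ndim={self.values.ndim}"
            )
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)

    @property
    def n(self) -> int:
        """Number of sites (rows)."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of individuals (columns)."""
        return self.values.shape[1]

    def validate(self, require_ages: bool = True) -> "MethylationDataset":
        """Check all structural invariants; return ``self`` if they hold."""
        if len(self.site_ids) != self.n:
            raise ValidationError(
                f"{len(self.site_ids)} site ids for {self.n} matrix rows"
            )
        if len(self.individual_ids) != self.m:
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {self.m} columns"
            )
        if len(set(self.site_ids)) != self.n:
            raise ValidationError("site ids are not unique")
        if len(set(self.individual_ids)) != self.m:
            raise ValidationError("individual ids are not unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite methylation value at site "
                f"{self.site_ids[bad[0]]!r}, individual "
                f"{self.individual_ids[bad[1]]!r}"
            )
        if self.ages is None:
            if require_ages:
                raise ValidationError("ages are not attached")
            return self
        if self.ages.shape != (self.m,):
            raise ValidationError(
                f"ages vector has shape {self.ages.shape}, expected ({self.m},)"
            )
        if not np.all(np.isfinite(self.ages)) or np.any(self.ages <= 0):
            raise ValidationError("ages must be finite and strictly positive")
        return self

    def subset_sites(self, row_indices: Sequence[int]) -> "MethylationDataset":
        """Return a new dataset restricted to the given site rows."""
        idx = list(row_indices)
        return MethylationDataset(
            site_ids=[self.site_ids[i] for i in idx],
            individual_ids=list(self.individual_ids),
            values=self.values[idx, :].copy(),
            ages=None if self.ages is None else self.ages.copy(),
        )


@dataclass
class MCFit:
    """Molecular-clock fit: one linear trend per site, times held fixed.

    ``rates[i]`` is the characteristic rate r_i (methylation units per
    year), ``starts[i]`` the start level s_i0, ``residuals[i, j]`` equals
    ``ŝ_ij − r_i·t_j − s_i0``, and ``rss`` is the total residual sum of
    squares — the quantity whose minimum is the maximum-likelihood fit
    under iid Gaussian noise.
    """

    rates: np.ndarray
    starts: np.ndarray
    rss: float
    residuals: np.ndarray

    @property
    def site_rss(self) -> np.ndarray:
        """Per-site residual sums of squares (length n)."""
        return np.einsum("ij,ij->i", self.residuals, self.residuals)


@dataclass
class UPMFit:
    """Universal-pacemaker fit: site trends plus inferred epigenetic ages.

    ``epigenetic_times[j]`` is the inferred age t_j' of individual ``j``
    under the pacemaker; the gauge freedom (times × c, rates / c leaves the
    likelihood unchanged) is fixed by the convention named in
    ``normalization``.  ``converged_rss_per_start`` records the RSS reached
    from each random restart; ``rss`` is their minimum.
    """

    rates: np.ndarray
    starts: np.ndarray
    epigenetic_times: np.ndarray
    rss: float
    n_starts: int
    converged_rss_per_start: list[float] = field(default_factory=list)
    normalization: str = "none"


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of the clock (null) vs pacemaker model.

    ``chi2 = n·m·log(rss_mc / rss_upm)`` with ``df`` degrees of freedom
    (by default the number of individuals, i.e. the free epigenetic ages
    gained by the pacemaker model); ``log_lambda = −chi2 / 2``.
    """

    chi2: float
    df: int
    p_value: float | None
    rss_mc: float
    rss_upm: float
    log_lambda: float


def read_methylation_matrix(
    path, delimiter: str = "\t", transpose: bool = False
) -> MethylationDataset:
    """Read a delimited methylation matrix (ages not attached).

    The first row must hold individual IDs, the first column site IDs and
    all remaining cells numeric.  With ``transpose=True`` the file is read
    with roles swapped (individuals in rows) and transposed on load.

    Raises
    ------
    ParseError
        On ragged rows, missing cells or non-numeric cells; the error
        message names the offending row/column labels.
    """
    try:
        raw = pd.read_csv(
            path,
            sep=delimiter,
            index_col=0,
            dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed matrix file {path}: {exc}") from exc
    if raw.index.isna().any() or raw.isna().any().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise ParseError(
            f"ragged or incomplete row in {path}: missing value in row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        row_label, col_label = raw.index[r], raw.columns[c]
        site, indiv = (col_label, row_label) if transpose else (row_label, col_label)
        raise ParseError(
            f"non-numeric value {raw.iat[r, c]!r} at site {site!r}, "
            f"individual {indiv!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    rows = [str(x) for x in raw.index]
    cols = [str(x) for x in raw.columns]
    if transpose:
        return MethylationDataset(site_ids=cols, individual_ids=rows, values=values.T)
    return MethylationDataset(site_ids=rows, individual_ids=cols, values=values)


def read_ages(path, delimiter: str = "\t") -> dict[str, float]:
    """Read a headerless two-column (individual_id, age_in_years) file.

    Ages must parse as finite, strictly positive reals; duplicate ids are
    rejected.
    """
    ages: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            ident, raw_age = parts[0].strip(), parts[1].strip()
            try:
                age = float(raw_age)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric age {raw_age!r} for "
                    f"individual {ident!r}"
                ) from None
            if not np.isfinite(age) or age <= 0:
                raise ValidationError(
                    f"{path}:{lineno}: age must be finite and > 0, got "
                    f"{raw_age!r} for individual {ident!r}"
                )
            if ident in ages:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate individual id {ident!r}"
                )
            ages[ident] = age
    return ages


def attach_and_validate(
    ds: MethylationDataset, ages: Mapping[str, float]
) -> MethylationDataset:
    """Align an age map to the dataset's column order and validate.

    Every individual in the dataset must appear in ``ages``.  At least two
    sites and three individuals are required: the pacemaker model estimates
    one free time per individual, so smaller inputs are unidentifiable.
    """
    missing = [ident for ident in ds.individual_ids if ident not in ages]
    if missing:
        raise ValidationError(
            "no age provided for individual(s): " + ", ".join(map(repr, missing))
        )
    if ds.n < 2 or ds.m < 3:
        raise InsufficientDataError(
            f"insufficient data: need at least 2 sites and 3 individuals, "
            f"got n={ds.n}, m={ds.m}"
        )
    age_vec = np.array([float(ages[ident]) for ident in ds.individual_ids])
    out = replace(ds, ages=age_vec)
    return out.validate()


def _format_cell(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".12g")
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def write_table(
    rows: Sequence[Mapping],
    path,
    delimiter: str = "\t",
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write records as a delimited table with a header line.

    Floats are serialized with 12 significant digits so that a write/read
    round trip preserves values to better than 1e-10 relative.  All records
    must share one field set; ``fieldnames`` is required when ``rows`` is
    empty (a header-only file is written).
    """
    if fieldnames is None:
        if not rows:
            raise ValidationError("fieldnames are required for an empty table")
        fieldnames = list(rows[0].keys())
    fieldset = set(fieldnames)
    for k, rec in enumerate(rows):
        if set(rec.keys()) != fieldset:
            raise ValidationError(
                f"record {k} fields {sorted(rec.keys())} do not match header "
                f"{sorted(fieldset)}"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(fieldnames) + "\n")
        for rec in rows:
            fh.write(delimiter.join(_format_cell(rec[f]) for f in fieldnames) + "\n")
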