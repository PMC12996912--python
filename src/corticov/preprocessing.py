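"""Covariate removal: standardized thickness residuals and site harmonization.

Every downstream stage (effect maps, covariance networks, epicenter scans)
consumes the subjects-by-regions matrix of standardized residuals produced
here: per region, thickness is regressed on an intercept plus covariates by
ordinary least squares and the residuals are divided by their sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_io import CohortTable, ParcelAtlas


@dataclass
class ResidualMatrix:
    """Subjects-by-regions standardized residuals z and their provenance."""

    values: np.ndarray                    # (n_subjects, n_regions)
    subject_ids: tuple[str, ...]
    atlas: ParcelAtlas = field(repr=False)
    covariates_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("residuals contain non-finite values")
        if v.shape != (len(self.subject_ids), self.atlas.n_regions):
            raise ValueError("residual matrix shape inconsistent with metadata")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.atlas.region_names))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df


def design_matrix(table: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + covariates; categorical columns one-hot with first level dropped."""
    cols = [np.ones(len(table))]
    for cov in covariates:
        if cov not in table.columns:
            raise ValueError(f"covariate column {cov!r} missing")
        col = table[cov]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"covariate {cov!r} has missing/non-finite values")
            if np.ptp(vals) == 0:
                raise ValueError(f"covariate {cov!r} is constant")
            cols.append(vals)
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            if dummies.shape[1] == 0:
                raise ValueError(f"covariate {cov!r} is constant")
            cols.extend(dummies.to_numpy(dtype=float).T)
    return np.column_stack(cols)


def residualize(
    cohort: CohortTable,
    regions: list[str] | None = None,
    covariates: list[str] = ("age", "sex"),
    subset: pd.Series | np.ndarray | None = None,
) -> ResidualMatrix:
    """OLS-residualize thickness on covariates, region by region, and z-scale.

    Parameters
    ----------
    regions
        Region names to include (default: all atlas regions, atlas order).
    covariates
        Covariate column names; the fit always includes an intercept.
    subset
        Optional boolean mask restricting the fitting sample (e.g. patients
        only); the default fits jointly across all rows.

    Residual columns have mean 0 (intercept in the fit) and SD 1 (ddof=1
    scaling); zero residual variance in any region is an error — it signals a
    degenerate input where thickness is an exact function of the covariates.
    """
    table = cohort.table
    if subset is not None:
        table = table.loc[np.asarray(subset, dtype=bool)].reset_index(drop=True)
    covariates = list(covariates)
    if regions is None:
        regions = list(cohort.atlas.region_names)
    else:
        unknown = [r for r in regions if r not in cohort.atlas.region_names]
        if unknown:
            raise ValueError(f"unknown regions: {unknown}")

    x = design_matrix(table, covariates)
    n, k = x.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} subjects for {k - 1}+ covariates, got {n}")

    y = table[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sd = resid.std(axis=0, ddof=1)
    dead = [regions[j] for j in np.nonzero(sd < 1e-12)[0]]
    if dead:
        raise ValueError(f"zero residual variance in regions {dead}")
    return ResidualMatrix(
        values=resid / sd,
        subject_ids=tuple(table["subject_id"].astype(str)),
        atlas=cohort.atlas,
        covariates_used=tuple(covariates),
    )


def harmonize_site(cohort: CohortTable, site_column: str = "site") -> CohortTable:
    """Per-site location-scale standardization of thickness columns.

    A deliberately simple stand-in for empirical-Bayes batch harmonization:
    within each site, thickness is centered and scaled per region, then the
    grand mean and pooled SD are restored so the output stays on the mm scale.
    With a single site the operation is the identity (within rounding).
    """
    table = cohort.table.copy()
    if site_column not in table.columns:
        raise ValueError(f"site column {site_column!r} missing")
    sites = table[site_column]
    counts = sites.value_counts()
    if (counts < 2).any():
        singles = sorted(counts[counts < 2].index)
        raise ValueError(f"singleton site(s): {singles}")

    regions = list(cohort.atlas.region_names)
    thick = table[regions].to_numpy(dtype=float)
    grand_mean = thick.mean(axis=0)
    pooled_sd = thick.std(axis=0, ddof=1)

    out = np.empty_like(thick)
    for s in counts.index:
        mask = (sites == s).to_numpy()
        block = thick[mask]
        sd = block.std(axis=0, ddof=1)
        if np.any(sd < 1e-12):
            raise ValueError(f"zero within-site SD at site {s!r}")
        out[mask] = (block - block.mean(axis=0)) / sd
    out = out * pooled_sd + grand_mean
    table[regions] = out
    return CohortTable(table=table, atlas=cohort.atlas)
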