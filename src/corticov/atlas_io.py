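"""Reading and writing atlases, connectomes and cohort tables.

All artifacts in a run share a single region ordering — the file order of the
atlas.  Every downstream vector or matrix is indexed by that order; readers
reorder labelled inputs to it and refuse inputs whose labels do not match.

Tables are UTF-8 delimited text with a header row.  The delimiter is inferred
from the file extension: ``.csv`` → comma, ``.tsv`` → tab.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("corticov")

#: Covariate / clinical columns expected in a cohort table, in canonical order.
COHORT_META_COLUMNS = (
    "subject_id",
    "diagnosis",
    "age",
    "sex",
    "site",
    "dose",
    "sans_avolition_apathy",
    "sans_anhedonia_asociality",
    "sans_alogia",
    "sans_blunted_affect",
    "saps_delusion",
    "saps_hallucination",
    "saps_bizarre_behavior",
    "saps_formal_thought",
    "hamd",
)

SANS_COLUMNS = (
    "sans_avolition_apathy",
    "sans_anhedonia_asociality",
    "sans_alogia",
    "sans_blunted_affect",
)
SAPS_COLUMNS = (
    "saps_delusion",
    "saps_hallucination",
    "saps_bizarre_behavior",
    "saps_formal_thought",
)


def _delimiter(path: Path | str) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


@dataclass(frozen=True)
class ParcelAtlas:
    """A cortical parcellation: named regions with unit-sphere centroids.

    Regions are indexed 0-based in file order.  Both hemispheres must carry
    the same number of regions; centroids are unit vectors so that geodesic
    distances and sphere rotations (the spin test) are well defined.
    """

    region_names: tuple[str, ...]
    hemispheres: tuple[str, ...]          # "L" or "R" per region
    centroids: np.ndarray                 # (n_regions, 3), unit norm

    def __post_init__(self) -> None:
        names = self.region_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        if len(names) < 4 or len(names) % 2:
            raise ValueError("atlas needs an even region count >= 4")
        hemi = np.asarray(self.hemispheres)
        if set(hemi) - {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        if (hemi == "L").sum() != (hemi == "R").sum():
            raise ValueError("unequal region counts per hemisphere")
        c = np.asarray(self.centroids, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite centroid coordinates")
        norms = np.linalg.norm(c, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("centroids must lie on the unit sphere")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def hemisphere_mask(self, hemi: str) -> np.ndarray:
        return np.asarray(self.hemispheres) == hemi

    def index_of(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise KeyError(f"region {name!r} not in atlas") from None


@dataclass(frozen=True)
class Connectome:
    """Square region-by-region connectivity matrix in atlas order."""

    weights: np.ndarray
    modality: str                         # "functional" | "structural"
    atlas: ParcelAtlas = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = self.atlas.n_regions
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != atlas size ({n}, {n})")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome contains non-finite entries")
        if np.max(np.abs(w - w.T)) > 1e-9:
            raise ValueError("connectome not symmetric")
        if np.max(np.abs(np.diag(w))) > 1e-12:
            raise ValueError("connectome diagonal must be zero")
        if self.modality == "structural" and np.min(w) < 0:
            raise ValueError("structural weights must be non-negative")
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class CohortTable:
    """Subjects-by-(covariates + thickness + symptoms) table plus its atlas.

    One row per subject.  Thickness columns are named after atlas regions and
    appear in atlas order; missing symptom cells stay missing (NaN), they are
    never imputed.
    """

    table: pd.DataFrame
    atlas: ParcelAtlas

    def __post_init__(self) -> None:
        missing = [r for r in self.atlas.region_names if r not in self.table.columns]
        if missing:
            raise ValueError(f"thickness columns missing for regions: {missing}")
        thick = self.thickness()
        if not np.all(np.isfinite(thick)) or np.any(thick <= 0):
            raise ValueError("thickness must be finite and strictly positive")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id rows")
        for col in SANS_COLUMNS + SAPS_COLUMNS:
            if col in self.table.columns:
                v = self.table[col].dropna()
                if len(v) and ((v < 0) | (v > 5)).any():
                    raise ValueError(f"{col} outside ordinal range 0-5")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def thickness(self) -> np.ndarray:
        """(n_subjects, n_regions) thickness matrix in atlas order."""
        return self.table[list(self.atlas.region_names)].to_numpy(dtype=float)


# ---------------------------------------------------------------- atlas I/O

def read_atlas(path: str | Path) -> ParcelAtlas:
    """Read an atlas table (region_name, hemisphere, x, y, z).

    Centroids are renormalized to unit length; region order is file order.
    """
    df = pd.read_csv(path, sep=_delimiter(path))
    required = {"region_name", "hemisphere", "x", "y", "z"}
    if missing := required - set(df.columns):
        raise ValueError(f"atlas file missing columns: {sorted(missing)}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite centroid coordinates in atlas file")
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length centroid in atlas file")
    coords = coords / norms[:, None]
    return ParcelAtlas(
        region_names=tuple(df["region_name"].astype(str)),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        centroids=coords,
    )


def write_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_name": atlas.region_names,
            "hemisphere": atlas.hemispheres,
            "x": atlas.centroids[:, 0],
            "y": atlas.centroids[:, 1],
            "z": atlas.centroids[:, 2],
        }
    )
    df.to_csv(path, sep=_delimiter(path), index=False, float_format="%.17g")


# ----------------------------------------------------------- connectome I/O

def read_connectome(
    path: str | Path, atlas: ParcelAtlas, modality: str = "functional"
) -> Connectome:
    """Read a labelled square connectivity matrix and align it to the atlas.

    Rows/columns are reordered to atlas order.  Small asymmetries (numeric
    round-trip noise) are averaged away; asymmetry beyond 1e-6 is still
    averaged but logged as a warning.
    """
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    names = list(atlas.region_names)
    extra = sorted(set(df.index) - set(names)) + sorted(set(df.columns) - set(names))
    missing = [n for n in names if n not in df.index or n not in df.columns]
    if extra or missing:
        raise ValueError(
            f"connectome labels do not match atlas (missing={missing}, extra={extra})"
        )
    w = df.loc[names, names].to_numpy(dtype=float)
    asym = np.max(np.abs(w - w.T)) if w.size else 0.0
    if asym > 1e-6:
        logger.warning("connectome %s asymmetric by %.3g; symmetrizing", path, asym)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return Connectome(weights=w, modality=modality, atlas=atlas)


def write_connectome(conn: Connectome, path: str | Path) -> None:
    names = list(conn.atlas.region_names)
    pd.DataFrame(conn.weights, index=names, columns=names).to_csv(
        path, sep=_delimiter(path), float_format="%.17g"
    )


# --------------------------------------------------------------- cohort I/O

def read_cohort(path: str | Path, atlas: ParcelAtlas) -> CohortTable:
    """Read a subject table; thickness columns are matched to atlas regions."""
    df = pd.read_csv(path, sep=_delimiter(path))
    unmatched = [r for r in atlas.region_names if r not in df.columns]
    if unmatched:
        raise ValueError(f"cohort file lacks thickness columns: {unmatched}")
    return CohortTable(table=df, atlas=atlas)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    meta = [c for c in COHORT_META_COLUMNS if c in cohort.table.columns]
    extra = [
        c
        for c in cohort.table.columns
        if c not in meta and c not in cohort.atlas.region_names
    ]
    cols = meta + extra + list(cohort.atlas.region_names)
    cohort.table[cols].to_csv(path, sep=_delimiter(path), index=False, float_format="%.17g")
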