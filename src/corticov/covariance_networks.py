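"""Intra-individual structural covariance networks and their spatial alignment.

For one subject with standardized residuals z, the morphological similarity
of regions i and j is the bounded kernel C(i,j) = exp(-(z_i - z_j)^2): 1 for
identical residuals, decaying smoothly toward 0 as residuals diverge.
Per-subject matrices are averaged into group-mean covariance networks; the
profile of a seed region, C_bar(seed, .), is then spatially correlated with a
symptom effect map, with significance from the spin-permutation null.

A single group-mean thickness profile (meta-analytic style input) is handled
by the same kernel applied to one "subject".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_stats import spearman
from .atlas_io import ParcelAtlas
from .effect_maps import EffectMap
from .preprocessing import ResidualMatrix
from .spatial_null import SpinEnsemble, make_spins, spin_test

VALID_KERNELS = ("exp_sq", "inv_sq_eps")


@dataclass(frozen=True)
class CovarianceMatrix:
    """Region-by-region similarity matrix; entries in (0, 1], unit diagonal."""

    values: np.ndarray
    owner: str                            # subject_id or "group-mean-profile"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("covariance matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("covariance matrix not symmetric")
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise ValueError("covariance entries must lie in (0, 1]")
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-12:
            raise ValueError("covariance diagonal must be 1")


@dataclass(frozen=True)
class CovarianceNetwork:
    """Mean covariance profile of one seed region across subjects."""

    seed: int
    profile: np.ndarray                   # C_bar(seed, .), self entry = 1
    n_subjects: int
    atlas: ParcelAtlas = field(repr=False)


def _kernel(delta: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "exp_sq":
        # floor at the smallest positive double: exp underflows to exactly 0
        # for |delta| > ~27, which would break the documented (0, 1] range
        return np.maximum(np.exp(-(delta**2)), np.finfo(float).tiny)
    if kernel == "inv_sq_eps":
        return 1.0 / (1.0 + delta**2)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {VALID_KERNELS}")


def intra_covariance(z, owner: str = "subject", kernel: str = "exp_sq") -> CovarianceMatrix:
    """Single-subject covariance matrix from a residual vector.

    ``exp_sq`` (default) is exp(-(z_i - z_j)^2); ``inv_sq_eps`` is the
    regularized reciprocal 1/(1 + (z_i - z_j)^2).  Both are strictly
    decreasing in |z_i - z_j| with range (0, 1], so for a single subject (or
    a single group-mean profile) they induce identical rank orderings and
    rank-based downstream statistics agree exactly.  After averaging across
    subjects the equivalence is only approximate (the kernels average
    differently), which is why the kernel is a configuration option.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("z must be a 1-D residual vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite residuals")
    c = _kernel(z[:, None] - z[None, :], kernel)
    return CovarianceMatrix(values=c, owner=owner)


def mean_covariance(
    residuals: ResidualMatrix | np.ndarray, kernel: str = "exp_sq"
) -> CovarianceMatrix:
    """Element-wise mean of per-subject covariance matrices.

    Accepts a ResidualMatrix (subjects x regions), a 2-D array of the same
    shape, or a single 1-D profile vector (group-mean thickness style), in
    which case the "mean" over one subject is that subject's matrix.
    """
    if isinstance(residuals, ResidualMatrix):
        z = residuals.values
    else:
        z = np.asarray(residuals, dtype=float)
    if z.ndim == 1:
        return intra_covariance(z, owner="group-mean-profile", kernel=kernel)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ValueError("need at least one subject")
    acc = np.zeros((z.shape[1], z.shape[1]))
    for row in z:
        acc += intra_covariance(row, kernel=kernel).values
    return CovarianceMatrix(values=acc / z.shape[0], owner="group-mean")


def covariance_network(
    residuals: ResidualMatrix | np.ndarray,
    seed: int,
    atlas: ParcelAtlas,
    kernel: str = "exp_sq",
) -> CovarianceNetwork:
    """Mean covariance profile of one seed region."""
    mean = mean_covariance(residuals, kernel=kernel)
    n_sub = residuals.n_subjects if isinstance(residuals, ResidualMatrix) else (
        1 if np.ndim(residuals) == 1 else np.shape(residuals)[0]
    )
    if not 0 <= seed < atlas.n_regions:
        raise ValueError(f"seed {seed} not in atlas")
    return CovarianceNetwork(
        seed=seed, profile=mean.values[seed].copy(), n_subjects=n_sub, atlas=atlas
    )


def network_alignment(
    network: CovarianceNetwork,
    effect: EffectMap,
    atlas: ParcelAtlas,
    n_rot: int = 1000,
    rng_seed: int = 0,
    spins: SpinEnsemble | None = None,
    include_seed: bool = False,
    tail: str = "two-sided",
) -> tuple[float, float]:
    """Spearman alignment of a seed's covariance profile with an effect map.

    The seed's self-entry (fixed at 1, mechanically coupled to its own effect
    size) is excluded from both vectors by default; ``include_seed=True``
    keeps it.  Significance comes from rotating the effect map against the
    fixed profile (spin test).  Returns (rs, p_spin).
    """
    if network.atlas is not atlas and network.atlas.region_names != atlas.region_names:
        raise ValueError("network and atlas disagree")
    if effect.atlas.region_names != atlas.region_names:
        raise ValueError("effect map and atlas disagree")
    if spins is None:
        spins = make_spins(atlas, n_rot=n_rot, rng_seed=rng_seed)
    exclude = None if include_seed else {network.seed}
    rs, p_spin, _ = spin_test(
        effect.coefficients, network.profile, spins, method="spearman",
        exclude=exclude, tail=tail,
    )
    return rs, p_spin


def rank_networks(
    residuals: ResidualMatrix,
    effect: EffectMap,
    atlas: ParcelAtlas,
    n_rot: int = 1000,
    rng_seed: int = 0,
    spins: SpinEnsemble | None = None,
    kernel: str = "exp_sq",
    include_seed: bool = False,
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Alignment of every region's covariance network with an effect map.

    Returns one row per seed region (seed, region_name, rs, p_spin, rank)
    sorted by descending |rs|, ties broken by region index.
    """
    if spins is None:
        spins = make_spins(atlas, n_rot=n_rot, rng_seed=rng_seed)
    mean = mean_covariance(residuals, kernel=kernel)
    rows = []
    for seed in range(atlas.n_regions):
        net = CovarianceNetwork(
            seed=seed, profile=mean.values[seed], n_subjects=residuals.n_subjects,
            atlas=atlas,
        )
        rs, p_spin = network_alignment(
            net, effect, atlas, spins=spins, include_seed=include_seed, tail=tail
        )
        rows.append((seed, atlas.region_names[seed], rs, p_spin))
    df = pd.DataFrame(rows, columns=["seed", "region_name", "rs", "p_spin"])
    df = df.sort_values(
        by=["rs", "seed"], key=lambda s: -s.abs() if s.name == "rs" else s
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
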