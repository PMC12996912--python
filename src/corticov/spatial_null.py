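"""Spin-permutation spatial null for parcellated cortical maps.

Correlations between two brain maps are inflated by spatial autocorrelation:
neighbouring parcels are not independent samples.  The spin test builds a
null distribution by randomly rotating one map's parcel positions on the
sphere — preserving its spatial covariance structure — and re-assigning each
parcel the value of the nearest rotated parcel (centroid variant; many-to-one
assignments are accepted, as is common practice with parcel centroids).

Rotations are drawn uniformly from SO(3) for the left hemisphere and applied
to the right hemisphere as the mirrored rotation F R F with F = diag(-1,1,1),
so homologous parcels rotate to homologous places and hemisphere blocks are
never mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas_io import ParcelAtlas

logger = logging.getLogger("corticov")

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class SpinEnsemble:
    """n_rot spin permutations of an atlas (source index per target parcel)."""

    permutations: np.ndarray              # (n_rot, n_regions) int
    rng_seed: int
    atlas: ParcelAtlas = field(repr=False)

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutations)
        n = self.atlas.n_regions
        if perm.ndim != 2 or perm.shape[1] != n:
            raise ValueError("permutation array shape inconsistent with atlas")
        if perm.min() < 0 or perm.max() >= n:
            raise ValueError("permutation entries out of range")
        hemi = np.asarray(self.atlas.hemispheres)
        if np.any(hemi[perm] != hemi[None, :]):
            raise ValueError("spin permutations mix hemispheres")

    @property
    def n_rot(self) -> int:
        return self.permutations.shape[0]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation from SO(3) via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))           # make the decomposition unique
    if np.linalg.det(q) < 0:              # reflect into the rotation group
        q[:, 2] = -q[:, 2]
    return q


def make_spins(atlas: ParcelAtlas, n_rot: int = 1000, rng_seed: int = 0) -> SpinEnsemble:
    """Draw a seeded ensemble of spin permutations for an atlas.

    Per rotation, each target parcel is reassigned the source parcel (same
    hemisphere) whose rotated centroid has the greatest dot product with the
    target centroid.
    """
    if n_rot < 1:
        raise ValueError("n_rot must be >= 1")
    if n_rot < 100:
        logger.warning("n_rot=%d is low for stable spin p-values (< 100)", n_rot)
    rng = np.random.default_rng(rng_seed)
    c = atlas.centroids
    left = atlas.hemisphere_mask("L")
    right = ~left
    idx_l = np.nonzero(left)[0]
    idx_r = np.nonzero(right)[0]

    perms = np.empty((n_rot, atlas.n_regions), dtype=np.intp)
    for k in range(n_rot):
        rot_l = random_rotation(rng)
        rot_r = _MIRROR @ rot_l @ _MIRROR
        for idx, rot in ((idx_l, rot_l), (idx_r, rot_r)):
            rotated = c[idx] @ rot.T
            sim = rotated @ c[idx].T          # (source, target) dot products
            perms[k, idx] = idx[np.argmax(sim, axis=0)]
    return SpinEnsemble(permutations=perms, rng_seed=int(rng_seed), atlas=atlas)


def _prep_map(m, n: int, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n,):
        raise ValueError(f"{name} must be a length-{n} vector")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"{name} contains non-finite values")
    return m


def spin_test(
    map_a,
    map_b,
    spins: SpinEnsemble,
    method: str = "spearman",
    exclude: set[int] | None = None,
    tail: str = "two-sided",
) -> tuple[float, float, np.ndarray]:
    """Spatial correlation of two parcel maps with spin-permutation p-value.

    ``map_a`` is the map being rotated (by convention the symptom/effect
    map); ``map_b`` stays fixed.  ``exclude`` drops a region set from both
    vectors — after permuting map_a, so excluded positions still receive
    rotated values from elsewhere.  Returns (r_obs, p_spin, null_r).

    p_spin = (1 + #{null at least as extreme}) / (1 + n_rot); the smallest
    attainable value is therefore 1/(n_rot + 1).
    """
    n = spins.atlas.n_regions
    a = _prep_map(map_a, n, "map_a")
    b = _prep_map(map_b, n, "map_b")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")

    keep = np.ones(n, dtype=bool)
    if exclude:
        keep[list(exclude)] = False
    if keep.sum() < 3:
        raise ValueError("too few regions left after exclusion")
    if np.ptp(a[keep]) == 0 or np.ptp(b[keep]) == 0:
        raise ValueError("constant map: correlation undefined")

    null_a = a[spins.permutations][:, keep]        # (n_rot, kept)
    obs_a = a[keep][None, :]
    b_kept = b[keep][None, :]
    if method == "spearman":
        null_a = stats.rankdata(null_a, axis=1)
        obs_a = stats.rankdata(obs_a, axis=1)
        b_kept = stats.rankdata(b_kept, axis=1)

    def _corr(rows: np.ndarray, fixed: np.ndarray) -> np.ndarray:
        rows = rows - rows.mean(axis=1, keepdims=True)
        fixed = fixed - fixed.mean(axis=1, keepdims=True)
        den = np.sqrt((rows**2).sum(axis=1) * (fixed**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            return (rows * fixed).sum(axis=1) / den

    r_obs = float(_corr(obs_a, b_kept)[0])
    null_r = _corr(null_a, b_kept)
    null_r = np.where(np.isfinite(null_r), null_r, 0.0)   # constant rotated map -> r := 0

    if tail == "two-sided":
        extreme = np.abs(null_r) >= abs(r_obs) - 1e-12
    elif tail == "greater":
        extreme = null_r >= r_obs - 1e-12
    else:
        extreme = null_r <= r_obs + 1e-12
    p = (1.0 + int(extreme.sum())) / (1.0 + spins.n_rot)
    return r_obs, float(p), null_r
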