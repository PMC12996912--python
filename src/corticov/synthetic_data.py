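"""Synthetic atlases, connectomes and cohorts with planted ground truth.

The generator emulates the structure of a two-disorder cortical-thickness
study: 68 parcellated regions (34 per hemisphere), distance-decay normative
connectomes, and subjects whose thickness residuals carry inter-regional
covariance plus a planted symptom effect.  The planted effect follows a
connectome-spreading model: an epicenter region's connectivity profile sets
per-region alteration weights, and a continuous amotivation propensity is a
noisy negative projection of each subject's latent residuals onto those
weights.  Ordinal 0-5 scale scores are obtained by quantile thresholding, so
rank-based statistics can recover the plant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_io import CohortTable, Connectome, ParcelAtlas

#: Standard 34 cortical region names per hemisphere (Desikan-Killiany style),
#: used whenever a 34-per-hemisphere atlas is generated so that the pipeline's
#: default orbitofrontal ROI names resolve.
DK_REGION_NAMES = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# Mean adult cortical thickness is ~2.5 mm, age-related thinning on the order
# of 0.01 mm/year in mid-adulthood, and small sex differences; these set the
# covariate structure that residualization must remove.
BASELINE_THICKNESS_MM = 2.5
BETA_AGE_MM_PER_YEAR = -0.01
BETA_SEX_MM = 0.05
REGIONAL_SD_MM = 0.12
AGE_RANGE_YEARS = (21.0, 50.0)


@dataclass(frozen=True)
class GroundTruth:
    """Bookkeeping for the planted effect in a simulated cohort."""

    epicenter_region: int
    gamma: float
    per_region_target_r: np.ndarray   # intended Spearman(thickness residual, amotivation)
    rng_seed: int

    def to_json(self, path: str | Path, atlas: ParcelAtlas | None = None) -> None:
        payload = {
            "epicenter_region": int(self.epicenter_region),
            "gamma": float(self.gamma),
            "per_region_target_r": [float(v) for v in self.per_region_target_r],
            "rng_seed": int(self.rng_seed),
        }
        if atlas is not None:
            payload["epicenter_name"] = atlas.region_names[self.epicenter_region]
        Path(path).write_text(json.dumps(payload, indent=2))


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the x<0 half of the unit sphere."""
    k = np.arange(n)
    x = -(k + 0.5) / n                       # polar coordinate along -x, in (-1, 0)
    r = np.sqrt(1.0 - x**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def make_atlas(n_per_hemisphere: int = 34, rng_seed: int = 0) -> ParcelAtlas:
    """Generate a mirrored two-hemisphere atlas on the unit sphere.

    Left-hemisphere centroids are a Fibonacci lattice restricted to x<0 with a
    small seeded jitter; right-hemisphere centroids are their mirror images
    through the x=0 plane, so mirrored spin rotations are exercised exactly.
    """
    if n_per_hemisphere < 2:
        raise ValueError("n_per_hemisphere must be >= 2")
    rng = np.random.default_rng(rng_seed)
    left = _fibonacci_hemisphere(n_per_hemisphere)
    left = left + 0.02 * rng.standard_normal(left.shape)
    left[:, 0] = -np.abs(left[:, 0]).clip(min=1e-3)   # stay strictly in x<0
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = left * np.array([-1.0, 1.0, 1.0])

    if n_per_hemisphere == len(DK_REGION_NAMES):
        base = DK_REGION_NAMES
    else:
        base = tuple(f"region{i:03d}" for i in range(n_per_hemisphere))
    names = tuple(f"lh_{b}" for b in base) + tuple(f"rh_{b}" for b in base)
    hemis = ("L",) * n_per_hemisphere + ("R",) * n_per_hemisphere
    return ParcelAtlas(
        region_names=names,
        hemispheres=hemis,
        centroids=np.vstack([left, right]),
    )


def simulate_connectome(
    atlas: ParcelAtlas,
    decay_length: float = 0.75,
    noise_sd: float = 0.05,
    rng_seed: int = 0,
    modality: str = "functional",
) -> Connectome:
    """Distance-decay connectome: w_ij = exp(-d_ij / lambda) + symmetric noise.

    d_ij is the geodesic (great-circle) angle between centroids in radians.
    Weights are clipped at zero, symmetrized and the diagonal zeroed, matching
    the shape of normative functional/structural connectivity matrices.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be > 0")
    rng = np.random.default_rng(rng_seed)
    c = atlas.centroids
    d = np.arccos(np.clip(c @ c.T, -1.0, 1.0))
    w = np.exp(-d / decay_length)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=w.shape)
        w = w + (eps + eps.T) / 2.0
    w = np.clip(w, 0.0, None)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return Connectome(weights=w, modality=modality, atlas=atlas)


def latent_correlation(connectome: Connectome, coupling: float = 0.6) -> np.ndarray:
    """Positive-definite inter-regional correlation matrix shaped by a connectome.

    Sigma = I + coupling * W / rho(W) with W the (zero-diagonal) weights and
    rho the spectral radius; coupling < 1 guarantees positive definiteness and
    the unit diagonal makes Sigma a correlation matrix.
    """
    if not 0 <= coupling < 1:
        raise ValueError("coupling must be in [0, 1)")
    w = connectome.weights
    rho = np.max(np.abs(np.linalg.eigvalsh(w)))
    return np.eye(w.shape[0]) + (coupling / rho) * w


def alteration_weights(connectome: Connectome, epicenter_region: int) -> np.ndarray:
    """Unit-norm alteration profile: the epicenter's connectivity row, with the
    undefined self-connection set to the row's maximum so the epicenter itself
    is maximally (but not uniquely) loaded."""
    n = connectome.atlas.n_regions
    if not 0 <= epicenter_region < n:
        raise ValueError(f"epicenter_region {epicenter_region} not in atlas (n={n})")
    a = connectome.weights[epicenter_region].copy()
    a[epicenter_region] = a.max()
    return a / np.linalg.norm(a)


def _quantile_ordinal(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Map a continuous vector to ordinal {0..n_levels-1} by rank quantiles.

    Equal-count bins on mid-ranks: preserves the weak ordering of ``values``
    exactly (up to ties created by binning)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(values))
    return np.floor(ranks * n_levels / len(values)).astype(int)


def simulate_network_load(
    atlas: ParcelAtlas,
    seed_region: int,
    n_subjects: int = 200,
    hub_r: float = 0.5,
    n_partners: int = 45,
    noise_sd: float = 0.2,
    rng_seed: int = 0,
):
    """Residuals plus a symptom whose load follows one seed's covariance network.

    The seed region acts as the hub of a distributed latent network: a random
    scattered set of ``n_partners`` regions shares the seed's latent factor
    with coupling ``hub_r`` (z_p = r f + sqrt(1-r^2) eps), remaining regions
    are independent.  The symptom is the negative projection of each
    subject's residuals onto the seed's empirical mean-covariance profile,
    plus Gaussian noise — i.e. symptom load on a region is proportional to
    how strongly that region covaries with the seed.

    A hub-and-spokes world is used deliberately: when latent correlation is a
    smooth function of distance, the covariance profiles of neighbouring
    seeds are statistically indistinguishable over 68 parcels and no method
    can single out the planted seed; a seed with a distinctive distributed
    network is the identifiable (and scientifically interesting) case.

    Returns ``(residuals, symptom, partner_indices)`` with ``residuals`` a
    :class:`~corticov.preprocessing.ResidualMatrix`.
    """
    from .preprocessing import ResidualMatrix  # deferred: avoid import cycle
    from .covariance_networks import mean_covariance

    n_regions = atlas.n_regions
    if not 0 <= seed_region < n_regions:
        raise ValueError("seed_region not in atlas")
    if not 0 < hub_r < 1:
        raise ValueError("hub_r must be in (0, 1)")
    if not 1 <= n_partners <= n_regions - 1:
        raise ValueError("n_partners out of range")
    rng = np.random.default_rng(rng_seed)
    partners = rng.choice(
        [i for i in range(n_regions) if i != seed_region], n_partners, replace=False
    )
    f = rng.standard_normal(n_subjects)
    z = rng.standard_normal((n_subjects, n_regions))
    z[:, seed_region] = f
    z[:, partners] = hub_r * f[:, None] + np.sqrt(1 - hub_r**2) * z[:, partners]
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    residuals = ResidualMatrix(
        values=z,
        subject_ids=tuple(f"sub-{i:04d}" for i in range(n_subjects)),
        atlas=atlas,
    )
    profile = mean_covariance(residuals).values[seed_region]
    symptom = -(z @ profile)
    symptom = symptom / symptom.std(ddof=1) + noise_sd * rng.standard_normal(n_subjects)
    return residuals, symptom, np.sort(partners)


def target_spearman(
    sigma: np.ndarray, a: np.ndarray, gamma: float, sigma_noise: float
) -> np.ndarray:
    """Analytic per-region Spearman between latent residuals and the propensity.

    For jointly Gaussian (z_r, m) with m = -gamma <a, z> + noise the Pearson
    correlation is -gamma (Sigma a)_r / sqrt(gamma^2 a'Sigma a + sigma^2);
    the population Spearman of a bivariate Gaussian is (6/pi) asin(r/2).
    """
    var_m = gamma**2 * float(a @ sigma @ a) + sigma_noise**2
    if var_m == 0:
        return np.zeros(len(a))
    r = -gamma * (sigma @ a) / np.sqrt(var_m)
    return (6.0 / np.pi) * np.arcsin(r / 2.0)


def simulate_cohort(
    atlas: ParcelAtlas,
    connectome: Connectome,
    n_per_group: int = 49,
    epicenter_region: int | None = None,
    gamma: float = 1.5,
    sigma_noise: float = 1.0,
    site_effects: dict[str, tuple[float, float]] | None = None,
    rng_seed: int = 0,
    coupling: float = 0.6,
    dose_lateral_r: float = 0.0,
) -> tuple[CohortTable, GroundTruth]:
    """Simulate a two-disorder cohort with a planted amotivation effect.

    Parameters
    ----------
    n_per_group
        Subjects per diagnostic arm (SCZ, BD); default mirrors the 49/49 arms
        of the study design this generator emulates.
    epicenter_region
        Region whose connectivity profile shapes the alteration map; defaults
        to the right rostral anterior cingulate when present, else region 0.
    gamma
        Effect weight coupling latent residuals to the amotivation propensity.
        gamma=0 is the global null.
    sigma_noise
        SD of the propensity noise (latent residuals have unit variance).
    site_effects
        Mapping site -> (additive shift mm, multiplicative scale); default is
        a single site with no effect.
    dose_lateral_r
        Optional planted correlation between antipsychotic dose and the left
        lateral seed region's residual (0 = dose independent of thickness).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if n_per_group < 10:
        raise ValueError("n_per_group must be >= 10")
    if epicenter_region is None:
        try:
            epicenter_region = atlas.index_of("rh_rostralanteriorcingulate")
        except KeyError:
            epicenter_region = 0

    rng = np.random.default_rng(rng_seed)
    n_regions = atlas.n_regions
    n = 2 * n_per_group

    sigma = latent_correlation(connectome, coupling=coupling)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, n_regions)) @ chol.T

    a = alteration_weights(connectome, epicenter_region)
    propensity = -gamma * (z @ a) + sigma_noise * rng.standard_normal(n)

    # Amotivation: two SANS globals whose sum preserves the propensity's rank
    # order.  Total in 0..10 via 11 quantile levels, split across the globals.
    amot_total = _quantile_ordinal(propensity, 11)
    avolition = np.ceil(amot_total / 2).astype(int)
    anhedonia = amot_total - avolition

    # Diminished expression: independent propensity (no planted thickness link).
    dimexp_total = _quantile_ordinal(rng.standard_normal(n), 11)
    alogia = np.ceil(dimexp_total / 2).astype(int)
    blunted = dimexp_total - alogia

    diagnosis = np.array(["SCZ"] * n_per_group + ["BD"] * n_per_group)
    age = rng.uniform(*AGE_RANGE_YEARS, size=n)
    sex = rng.integers(0, 2, size=n)

    if site_effects is None:
        site_effects = {"site1": (0.0, 1.0)}
    sites = np.array(sorted(site_effects))
    site = sites[rng.integers(0, len(sites), size=n)]
    shift = np.array([site_effects[s][0] for s in site])
    scale = np.array([site_effects[s][1] for s in site])

    baseline = BASELINE_THICKNESS_MM + 0.15 * rng.standard_normal(n_regions)
    thickness = (
        baseline[None, :]
        + BETA_AGE_MM_PER_YEAR * age[:, None]
        + BETA_SEX_MM * sex[:, None]
        + REGIONAL_SD_MM * z
    )
    thickness = thickness * scale[:, None] + shift[:, None]
    if np.any(thickness <= 0):          # pragma: no cover - defensive
        raise RuntimeError("simulated thickness non-positive; check site scales")

    # Dose: log-normal mg/day, independent of thickness unless a lateral-seed
    # association is requested.
    dose_noise = rng.standard_normal(n)
    if dose_lateral_r != 0.0:
        try:
            lat = atlas.index_of("lh_lateralorbitofrontal")
        except KeyError:
            lat = 0
        r = float(np.clip(dose_lateral_r, -0.99, 0.99))
        dose_latent = r * z[:, lat] + np.sqrt(1 - r**2) * dose_noise
    else:
        dose_latent = dose_noise
    dose = np.round(np.exp(1.2 + 0.8 * dose_latent), 2)

    saps_pos = rng.integers(0, 6, size=(n, 2))
    saps_dis = rng.integers(0, 4, size=(n, 2))
    hamd = rng.poisson(12.0, size=n)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": age,
            "sex": sex,
            "site": site,
            "dose": dose,
            "sans_avolition_apathy": avolition,
            "sans_anhedonia_asociality": anhedonia,
            "sans_alogia": alogia,
            "sans_blunted_affect": blunted,
            "saps_delusion": saps_pos[:, 0],
            "saps_hallucination": saps_pos[:, 1],
            "saps_bizarre_behavior": saps_dis[:, 0],
            "saps_formal_thought": saps_dis[:, 1],
            "hamd": hamd,
        }
    )
    for j, name in enumerate(atlas.region_names):
        table[name] = thickness[:, j]

    truth = GroundTruth(
        epicenter_region=int(epicenter_region),
        gamma=float(gamma),
        per_region_target_r=target_spearman(sigma, a, gamma, sigma_noise),
        rng_seed=int(rng_seed),
    )
    return CohortTable(table=table, atlas=atlas), truth
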