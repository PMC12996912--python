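"""ROI-level rank-correlation machinery.

Spearman correlations with the t-approximation p-value, paired percentile
bootstrap confidence intervals, Benjamini-Hochberg FDR, partial Spearman
correlation, and the backtransformed-average z test (Hittner) for comparing
two overlapping dependent correlations.  All ranking uses mid-ranks so heavy
ties in ordinal symptom sums are handled consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None
    p_fdr: float | None = None


@dataclass(frozen=True)
class DependentComparison:
    """Z test of H0: rho_jk = rho_jh for correlations sharing variable j."""

    z_stat: float
    p: float
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    two_sided: bool = False


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the two-sided t-approximation p-value.

    Mid-ranks for ties; rows with a missing value in either vector are
    dropped pairwise.  Constant input is an error (undefined correlation).
    """
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rs, p = stats.spearmanr(x, y)
    return CorrelationResult(rs=float(rs), p=float(np.clip(p, _TINY, 1.0)), n=n)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of `a` with the matching row of `b`."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = (a * b).sum(axis=-1)
    den = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    return num / den


def bootstrap_ci(
    x,
    y,
    n_boot: int = 1000,
    level: float = 0.95,
    rng_seed: int = 0,
    paired: bool = True,
) -> CorrelationResult:
    """Percentile bootstrap interval for the Spearman correlation.

    Subjects are resampled with replacement.  ``paired=True`` (default)
    resamples (x, y) pairs jointly; ``paired=False`` resamples only the x
    margin against the fixed original y — the literal reading of resampling
    "the ROI variables" against the original symptom scores, kept behind a
    flag because it destroys the sampling pairing.  Resamples in which either
    margin is constant are redrawn (at most 100 sweeps).
    """
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 10:
        raise ValueError(f"need n >= 10 complete pairs for the bootstrap, got {n}")
    point = spearman(x, y)
    rng = np.random.default_rng(rng_seed)

    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx] if paired else np.broadcast_to(y, (n_boot, n))
    for _ in range(100):
        bad = (np.ptp(xb, axis=1) == 0) | (np.ptp(yb, axis=1) == 0)
        if not bad.any():
            break
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        xb = xb.copy()
        xb[bad] = x[redraw]
        if paired:
            yb = yb.copy()
            yb[bad] = y[redraw]
    else:
        raise RuntimeError("constant bootstrap resamples persisted after 100 redraws")

    r_boot = _rowwise_pearson(_rank_rows(xb), _rank_rows(yb))
    alpha = 1.0 - level
    lo, hi = np.quantile(r_boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return CorrelationResult(
        rs=point.rs,
        p=point.p,
        n=n,
        ci_low=float(min(lo, point.rs)),
        ci_high=float(max(hi, point.rs)),
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def partial_spearman(x, y, covariate) -> CorrelationResult:
    """Partial Spearman correlation of x and y controlling for one covariate.

    All three vectors are rank-transformed (mid-ranks); x- and y-ranks are
    residualized on the covariate ranks (with intercept) and the Pearson
    correlation of the residuals is returned, with a t-approximation p on
    n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y and covariate must be equal-length 1-D vectors")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[keep], y[keep], c[keep]
    n = len(x)
    if n < 5:
        raise ValueError(f"need n >= 5 complete triples, got {n}")
    if np.ptp(c) == 0:
        raise ValueError("constant covariate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")

    rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
    design = np.column_stack([np.ones(n), rc])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    # a margin explained exactly by the covariate leaves only rounding noise
    ss_x = ((rx - rx.mean()) ** 2).sum()
    ss_y = ((ry - ry.mean()) ** 2).sum()
    if (ex**2).sum() < 1e-16 * ss_x or (ey**2).sum() < 1e-16 * ss_y:
        return CorrelationResult(rs=0.0, p=1.0, n=n)
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    r = float((ex * ey).sum() / denom)
    df = n - 3
    if abs(r) >= 1.0:
        p = _TINY
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(rs=r, p=float(np.clip(p, _TINY, 1.0)), n=n)


def hittner_compare(
    r_jk: float, r_jh: float, r_kh: float, n: int, two_sided: bool = False
) -> DependentComparison:
    """Compare two overlapping dependent correlations (shared variable j).

    Fisher-transforms r_jk and r_jh and uses Dunn & Clark's covariance term c
    with the backtransformed average r_bar = tanh((z_jk + z_jh)/2) substituted
    for both correlations:

        Z = (z_jk - z_jh) * sqrt((n - 3) / (2 - 2c))

    One-sided p (lower tail of the signed Z) by default, matching directional
    hypotheses about which correlation is stronger; ``two_sided=True`` doubles
    the tail.  The three correlations must form a positive semidefinite 3x3
    correlation matrix.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must satisfy |r| < 1")
    corr = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(corr)[0] < -1e-12:
        raise ValueError("inconsistent correlation triple (matrix not PSD)")

    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    r_bar = np.tanh((z_jk + z_jh) / 2.0)
    c = (
        r_kh * (1.0 - 2.0 * r_bar**2)
        - 0.5 * r_bar**2 * (1.0 - 2.0 * r_bar**2 - r_kh**2)
    ) / (1.0 - r_bar**2) ** 2
    z = (z_jk - z_jh) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    if two_sided:
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.cdf(z) if z <= 0 else stats.norm.sf(z)
    return DependentComparison(
        z_stat=float(z),
        p=float(np.clip(p, _TINY, 1.0)),
        r_jk=float(r_jk),
        r_jh=float(r_jh),
        r_kh=float(r_kh),
        n=int(n),
        two_sided=two_sided,
    )
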