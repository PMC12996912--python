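"""Brain-wide symptom effect maps.

An effect map is the vector of per-region Spearman correlations between
standardized thickness residuals and a symptom dimension — the "brain-wide
cortical alterations" pattern that covariance networks and connectivity
profiles are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_stats import spearman
from .atlas_io import ParcelAtlas
from .preprocessing import ResidualMatrix


@dataclass(frozen=True)
class EffectMap:
    coefficients: np.ndarray              # per-region rs
    p_values: np.ndarray
    symptom: str
    n: int
    atlas: ParcelAtlas = field(repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.coefficients, dtype=float)
        if r.shape != (self.atlas.n_regions,):
            raise ValueError("effect map length != atlas region count")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlation coefficients outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_name": self.atlas.region_names,
                "rs": self.coefficients,
                "p": self.p_values,
            }
        )


def effect_map(
    residuals: ResidualMatrix, symptom, symptom_label: str = "symptom"
) -> EffectMap:
    """Correlate every region's residuals with a per-subject symptom vector.

    Rows with a missing symptom value are dropped (residuals themselves are
    always complete); at least 10 complete pairs are required.
    """
    s = np.asarray(symptom, dtype=float)
    if s.shape != (residuals.n_subjects,):
        raise ValueError("symptom vector not aligned to residual subjects")
    keep = np.isfinite(s)
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"need >= 10 complete symptom observations, got {n}")
    z = residuals.values[keep]
    s = s[keep]
    rs = np.empty(z.shape[1])
    p = np.empty(z.shape[1])
    for j in range(z.shape[1]):
        res = spearman(z[:, j], s)
        rs[j], p[j] = res.rs, res.p
    return EffectMap(
        coefficients=rs, p_values=p, symptom=symptom_label, n=n, atlas=residuals.atlas
    )
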