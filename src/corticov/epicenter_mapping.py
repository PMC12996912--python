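"""Connectome epicenter mapping of symptom effect maps.

A region is a candidate epicenter when its normative connectivity profile
spatially matches the brain-wide alteration map: strong connections to
strongly altered regions, weak connections to spared ones.  The region's own
effect-map value plays no special role — an epicenter need not itself be
strongly altered.  For every region the connectivity row is Spearman-
correlated with the effect map (the structurally-zero self entry excluded
from both vectors by default), significance comes from the spin-permutation
null, and regions are ranked by descending correlation strength |r|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas_io import Connectome
from .effect_maps import EffectMap
from .spatial_null import SpinEnsemble, spin_test


def epicenter_scan(
    effect: EffectMap,
    connectome: Connectome,
    spins: SpinEnsemble | None = None,
    include_self: bool = False,
    tail: str = "two-sided",
    n_rot_used: int | None = None,
) -> pd.DataFrame:
    """Correlate every region's connectivity profile with an effect map.

    Returns a table (region, region_name, modality, r, p_spin, rank) sorted
    by descending |r| (sign retained; the strongest epicenters of thickness
    reduction have negative r), ties broken by region index.  ``spins=None``
    skips the permutation test and reports p_spin = NaN — useful inside
    simulation loops where only the ranking is needed.
    """
    atlas = connectome.atlas
    if effect.atlas.region_names != atlas.region_names:
        raise ValueError("effect map and connectome atlases disagree")
    n = atlas.n_regions
    rows = []
    for i in range(n):
        profile = connectome.weights[i]
        exclude = None if include_self else {i}
        keep = np.ones(n, dtype=bool)
        if exclude:
            keep[i] = False
        if np.ptp(profile[keep]) == 0:
            raise ValueError(
                f"constant connectivity profile for region {atlas.region_names[i]!r}"
            )
        if spins is None:
            from .association_stats import spearman

            res = spearman(profile[keep], effect.coefficients[keep])
            r, p = res.rs, float("nan")
        else:
            r, p, _ = spin_test(
                effect.coefficients, profile, spins, method="spearman",
                exclude=exclude, tail=tail,
            )
        rows.append((i, atlas.region_names[i], connectome.modality, r, p))
    df = pd.DataFrame(rows, columns=["region", "region_name", "modality", "r", "p_spin"])
    df = df.sort_values(
        by=["r", "region"], key=lambda s: -s.abs() if s.name == "r" else s
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def run_both_modalities(
    effect: EffectMap,
    fc: Connectome,
    sc: Connectome,
    spins: SpinEnsemble | None = None,
    alpha: float = 0.05,
    include_self: bool = False,
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Epicenter scans for functional and structural connectomes, stacked.

    The joint table carries both modalities (2 x n_regions rows) plus a
    ``significant_both`` flag marking regions with p_spin < alpha in both.
    """
    if fc.atlas.region_names != sc.atlas.region_names:
        raise ValueError("functional and structural connectomes disagree on atlas")
    scan_fc = epicenter_scan(effect, fc, spins=spins, include_self=include_self, tail=tail)
    scan_sc = epicenter_scan(effect, sc, spins=spins, include_self=include_self, tail=tail)
    both = pd.concat([scan_fc, scan_sc], ignore_index=True)
    sig = {}
    for region in both["region"].unique():
        ps = both.loc[both["region"] == region, "p_spin"]
        sig[region] = bool((ps < alpha).all()) if ps.notna().all() else False
    both["significant_both"] = both["region"].map(sig)
    return both
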