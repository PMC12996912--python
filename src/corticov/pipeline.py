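"""Config-driven orchestration of the full analysis.

Stages run in the order the analysis is designed: residualize thickness on
covariates, score symptom dimensions, ROI association statistics (Spearman +
bootstrap CI + FDR + dependent-correlation comparison), brain-wide effect
maps, covariance-network ranking, and epicenter scans for both connectome
modalities.  One configured seed drives every random draw; per-stage seeds
are derived from it by hashing fixed stage names, so stages are individually
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association_stats import bootstrap_ci, fdr_bh, hittner_compare
from .atlas_io import read_atlas, read_cohort, read_connectome
from .covariance_networks import rank_networks
from .effect_maps import effect_map
from .epicenter_mapping import run_both_modalities
from .preprocessing import residualize
from .spatial_null import make_spins
from .symptom_dimensions import compute_dimensions

logger = logging.getLogger("corticov")

#: Stages that consume randomness; each derives its own seed from the single
#: configured rng_seed via stage_seed(), so every draw traces to one seed.
RANDOM_STAGES = ("spins", "bootstrap", "simulate")

DEFAULT_ROIS = (
    "lh_lateralorbitofrontal",
    "rh_lateralorbitofrontal",
    "lh_medialorbitofrontal",
    "rh_medialorbitofrontal",
)


def stage_seed(rng_seed: int, stage: str) -> int:
    """Deterministic sub-seed (< 2^31) for a named stage."""
    h = hashlib.sha256(f"{stage}:{rng_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of one analysis run; defaults mirror the replication setup
    (4 orbitofrontal ROIs, 1000 bootstrap resamples, 1000 spin rotations,
    FDR q < 0.05)."""

    atlas: str = "atlas.csv"
    cohort: str = "cohort.csv"
    connectome_fc: str = "connectome_fc.csv"
    connectome_sc: str = "connectome_sc.csv"
    out_dir: str = "run"
    covariates: tuple[str, ...] = ("age", "sex")
    symptoms: tuple[str, ...] = ("amotivation", "diminished_expression")
    rois: tuple[str, ...] = DEFAULT_ROIS
    n_boot: int = 1000
    n_rot: int = 1000
    q_fdr: float = 0.05
    rng_seed: int = 0
    include_seed_region: bool = False     # keep seed/self entries in spatial correlations
    spin_tail: str = "two-sided"
    bootstrap_paired: bool = True
    kernel: str = "exp_sq"

    def __post_init__(self) -> None:
        if self.n_rot < 100:
            raise ValueError("n_rot must be >= 100")
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must be in (0, 1)")
        if self.rng_seed is None:
            raise ValueError("rng_seed must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(data) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "symptoms", "rois"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("covariates", "symptoms", "rois"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    """Write via an .incomplete temp name, renaming on success — aborted runs
    leave their partial outputs marked."""
    tmp = path.with_name(path.name + ".incomplete")
    df.to_csv(tmp, index=False, float_format="%.17g", **kwargs)
    tmp.rename(path)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write outputs + a reproducibility manifest.

    Returns the run directory.  Identical configs (and inputs) produce
    bit-identical CSVs.  A stage failure raises StageError naming the stage;
    outputs written before the failure remain in place and the failed
    stage's partial file keeps its .incomplete suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    stage = "load-inputs"
    try:
        atlas = read_atlas(config.atlas)
        fc = read_connectome(config.connectome_fc, atlas, modality="functional")
        sc = read_connectome(config.connectome_sc, atlas, modality="structural")
        cohort = read_cohort(config.cohort, atlas)
        timings[stage] = time.time() - t0

        stage = "dimensions"
        t = time.time()
        cohort = compute_dimensions(cohort)
        timings[stage] = time.time() - t

        stage = "residualize"
        t = time.time()
        residuals = residualize(cohort, covariates=list(config.covariates))
        _write_csv(residuals.to_frame(), out / "residuals.csv")
        timings[stage] = time.time() - t

        stage = "spins"
        t = time.time()
        spins = make_spins(atlas, n_rot=config.n_rot,
                           rng_seed=stage_seed(config.rng_seed, "spins"))
        timings[stage] = time.time() - t

        stage = "associations"
        t = time.time()
        assoc = _associations_stage(config, cohort, residuals)
        _write_csv(assoc, out / "associations.csv")
        timings[stage] = time.time() - t

        maps = {}
        for symptom in config.symptoms:
            stage = f"effect-map[{symptom}]"
            t = time.time()
            em = effect_map(
                residuals, cohort.table[symptom].to_numpy(dtype=float),
                symptom_label=symptom,
            )
            maps[symptom] = em
            _write_csv(em.to_frame(), out / f"effect_map_{symptom}.csv")
            timings[stage] = time.time() - t

        primary = maps[config.symptoms[0]]

        stage = "covnet-ranking"
        t = time.time()
        ranking = rank_networks(
            residuals, primary, atlas, spins=spins, kernel=config.kernel,
            include_seed=config.include_seed_region, tail=config.spin_tail,
        )
        _write_csv(ranking, out / "covnet_ranking.csv")
        timings[stage] = time.time() - t

        stage = "epicenters"
        t = time.time()
        epi = run_both_modalities(
            primary, fc, sc, spins=spins, alpha=config.q_fdr,
            include_self=config.include_seed_region, tail=config.spin_tail,
        )
        for modality in ("functional", "structural"):
            _write_csv(
                epi[epi["modality"] == modality].reset_index(drop=True),
                out / f"epicenters_{modality}.csv",
            )
        timings[stage] = time.time() - t
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "stage_seeds": {s: stage_seed(config.rng_seed, s) for s in RANDOM_STAGES},
        "versions": {
            "corticov": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "file_hashes": {name: _sha256(out / name) for name in outputs},
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return out


def _associations_stage(config, cohort, residuals) -> pd.DataFrame:
    """ROI x symptom Spearman table with bootstrap CIs, FDR-adjusted p, and
    the dependent-correlation comparison between the two symptom dimensions
    per ROI (when exactly two symptoms are configured)."""
    from .association_stats import spearman  # local to keep module surface tidy

    missing = [r for r in config.rois if r not in cohort.atlas.region_names]
    if missing:
        raise ValueError(f"configured ROIs not in atlas: {missing}")
    boot_seed = stage_seed(config.rng_seed, "bootstrap")
    rows = []
    for roi in config.rois:
        j = cohort.atlas.index_of(roi)
        zj = residuals.values[:, j]
        for symptom in config.symptoms:
            s = cohort.table[symptom].to_numpy(dtype=float)
            keep = np.isfinite(s)
            res = bootstrap_ci(
                zj[keep], s[keep], n_boot=config.n_boot,
                rng_seed=boot_seed, paired=config.bootstrap_paired,
            )
            rows.append(
                dict(roi=roi, symptom=symptom, rs=res.rs, p=res.p, n=res.n,
                     ci_low=res.ci_low, ci_high=res.ci_high)
            )
    df = pd.DataFrame(rows)
    p_adj, reject = fdr_bh(df["p"].to_numpy(), q=config.q_fdr)
    df["p_fdr"] = p_adj
    df["significant"] = reject

    if len(config.symptoms) == 2:
        sym_a, sym_b = config.symptoms
        a = cohort.table[sym_a].to_numpy(dtype=float)
        b = cohort.table[sym_b].to_numpy(dtype=float)
        z_col, p_col = [], []
        for roi in df["roi"]:
            j = cohort.atlas.index_of(roi)
            zj = residuals.values[:, j]
            keep = np.isfinite(a) & np.isfinite(b)
            r_jk = spearman(zj[keep], a[keep]).rs
            r_jh = spearman(zj[keep], b[keep]).rs
            r_kh = spearman(a[keep], b[keep]).rs
            cmp_res = hittner_compare(r_jk, r_jh, r_kh, int(keep.sum()))
            z_col.append(cmp_res.z_stat)
            p_col.append(cmp_res.p)
        df["hittner_z"] = z_col
        df["hittner_p"] = p_col
    return df
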