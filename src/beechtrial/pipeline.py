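"""End-to-end orchestration: simulate → derive → fit → partition → correlate.

The full analysis of a (virtual) provenance trial runs as a fixed stage
order: generate the trial (or ingest CSVs), derive anatomy and growth traits,
fit vulnerability curves, compute climate-of-origin indices, partition trait
variance, fit the climate models, and compute trait correlations.  Every run
writes a manifest (seed, config hash, per-file row counts) so reruns are
auditable; with a fixed seed all outputs are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as btio
from .anatomy import CrossSectionSample, cross_section_traits
from .climate import climate_indices
from .growth import DEFAULT_STAND_AGE_YR, aboveground_biomass
from .relations import pearson_matrix
from .simulate import (
    DEFAULT_TRAIT_SPECS,
    PLCSimSpec,
    TrialDesign,
    VesselSimSpec,
    simulate_origin_climate,
    simulate_plc_series,
    simulate_trial,
    simulate_vessel_population,
)
from .varcomp import (
    LOG_TRANSFORM_TRAITS,
    fit_climate_model,
    variance_partition_summary,
)
from .vulnerability import fit_vulnerability_curve

logger = logging.getLogger(__name__)

ID_COLS = ["tree_id", "provenance", "block"]

#: Climate envelope of the trial's provenance origins (MAT °C, MAP mm).
MAT_RANGE = (3.4, 15.3)
MAP_RANGE = (575.0, 1080.0)


@dataclass
class RunConfig:
    """Configuration of one full simulated-trial analysis run."""

    seed: int = 0
    n_provenances: int = 10
    n_blocks: int = 3
    n_trees_per_cell: int = 4
    n_vessels: int = 400
    plc_noise_sd: float = 3.0
    stand_age_yr: float = DEFAULT_STAND_AGE_YR
    cv_intra_mode: str = "mean"
    lumen_area: str = "idealized"
    log_transform_traits: tuple[str, ...] = tuple(sorted(LOG_TRANSFORM_TRAITS))
    out_dir: str = "out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "log_transform_traits" in d:
            d["log_transform_traits"] = tuple(d["log_transform_traits"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-stage seeds derived from the master seed."""
    return np.random.default_rng(seed).integers(0, 2**31, size=n)


def simulate_inputs(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Generate all raw input tables of a virtual trial.

    Returns trees (trait table), vessels, branches, plc and climate frames in
    the reader schemas of :mod:`beechtrial.io`.
    """
    design = TrialDesign(
        cfg.n_provenances, cfg.n_blocks, cfg.n_trees_per_cell, seed=cfg.seed
    )
    trees = simulate_trial(design, DEFAULT_TRAIT_SPECS)
    n = len(trees)
    seeds = _child_seeds(cfg.seed, 2 * n + cfg.n_provenances)

    vspec = VesselSimSpec(n_vessels=cfg.n_vessels)
    vessel_rows, branch_rows, plc_rows = [], [], []
    for i, row in enumerate(trees.itertuples()):
        branch_id = row.tree_id
        pop = simulate_vessel_population(vspec, seed=int(seeds[i]))
        vessel_rows.extend(
            {"branch_id": branch_id, "a_um": v.a, "b_um": v.b} for v in pop
        )
        rng = np.random.default_rng(int(seeds[i]) + 1)
        a_cross = rng.uniform(28.0, 44.0)  # ~6–7.5 mm segments
        branch_rows.append(
            {
                "branch_id": branch_id,
                "a_cross_mm2": a_cross,
                "branch_age_yr": int(rng.integers(2, 5)),
                "leaf_area_m2": rng.uniform(0.15, 0.45),
            }
        )
        pspec = PLCSimSpec(
            true_p50=getattr(row, "P50", -3.0), noise_sd=cfg.plc_noise_sd
        )
        series = simulate_plc_series(pspec, seed=int(seeds[n + i]), branch_id=branch_id)
        plc_rows.extend(
            {"branch_id": branch_id, "pressure_mpa": p, "plc": v}
            for p, v in zip(series.pressures_mpa, series.plc)
        )

    climate_rows = []
    provs = trees["provenance"].unique()
    mats = np.linspace(*MAT_RANGE, len(provs))
    maps = np.linspace(*MAP_RANGE, len(provs))
    for j, prov in enumerate(provs):
        mc = simulate_origin_climate(
            mats[j], maps[j], seed=int(seeds[2 * n + j]), provenance=prov
        )
        climate_rows.extend(
            {
                "provenance": prov,
                "month": m + 1,
                "tmean_c": mc.tmean_c[m],
                "prec_mm": mc.prec_mm[m],
            }
            for m in range(12)
        )

    return {
        "trees": trees,
        "vessels": pd.DataFrame(vessel_rows),
        "branches": pd.DataFrame(branch_rows),
        "plc": pd.DataFrame(plc_rows),
        "climate": pd.DataFrame(climate_rows),
    }


def derive_anatomy(samples: list[CrossSectionSample], lumen_area="idealized") -> pd.DataFrame:
    rows = []
    for s in samples:
        t = cross_section_traits(s, lumen_area=lumen_area)
        rows.append(
            {
                "branch_id": t.branch_id,
                "n_vessels": t.n_vessels,
                "D": t.d_mean_um,
                "D_h": t.d_hyd_um,
                "VD": t.vessel_density_mm2,
                "lumen_fraction": t.lumen_fraction_pct,
                "KStheo": t.ks_theo,
                "KLtheo": None if t.kl_theo is None else t.kl_theo / 1e-4,
                "A_growth": t.a_growth_mm2_yr,
            }
        )
    return pd.DataFrame(rows)


def fit_all_curves(series_list, **kwargs) -> pd.DataFrame:
    rows = []
    for s in series_list:
        f = fit_vulnerability_curve(s, **kwargs)
        rows.append(
            {
                "branch_id": f.branch_id,
                "p50": f.p50,
                "slope": f.slope,
                "p12": f.p12,
                "p88": f.p88,
                "rss": f.rss,
                "max_plc_reached": f.max_plc_reached,
                "qc_pass": f.qc_pass,
            }
        )
    return pd.DataFrame(rows)


def derive_climate_indices(monthly) -> pd.DataFrame:
    rows = []
    for mc in monthly:
        ci = climate_indices(mc)
        rows.append(
            {
                "provenance": ci.provenance,
                "mat_c": ci.mat_c,
                "map_mm": ci.map_mm,
                "msp_mm": ci.msp_mm,
                "eq": ci.eq,
                "fai": ci.fai,
                "gai": ci.gai,
            }
        )
    return pd.DataFrame(rows)


def partition_all_traits(traits: pd.DataFrame, intra="mean") -> pd.DataFrame:
    """Per-trait variance decomposition over all numeric trait columns."""
    rows = []
    for col in traits.columns:
        if col in ID_COLS or not pd.api.types.is_numeric_dtype(traits[col]):
            continue
        sub = traits[[*ID_COLS, col]].dropna()
        try:
            s = variance_partition_summary(
                col, sub[col], sub["provenance"], sub["block"], intra=intra
            )
        except ValueError as exc:
            logger.warning("varcomp skipped for %s: %s", col, exc)
            continue
        rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def climate_models_all_traits(
    traits: pd.DataFrame,
    fai_by_provenance: dict[str, float],
    log_transform_traits=LOG_TRANSFORM_TRAITS,
) -> pd.DataFrame:
    rows = []
    for col in traits.columns:
        if col in ID_COLS or not pd.api.types.is_numeric_dtype(traits[col]):
            continue
        sub = traits[[*ID_COLS, col]].dropna()
        try:
            f = fit_climate_model(
                sub[col],
                fai_by_provenance,
                sub["provenance"],
                sub["block"],
                log_transform=col in log_transform_traits,
            )
        except ValueError as exc:
            logger.warning("climate model skipped for %s: %s", col, exc)
            continue
        d = dataclasses.asdict(f)
        d["trait"] = col
        rows.append(d)
    cols = ["trait"] + [c for c in rows[0] if c != "trait"] if rows else None
    return pd.DataFrame(rows, columns=cols)


def run_full_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Run the complete simulated-trial analysis and write all outputs.

    Returns a mapping of output name → written path.  The manifest records
    the seed, config hash and per-file row counts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = simulate_inputs(cfg)
    paths: dict[str, Path] = {}
    for name, df in inputs.items():
        paths[name] = btio.write_csv(df, out / f"{name}.csv")
        logger.info("wrote %s (%d rows, seed %d)", paths[name], len(df), cfg.seed)

    samples = btio.read_cross_sections(paths["vessels"], paths["branches"])
    anatomy = derive_anatomy(samples, lumen_area=cfg.lumen_area)
    paths["anatomy_traits"] = btio.write_csv(anatomy, out / "anatomy_traits.csv")

    series = btio.read_plc(paths["plc"])
    vc_fits = fit_all_curves(series)
    paths["vc_fits"] = btio.write_csv(vc_fits, out / "vc_fits.csv")

    monthly = btio.read_climate(paths["climate"])
    clim = derive_climate_indices(monthly)
    paths["climate_indices"] = btio.write_csv(clim, out / "climate_indices.csv")

    trees = inputs["trees"].copy()
    trees["AGB"] = [
        aboveground_biomass(d, h) for d, h in zip(trees["DBH"], trees["Height"])
    ]
    trees["ABI"] = trees["AGB"] / cfg.stand_age_yr
    merged = (
        trees.merge(
            anatomy.rename(columns={"branch_id": "tree_id"}), on="tree_id", how="left"
        )
        .merge(
            vc_fits.rename(
                columns={
                    "branch_id": "tree_id",
                    "p12": "P12_fit",
                    "p50": "P50_fit",
                    "p88": "P88_fit",
                }
            )[["tree_id", "P12_fit", "P50_fit", "P88_fit", "qc_pass"]],
            on="tree_id",
            how="left",
        )
        .drop(columns=["qc_pass", "n_vessels"])
    )
    paths["traits"] = btio.write_csv(merged, out / "traits.csv")

    varcomp = partition_all_traits(merged, intra=cfg.cv_intra_mode)
    paths["varcomp"] = btio.write_csv(varcomp, out / "varcomp.csv")

    fai = dict(zip(clim["provenance"], clim["fai"]))
    cm = climate_models_all_traits(
        merged, fai, log_transform_traits=set(cfg.log_transform_traits)
    )
    paths["climate_model"] = btio.write_csv(cm, out / "climate_model.csv")

    corr = pearson_matrix(merged, level="tree")
    paths["correlations"] = btio.write_csv(corr, out / "correlations.csv")

    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "rows": {k: int(pd.read_csv(v).shape[0]) for k, v in paths.items()},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths
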