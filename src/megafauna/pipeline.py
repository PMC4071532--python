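"""End-to-end orchestration: climate -> ranges -> richness -> models -> spatial.

Every stage reads its upstream artifacts from (and writes its own artifacts
to) a run directory as plain-text CSV/ASCII files with a provenance header,
so any single stage can be re-run from cached outputs and reproduce the
downstream results byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import (
    EPOCH_SPANS_YR,
    compute_anomaly,
    read_ascii_grid,
    region_climate,
    spatial_gradient,
    standardize_scores,
    velocity,
    write_ascii_grid,
)
from .errors import InvalidConfigError
from .models import (
    ModelSpec,
    aic_select,
    enumerate_candidates,
    f_test_nested,
    fit_arcsine_glm,
    lump_hominin_categories,
)
from .ranges import extinction_counts, fill_presence_matrix, filter_species
from .richness import build_extinction_table
from .spatial import correlogram, knn_weights, sar_error_fit
from .synthetic import (
    DGPParams,
    RegionSet,
    WorldConfig,
    generate_climate_field,
    generate_extinctions,
    generate_regions,
    generate_species_table,
    round_half_up,
)

#: Modern-human arrival times (kyr BP) by hominin-history class, used by the
#: arrival-time covariate that competes with the categorical coding.
ARRIVAL_TIME_KYR = {
    "Homo-origin": 200.0,
    "Archaic-early": 100.0,
    "Archaic-late": 60.0,
    "Archaic-peripheral": 45.0,
    "Homo_sapiens-only": 20.0,
}

STAGES = ("simulate", "climate", "ranges", "richness", "fit", "spatial")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults mirror the primary analysis."""

    mode: str = "synthetic"
    epoch_pair: tuple[str, str] = ("lgm", "present")
    min_mass_kg: float = 10.0
    include_uncertain: bool = False
    interpolation: bool = True
    alpha_richness: float = 0.10
    alpha_lump: float = 0.05
    k_neighbours: int = 4
    class_width_km: float = 500.0
    seed: int = 0
    n_regions: int = 229
    grid_shape: tuple[int, int] = (30, 30)
    cell_size_km: float = 250.0
    continents: int = 6
    n_species: int = 177
    smoothness_km: float = 600.0
    epoch_correlation: float = 0.8
    impact_effect: float = 0.35
    dgp: DGPParams = field(default_factory=DGPParams)
    raster_paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        self.epoch_pair = tuple(self.epoch_pair)
        if self.epoch_pair not in EPOCH_SPANS_YR:
            raise InvalidConfigError(f"unknown epoch pair {self.epoch_pair}")
        if self.min_mass_kg not in (10.0, 44.0):
            # non-standard thresholds are allowed but flagged in the log
            pass

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dgp = raw.pop("dgp", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if dgp:
            cfg.dgp = DGPParams(**dgp)
        return cfg

    def world_config(self) -> WorldConfig:
        return WorldConfig(
            n_regions=self.n_regions,
            grid_shape=tuple(self.grid_shape),
            cell_size_km=self.cell_size_km,
            continents=self.continents,
            seed=self.seed,
        )

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        payload["dgp"]["beta"] = list(self.dgp.beta)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Artifact I/O
# ---------------------------------------------------------------------------


def _header(cfg: RunConfig) -> str:
    return (
        f"# megafauna {__version__}\n"
        f"# config_hash {cfg.digest()}\n"
        f"# seed {cfg.seed}\n"
    )


def save_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, index=False, lineterminator="\n")


def load_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _regions_from_artifacts(out: Path, cfg: RunConfig) -> RegionSet:
    table = load_csv(out / "regions.csv")
    membership = np.loadtxt(out / "membership.txt", dtype=int)
    rows, cols = membership.shape
    adj = nx.Graph()
    adj.add_nodes_from(table["region_id"])
    for r in range(rows):
        for c in range(cols):
            a = membership[r, c]
            if c + 1 < cols and membership[r, c + 1] != a:
                adj.add_edge(a, membership[r, c + 1])
            if r + 1 < rows and membership[r + 1, c] != a:
                adj.add_edge(a, membership[r + 1, c])
    return RegionSet(table, membership, adj, cfg.cell_size_km)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, out: Path, log: list[str]) -> None:
    """Generate the world: regions, epoch climate grids, species, extinctions."""
    regions = generate_regions(cfg.world_config())
    save_csv(regions.table, out / "regions.csv", cfg)
    np.savetxt(out / "membership.txt", regions.membership, fmt="%d")
    log.append(f"simulate: {regions.n} regions on {cfg.grid_shape} lattice")

    rng = np.random.default_rng(cfg.seed)
    for var, trend, noise in (("temperature", 25.0, 4.0), ("precipitation", 1200.0, 300.0)):
        sub = int(rng.integers(0, 2**31))
        eps_a = np.random.default_rng(sub).standard_normal(cfg.grid_shape)
        eps_c = np.random.default_rng(sub + 1).standard_normal(cfg.grid_shape)
        r = cfg.epoch_correlation
        eps_b = r * eps_a + np.sqrt(1 - r**2) * eps_c
        for epoch, eps in zip(cfg.epoch_pair, (eps_a, eps_b)):
            grid = generate_climate_field(
                cfg.world_config(),
                epoch,
                cfg.smoothness_km,
                cfg.seed,
                variable=var,
                trend_amplitude=trend,
                noise_sd=noise,
                innovations=eps,
            )
            write_ascii_grid(out / f"climate_{var}_{epoch}.asc", grid)
    log.append(f"simulate: climate grids for epochs {cfg.epoch_pair}")

    species, presence = generate_species_table(
        cfg.n_species, regions=regions, seed=cfg.seed + 1
    )
    save_csv(species, out / "species.csv", cfg)
    save_csv(presence, out / "presence.csv", cfg)
    log.append(f"simulate: {len(species)} species, {len(presence)} presence records")


def stage_climate(cfg: RunConfig, out: Path, log: list[str]) -> None:
    """Anomaly, gradient, velocity and standardized per-region scores."""
    regions = _regions_from_artifacts(out, cfg)
    years = EPOCH_SPANS_YR[cfg.epoch_pair]
    frames = {}
    for var in ("temperature", "precipitation"):
        if cfg.mode == "real":
            paths = []
            for epoch in cfg.epoch_pair:
                p = cfg.raster_paths.get(f"{var}_{epoch}")
                if p is None or not Path(p).exists():
                    raise InvalidConfigError(
                        f"real mode needs raster {var}_{epoch}; missing path: {p}"
                    )
                paths.append(Path(p))
            a = read_ascii_grid(paths[0], variable=var)
            b = read_ascii_grid(paths[1], variable=var)
        else:
            a = read_ascii_grid(out / f"climate_{var}_{cfg.epoch_pair[0]}.asc", variable=var)
            b = read_ascii_grid(out / f"climate_{var}_{cfg.epoch_pair[1]}.asc", variable=var)
        anom = compute_anomaly(a, b)
        grad = spatial_gradient(b)
        vel = velocity(anom, grad, years)
        frames[var] = region_climate(anom, vel, regions.membership)
    t, p = frames["temperature"], frames["precipitation"]
    df = pd.DataFrame(
        {
            "region_id": t.region_ids,
            "anomaly_mean_T": t.anomaly_mean,
            "velocity_mean_T": t.velocity_mean,
            "velocity_range_T": t.velocity_range,
            "anomaly_mean_P": p.anomaly_mean,
            "velocity_mean_P": p.velocity_mean,
            "velocity_range_P": p.velocity_range,
            "T_anom": t.score_anomaly,
            "T_vel": t.score_velocity,
            "P_anom": p.score_anomaly,
            "P_vel": p.score_velocity,
        }
    )
    save_csv(df, out / "region_climate.csv", cfg)
    log.append(
        "climate: median velocity range per region "
        f"T={np.median(t.velocity_range):.1f} P={np.median(p.velocity_range):.1f} m/yr"
    )


def stage_ranges(cfg: RunConfig, out: Path, log: list[str]) -> None:
    """Filter species, fill range gaps, count extinctions per region."""
    regions = _regions_from_artifacts(out, cfg)
    species = load_csv(out / "species.csv")
    presence = load_csv(out / "presence.csv")
    accepted = filter_species(
        species, cfg.min_mass_kg, include_uncertain=cfg.include_uncertain
    )
    save_csv(accepted, out / "species_filtered.csv", cfg)
    log.append(
        f"ranges: {len(accepted)}/{len(species)} species pass filters "
        f"(min mass {cfg.min_mass_kg} kg, uncertain={cfg.include_uncertain})"
    )
    kept = presence[presence["species"].isin(accepted["name"])]
    if cfg.interpolation:
        clim = load_csv(out / "region_climate.csv")
        env = dict(zip(clim["region_id"], clim["T_anom"]))
        filled = fill_presence_matrix(kept, regions, env)
        n_interp = int((filled["provenance"] == "interpolated").sum())
        log.append(f"ranges: gap filling added {n_interp} interpolated presences")
    else:
        filled = kept.reset_index(drop=True)
        log.append("ranges: interpolation disabled; direct records only")
    save_csv(filled, out / "presence_filled.csv", cfg)
    per_region, per_continent = extinction_counts(filled, regions)
    save_csv(per_region.reset_index(), out / "extinct_counts.csv", cfg)
    save_csv(per_continent.reset_index(), out / "continent_tallies.csv", cfg)
    log.append(
        f"ranges: max per-region count {int(per_region.max())}, "
        f"{int((per_region == 0).sum())} regions with no recorded extinction"
    )


def stage_richness(cfg: RunConfig, out: Path, log: list[str]) -> None:
    """DGP extinction counts, richness inputs, correction, proportions."""
    regions = _regions_from_artifacts(out, cfg)
    clim = load_csv(out / "region_climate.csv")
    ta = clim.sort_values("region_id")["T_anom"].to_numpy()
    ext = generate_extinctions(regions, ta, cfg.dgp, cfg.seed + 2)
    save_csv(ext, out / "extinctions.csv", cfg)

    rng = np.random.default_rng(cfg.seed + 3)
    extant = (ext["total_species"] - ext["extinct_count"]).to_numpy()
    impact = np.round(rng.uniform(0.0, 1.0, regions.n), 4)
    observed_extant = round_half_up(extant * (1.0 - cfg.impact_effect * impact))
    small = rng.integers(40, 160, regions.n)
    rich = pd.DataFrame(
        {
            "region_id": ext["region_id"],
            "continent": ext["continent"],
            "hominin_class": ext["hominin_class"],
            "ta_std": ext["ta_std"],
            "extinct": ext["extinct_count"],
            "extant_large": observed_extant,
            "small_richness": small,
            "human_impact": impact,
        }
    )
    save_csv(rich, out / "richness_inputs.csv", cfg)
    table, excluded = build_extinction_table(rich, alpha=cfg.alpha_richness)
    save_csv(table, out / "extinction_table.csv", cfg)
    log.append(
        f"richness: corrected table for {len(table)} regions; "
        f"excluded {len(excluded)} with undefined proportion"
    )


def _model_data(out: Path) -> pd.DataFrame:
    table = load_csv(out / "extinction_table.csv")
    clim = load_csv(out / "region_climate.csv")
    data = table.merge(clim, on="region_id")
    data["proportion"] = data["proportion_extinct"]
    data["arrival_time"] = data["hominin_class"].map(ARRIVAL_TIME_KYR)
    return data.sort_values("region_id").reset_index(drop=True)


def stage_fit(cfg: RunConfig, out: Path, log: list[str]) -> dict:
    """Enumerate, fit and AIC-select the climate, hominin and combined models."""
    data = _model_data(out)
    results = {}
    climate_fits = [fit_arcsine_glm(s, data) for s in enumerate_candidates("climate")]
    best_climate, rank_c = aic_select(climate_fits)
    save_csv(rank_c, out / "model_climate_ranking.csv", cfg)
    hominin_fits = [fit_arcsine_glm(s, data) for s in enumerate_candidates("hominin")]
    best_hominin, rank_h = aic_select(hominin_fits)
    save_csv(rank_h, out / "model_hominin_ranking.csv", cfg)
    combined_specs = enumerate_candidates(
        "combined", best_climate.spec, best_hominin.spec
    )
    combined_fits = [fit_arcsine_glm(s, data) for s in combined_specs]
    best_combined, rank_cb = aic_select(combined_fits)
    save_csv(rank_cb, out / "model_combined_ranking.csv", cfg)
    save_csv(best_combined.table(), out / "best_model_terms.csv", cfg)

    groups = lump_hominin_categories(data, alpha=cfg.alpha_lump)
    with open(out / "hominin_lumping.json", "w") as fh:
        json.dump([list(g) for g in groups], fh, indent=1)

    for name, small in (("climate", best_climate), ("hominin", best_hominin)):
        if set(small.names) <= set(best_combined.names):
            F, p, df = f_test_nested(small, best_combined)
            log.append(f"fit: combined vs {name}: F{df} = {F:.3f}, p = {p:.3g}")
    log.append(
        f"fit: best climate [{best_climate.spec.label()}] R2={best_climate.r2:.3f}; "
        f"best hominin [{best_hominin.spec.label()}] R2={best_hominin.r2:.3f}; "
        f"best combined [{best_combined.spec.label()}] AIC={best_combined.aic:.2f}"
    )
    log.append(f"fit: hominin lumping -> {[list(g) for g in groups]}")
    results["best_climate"] = best_climate
    results["best_hominin"] = best_hominin
    results["best_combined"] = best_combined
    return results


def stage_spatial(cfg: RunConfig, out: Path, log: list[str]) -> dict:
    """SAR error model on the best combined spec; correlograms before/after."""
    from .models import arcsine_transform, build_design

    regions = _regions_from_artifacts(out, cfg)
    data = _model_data(out)
    rank = load_csv(out / "model_combined_ranking.csv")
    spec = _spec_from_label(rank["model"].iloc[0])
    X, names = build_design(spec, data)
    y = arcsine_transform(data["proportion"])
    coords = (
        regions.table.set_index("region_id")
        .loc[data["region_id"], ["centroid_x_km", "centroid_y_km"]]
        .to_numpy()
    )
    W = knn_weights(coords, k=cfg.k_neighbours)
    fit = sar_error_fit(X, y, W, names=names)

    glm_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    cg_before = correlogram(glm_resid, coords, cfg.class_width_km, seed=cfg.seed + 4)
    cg_after = correlogram(
        fit.innovations, coords, cfg.class_width_km, seed=cfg.seed + 4
    )
    for tag, cg in (("glm", cg_before), ("sar", cg_after)):
        save_csv(
            pd.DataFrame(
                {
                    "class_lo_km": cg.class_lo_km,
                    "class_hi_km": cg.class_hi_km,
                    "n_pairs": cg.n_pairs,
                    "moran_i": cg.moran_i,
                    "p_perm": cg.p_perm,
                }
            ),
            out / f"correlogram_{tag}.csv",
            cfg,
        )
    rows = list(
        zip(fit.names, fit.params, fit.bse, fit.zvalues, fit.pvalues)
    )
    report = pd.DataFrame(rows, columns=["term", "estimate", "sd", "Z", "p"])
    extra = pd.DataFrame(
        {
            "term": ["lambda", "sigma2", "logLik", "AIC", "pseudo_R2"],
            "estimate": [fit.lam, fit.sigma2, fit.loglik, fit.aic, fit.pseudo_r2],
            "sd": [fit.lam_se, np.nan, np.nan, np.nan, np.nan],
            "Z": np.nan,
            "p": np.nan,
        }
    )
    save_csv(pd.concat([report, extra], ignore_index=True), out / "sar_fit.csv", cfg)
    i1, p1 = cg_before.first_class()
    i2, p2 = cg_after.first_class()
    log.append(
        f"spatial: SAR lambda={fit.lam:.3f} pseudoR2={fit.pseudo_r2:.3f}; "
        f"first-class Moran I {i1:.3f} (p={p1:.3g}) before, {i2:.3f} (p={p2:.3g}) after"
    )
    _write_geojson(regions, data, out / "regions.geojson")
    return {"sar": fit, "correlogram_glm": cg_before, "correlogram_sar": cg_after}


def _spec_from_label(label: str) -> ModelSpec:
    """Inverse of ModelSpec.label() for cached ranking tables."""
    climate, hominin, interactions = [], None, []
    for part in label.split(" + "):
        part = part.strip()
        if part.startswith("hominin["):
            hominin = part[len("hominin[") : -1]
        elif part.startswith("hominin:"):
            interactions.append(part.split(":", 1)[1])
        else:
            climate.append(part)
    return ModelSpec(
        climate=tuple(climate), hominin=hominin, interactions=tuple(interactions)
    )


def _write_geojson(regions: RegionSet, data: pd.DataFrame, path: Path) -> None:
    from shapely.geometry import mapping

    from .ranges import region_geometries

    geoms = region_geometries(regions)
    props = data.set_index("region_id")
    feats = []
    for rid, geom in geoms.items():
        attrs = {"region_id": rid}
        if rid in props.index:
            row = props.loc[rid]
            attrs.update(
                {
                    "hominin_class": row["hominin_class"],
                    "proportion_extinct": float(row["proportion_extinct"]),
                    "T_anom": float(row["T_anom"]),
                }
            )
        feats.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def run_pipeline(cfg: RunConfig, out_dir, stages=STAGES) -> dict:
    """Run the requested stages in order, writing artifacts and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"# megafauna {__version__} config {cfg.digest()} seed {cfg.seed}"]
    results: dict = {}
    order = [s for s in STAGES if s in stages]
    for stage in order:
        try:
            fn = globals()[f"stage_{stage}"]
            res = fn(cfg, out, log)
            if res:
                results.update(res)
        except Exception:
            log.append(f"ERROR in stage {stage}; partial outputs preserved in {out}")
            (out / "run.log").write_text("\n".join(log) + "\n")
            raise
    (out / "run.log").write_text("\n".join(log) + "\n")
    results["log"] = log
    return results
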