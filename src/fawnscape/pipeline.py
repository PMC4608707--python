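"""End-to-end pipeline: synthesize a study system, then run the full
landscape-survival analysis on it.

Stages: landscape covariates -> use-availability RSF and suitability map ->
integrated predation risk + winter severity + greenness -> Kaplan-Meier /
log-rank -> daily and seasonal Cox frailty model suites -> spatial mortality
map.  Every random draw derives its seed from the single pipeline seed, and
a manifest records seeds and output checksums so reruns are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import risk as risk_mod
from . import synthetic as syn
from .io import PipelineConfig, write_ascii_grid, write_wkt_lines
from .landscape import (
    Standardizer,
    VEGETATION_CLASSES,
    build_grid,
    draw_availability_points,
    label_patches,
    standardize,
    vif_screen,
)
from .rsf import evaluate_model_set, suitability_score
from .spatial import mortality_map
from .survival import add_interaction_columns, build_intervals, km_fit, logrank, run_suite

__all__ = ["default_truth", "simulate_study", "analyze", "run_pipeline"]

#: Covariates entering the RSF (the study's Table-2 style metric set).
RSF_COVARIATES = [
    *[f"prop_{c}" for c in VEGETATION_CLASSES],
    "patch_area_km2", "nearest_patch_km", "dist_road_m", "dist_water_m",
]

#: Hazard-model covariates (daily/seasonal suite vocabulary).
HAZARD_COVARIATES = [
    "resource_use", "predation_risk", "birth_mass", "winter_severity",
    "hiding_cover",
]


def default_truth(seed: int = 0) -> syn.SyntheticTruth:
    """Generative parameters used for the standard synthetic study.

    Selection favours deciduous forest and road proximity and avoids lowland
    forest (negative road-distance and lowland coefficients); the hazard
    decreases with resource use and birth mass, increases with predation risk
    and winter severity, with a negative mass x severity interaction (heavy
    fawns buffer severe winters).  Hazard coefficients are per natural unit
    of each covariate (suitability in [0,1], risk in [0,4], mass in kg,
    severity in index units).
    """
    return syn.SyntheticTruth(
        rsf_beta={
            "prop_deciduous_forest": 0.5,
            "prop_lowland_forest": -0.6,
            "dist_road_m": -1.0,
            "nearest_patch_km": 0.4,
        },
        hazard_beta={
            "resource_use": -2.0,
            "predation_risk": 0.45,
            "birth_mass": -0.35,
            "winter_severity": 0.0005,
            "mass_x_winter": -0.0003,  # applies to (mass - intercept) x severity
        },
        frailty_var_fawn=0.15,
        frailty_var_year=0.05,
        baseline_hazard=0.029,
        seed=seed,
    )


def _subseed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + 7919 * k + 17) % (2**31 - 1))


def simulate_study(config: PipelineConfig, truth: syn.SyntheticTruth | None = None
                   ) -> syn.SyntheticDataset:
    """Generate one full synthetic study system under the configured conditions."""
    config.validate()
    seed = config.seed
    if truth is None:
        truth = default_truth(seed)

    raster, roads, water = syn.gen_landscape(
        _subseed(seed, 1), config.landscape_size, config.landscape_size
    )
    patches = label_patches(raster)
    grid = build_grid(raster, roads, water, config.cell_area_m2, patches=patches)

    predators = syn.gen_predator_surfaces(_subseed(seed, 2), grid)
    weather = pd.concat(
        [syn.gen_weather(_subseed(seed, 3 + i), lvl, year=yr)
         for i, (yr, lvl) in enumerate(zip(config.years, config.severity_levels))],
        ignore_index=True,
    )
    wsi = risk_mod.annual_wsi(weather)
    wsi_map = dict(zip(wsi["year"], wsi["centered"]))

    rng = np.random.default_rng(_subseed(seed, 10))
    greenness = {
        yr: rng.normal(rng.uniform(-0.6, 0.6), 0.9, 4000)
        for yr in config.years
    }

    # true selection surface on the grid's own standardized covariates
    cells_std, _ = standardize(grid.cells, RSF_COVARIATES)
    beta_vec = np.array([truth.rsf_beta.get(c, 0.0) for c in RSF_COVARIATES])
    # cells with undefined metrics select at the average (0 standardized)
    X_true = np.nan_to_num(cells_std[RSF_COVARIATES].to_numpy())
    true_eta = X_true @ beta_vec
    true_w = np.exp(true_eta - true_eta.max())
    from .rsf import linear_stretch
    true_use = linear_stretch(true_w)
    integrated = risk_mod.integrate_risk(predators).integrated

    cohorts, telemetry = [], []
    offset = 0
    for i, yr in enumerate(config.years):
        cohort = syn.gen_cohort(
            _subseed(seed, 20 + i), config.n_fawns_per_year[i], wsi_map[yr],
            year=yr, mass_intercept_kg=truth.mass_intercept_kg,
            mass_slope_kg_per_wsi=truth.mass_slope_kg_per_wsi,
            mass_sd_kg=truth.mass_sd_kg, id_offset=offset,
        )
        offset += len(cohort)
        cohorts.append(cohort)
        rng_i = np.random.default_rng(_subseed(seed, 40 + i))
        for rec in cohort.itertuples(index=False):
            n_locs = int(rng_i.integers(config.locs_per_fawn[0],
                                        config.locs_per_fawn[1] + 1))
            b_fawn = rng_i.normal(0, np.sqrt(truth.frailty_var_fawn))
            telemetry.append(syn.gen_telemetry(
                _subseed(seed, 1000 + rec.fawn_id), rec.fawn_id, yr,
                rec.birth_doy, grid, X_true,
                beta_vec, n_locs, fawn_intercept=b_fawn,
            ))
    fawns = pd.concat(cohorts, ignore_index=True)
    telemetry = pd.concat(telemetry, ignore_index=True)

    # per-fawn daily hazard covariates: most recent relocation carried forward
    hb = truth.hazard_beta
    beta_h = np.array([hb["resource_use"], hb["predation_risk"], hb["birth_mass"],
                       hb["winter_severity"], hb["mass_x_winter"]])
    daily_cov = {}
    for rec in fawns.itertuples(index=False):
        tel = telemetry[telemetry["fawn_id"] == rec.fawn_id]
        cells = grid.cell_index(tel["x"].to_numpy(), tel["y"].to_numpy())
        days = np.arange(rec.birth_doy + 1, syn.SEASON_END_DOY + 1)
        idx = np.clip(np.searchsorted(tel["doy"].to_numpy(), days, side="right") - 1,
                      0, len(tel) - 1)
        use = true_use[cells[idx]]
        rk = integrated[cells[idx]]
        w = wsi_map[rec.year]
        m_ctr = rec.birth_mass_kg - truth.mass_intercept_kg
        X = np.column_stack([
            use, rk, np.full(len(days), rec.birth_mass_kg),
            np.full(len(days), w), np.full(len(days), m_ctr * w),
        ])
        daily_cov[rec.fawn_id] = X

    fates = syn.gen_fates(
        _subseed(seed, 60), fawns, daily_cov, beta_h,
        frailty_var_fawn=0.0,  # fawn heterogeneity already enters via telemetry
        frailty_var_year=truth.frailty_var_year,
        baseline_hazard=truth.baseline_hazard,
    )
    return syn.SyntheticDataset(
        raster, roads, water, predators, weather, fawns, telemetry, fates,
        truth, grid=grid, greenness=greenness,
    )


def analyze(data: syn.SyntheticDataset, config: PipelineConfig) -> dict:
    """Run the full analysis on a (synthetic or loaded) study dataset."""
    config.validate()
    grid = data.grid
    report: dict = {}

    # --- covariates: used vs availability points on the grid ---------------
    used_xy = data.telemetry[["x", "y"]].to_numpy()
    avail_xy = draw_availability_points(used_xy, len(used_xy), _subseed(config.seed, 70))
    used_cells = grid.cell_index(used_xy[:, 0], used_xy[:, 1])
    avail_cells = grid.cell_index(avail_xy[:, 0], avail_xy[:, 1])
    rng = np.random.default_rng(_subseed(config.seed, 71))
    ua = pd.concat([
        pd.DataFrame({
            "used": 1, "fawn_id": data.telemetry["fawn_id"],
            "year": data.telemetry["year"], "cell_id": used_cells}),
        pd.DataFrame({
            "used": 0,
            "fawn_id": data.telemetry["fawn_id"].sample(
                frac=1.0, random_state=int(rng.integers(2**31))).to_numpy(),
            "year": data.telemetry["year"].sample(
                frac=1.0, random_state=int(rng.integers(2**31))).to_numpy(),
            "cell_id": avail_cells}),
    ], ignore_index=True)
    cell_cov = grid.cells.set_index("cell_id")[RSF_COVARIATES]
    ua = ua.join(cell_cov, on="cell_id")
    ua = ua.dropna(subset=RSF_COVARIATES).reset_index(drop=True)

    ua_std, rsf_standardizer = standardize(ua, RSF_COVARIATES)
    rsf_cols = rsf_standardizer.columns
    vif = vif_screen(ua_std, rsf_cols, config.vif_threshold)
    retained = vif.loc[vif["retained"], "covariate"].tolist()
    report["vif"] = vif

    # --- RSF model set and suitability surface -----------------------------
    models = evaluate_model_set(ua_std, retained, alpha=config.alpha)
    report["rsf_models"] = models
    top = models.iloc[0]["fit"]
    report["rsf_top"] = top
    surface = suitability_score(grid.cells, top, grid, rsf_standardizer)
    report["suitability"] = surface

    # --- risk, winter severity, greenness ----------------------------------
    risk_surface = risk_mod.integrate_risk(data.predator_surfaces)
    wsi = risk_mod.annual_wsi(data.weather)
    green = pd.concat(
        [risk_mod.greenness_summary(v, yr) for yr, v in data.greenness.items()],
        ignore_index=True,
    )
    report["risk"] = risk_surface
    report["wsi"] = wsi
    report["greenness"] = green

    # --- interval construction ---------------------------------------------
    tel = data.telemetry.copy()
    tel_cells = grid.cell_index(tel["x"].to_numpy(), tel["y"].to_numpy())
    tel["resource_use"] = surface.stretched[tel_cells]
    tel["predation_risk"] = risk_surface.integrated[tel_cells]
    year_attr = (
        wsi.set_index("year")["centered"].rename("winter_severity").to_frame()
        .join(green.set_index("year")["mean"].rename("hiding_cover"))
    )

    intervals = {}
    for mode in ("daily", "seasonal"):
        iv = build_intervals(data.fawns, data.fates, tel,
                             ["resource_use", "predation_risk"], mode=mode,
                             seasonal_stat=config.seasonal_stat)
        iv = iv.join(year_attr, on="year")
        iv = iv.rename(columns={"birth_mass_kg": "birth_mass"})
        n0 = len(iv)
        iv = iv.dropna(subset=HAZARD_COVARIATES).reset_index(drop=True)
        iv.attrs["n_dropped_missing"] = n0 - len(iv)
        iv_std, st = standardize(iv, HAZARD_COVARIATES)
        iv_std = add_interaction_columns(iv_std)
        iv_std.attrs["standardizer"] = st
        intervals[mode] = iv_std
    report["intervals"] = intervals

    # --- baseline survival and year comparison -----------------------------
    seasonal = intervals["seasonal"]
    report["km"] = km_fit(seasonal, by="year")
    report["logrank"] = logrank(seasonal, by="year")
    report["km_end_of_season"] = {
        yr: curve.at(syn.SEASON_END_DOY) for yr, curve in report["km"].items()
    }

    # --- model suites -------------------------------------------------------
    report["suite_daily"] = run_suite(intervals["daily"])
    report["suite_seasonal"] = run_suite(intervals["seasonal"])

    # --- spatial mortality prediction --------------------------------------
    daily_suite = report["suite_daily"]
    row = daily_suite[daily_suite["model"] == "non_ideal_use + maternal_effects"]
    map_fit = (row.iloc[0]["fit"] if len(row) else daily_suite.iloc[0]["fit"])
    st = intervals["daily"].attrs["standardizer"]
    cell_cov = pd.DataFrame({
        "resource_use": surface.stretched,
        "predation_risk": risk_surface.integrated,
    })
    for c in ("resource_use", "predation_risk"):
        cell_cov[c] = (cell_cov[c] - st.means[c]) / st.sds[c]
    report["mortality"] = mortality_map(
        map_fit, intervals["daily"], grid, cell_cov
    )
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, analyze, and write every artifact plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "artifacts": {}}

    stage = "synthesize"
    try:
        data = simulate_study(config)
        write_ascii_grid(out / "vegetation.asc", data.raster.values,
                         data.raster.origin, data.raster.pixel_size)
        write_wkt_lines(out / "roads.wkt", data.roads)
        write_wkt_lines(out / "water.wkt", data.water)
        data.weather.to_csv(out / "weather.csv", index=False)
        data.fawns.to_csv(out / "fawns.csv", index=False)
        data.telemetry.to_csv(out / "telemetry.csv", index=False)
        data.fates.to_csv(out / "fates.csv", index=False)
        manifest["stages"][stage] = "ok"

        stage = "analyze"
        report = analyze(data, config)
        data.grid.cells.to_csv(out / "grid_covariates.csv", index=False)
        report["wsi"].to_csv(out / "wsi.csv", index=False)
        pd.DataFrame({
            "cell_id": np.arange(data.grid.n_cells),
            "suitability": report["suitability"].stretched,
            "integrated_risk": report["risk"].integrated,
        }).to_csv(out / "suitability.csv", index=False)
        for mode in ("daily", "seasonal"):
            rows = []
            for _, r in report[f"suite_{mode}"].iterrows():
                fit = r["fit"]
                for par, coef, se, p, hr in zip(
                        fit.covariates, fit.coef, fit.se, fit.pvalues,
                        fit.hazard_ratios):
                    rows.append({"model": r["model"], "parameter": par,
                                 "coefficient": coef, "se": se, "p": p,
                                 "hazard_ratio": hr,
                                 "deviance_explained": r["deviance_explained"],
                                 "loglik_chi2": r["loglik_chi2"],
                                 "model_p": r["model_p"]})
                if not fit.covariates:
                    rows.append({"model": r["model"], "parameter": "-",
                                 "deviance_explained": r["deviance_explained"],
                                 "loglik_chi2": r["loglik_chi2"],
                                 "model_p": r["model_p"]})
            pd.DataFrame(rows).to_csv(out / f"suite_{mode}.csv", index=False)
        report["mortality"].table.to_csv(out / "mortality_map.csv", index=False)
        km_rows = []
        for yr, c in report["km"].items():
            for t, s, se in zip(c.times, c.survival, c.se):
                km_rows.append({"year": yr, "time": t, "S": s, "SE": se})
        pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["artifacts"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest"] = manifest
    return report
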