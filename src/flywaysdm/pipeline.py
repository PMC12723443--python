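"""End-to-end orchestration: simulate -> screen -> fit -> stack ->
importance -> preference -> landscape -> gaps, with one root seed,
deterministic per-stage seeds, and a JSON run manifest.

Per-stage seeds are derived as ``crc32(root_seed:stage:name)`` so adding a
species or group never perturbs another's results.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .raster import (
    OccurrenceSet,
    RasterLayer,
    RasterStack,
    dedup_grid,
    read_ascii_grid,
    read_occurrences_csv,
    write_ascii_grid,
    write_occurrences_csv,
)
from .synthetic import LandscapeConfig, SyntheticBundle, generate_bundle
from .maxent import build_features, evaluate_subsample, fit, percent_contribution, sample_background
from .screening import pearson_at_points, select_variables
from .stacking import build_group_suitability, stack_richness, classify_hotspots, unique_group_cells
from .importance import assemble_design, fit_gbt
from .preference import rf_index
from .landscape import exposure_summary, shannon_window
from .terrain import terrain_profiles
from .gaps import regional_overlay

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_inputs"]


def stage_seed(root_seed: int, stage: str, name: str = "") -> int:
    return zlib.crc32(f"{root_seed}:{stage}:{name}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their protocol defaults."""

    # synthetic landscape (used when no input directory is given)
    nrows: int = 96
    ncols: int = 96
    cellsize: float = 300.0
    n_env_layers: int = 6
    n_groups: int = 3
    n_species_per_group: int = 2
    n_occurrences_per_group: int = 300
    driver_coefficient: float = 2.0

    # occurrences
    dedup_cellsize: float = 1000.0

    # screening
    r_threshold: float = 0.8
    contribution_threshold: float = 10.0  # percent

    # maxent evaluation
    n_background: int = 10000
    train_fraction: float = 0.75
    n_replicates: int = 10
    auc_min: float = 0.90
    cv_max: float = 0.15
    feature_classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    beta_multiplier: float = 1.0

    # boosted trees
    gbt_split: float = 0.7
    gbt_folds: int = 5
    gbt_sample_cap: int = 100_000

    # landscape metrics
    window_edge: float = 900.0
    density_window: float = 1000.0
    shei_basis: str = "window"

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_fraction", "gbt_split"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must lie in (0,1]")
        for name in ("contribution_threshold", "n_background", "window_edge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_inputs(input_dir: str | Path) -> tuple[RasterStack, OccurrenceSet, RasterLayer, RasterLayer]:
    """Read a run directory: every ``layer_*.asc`` plus occurrences, reserves
    and regions, as written by the simulate stage."""
    d = Path(input_dir)
    layers = []
    for p in sorted(d.glob("layer_*.asc")):
        name = p.stem.removeprefix("layer_")
        kind = "categorical" if name in ("lc", "reserves", "regions") else "continuous"
        layers.append(read_ascii_grid(p, name=name, kind=kind))
    stack = RasterStack(layers)
    occ = read_occurrences_csv(d / "occurrences.csv", stack.grid)
    reserves = read_ascii_grid(d / "reserves.asc", name="reserves", kind="categorical")
    regions = read_ascii_grid(d / "regions.asc", name="regions", kind="categorical")
    return stack, occ, reserves, regions


def _write_bundle(bundle: SyntheticBundle, out: Path) -> None:
    for lyr in bundle.stack:
        write_ascii_grid(lyr, out / f"layer_{lyr.name}.asc")
    write_occurrences_csv(bundle.occurrences, out / "occurrences.csv")
    write_ascii_grid(bundle.reserves, out / "reserves.asc")
    write_ascii_grid(bundle.regions, out / "regions.asc")
    manifest = dict(
        kind="synthetic_bundle",
        config=asdict(bundle.config) | {"target_correlation": None},
        groups=[
            dict(name=g.name, coefficients=g.coefficients, intercept=g.intercept)
            for g in bundle.groups
        ],
    )
    (out / "bundle_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    write_rasters: bool = True,
) -> dict:
    """Run every stage; returns a results dict and writes CSV ledgers,
    rasters, and ``manifest.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    # ------------------------------------------------------------- simulate
    bundle = None
    with stage("simulate"):
        if input_dir is None:
            lc_conf = LandscapeConfig(
                nrows=config.nrows,
                ncols=config.ncols,
                cellsize=config.cellsize,
                n_env_layers=config.n_env_layers,
                seed=stage_seed(config.seed, "simulate"),
            )
            from .synthetic import default_groups

            bundle = generate_bundle(
                lc_conf,
                groups=default_groups(config.n_groups, config.driver_coefficient),
                n_occurrences_per_group=config.n_occurrences_per_group,
                n_species_per_group=config.n_species_per_group,
            )
            stack, occ, reserves, regions = (
                bundle.stack,
                bundle.occurrences,
                bundle.reserves,
                bundle.regions,
            )
            if write_rasters:
                _write_bundle(bundle, out)
        else:
            stack, occ, reserves, regions = load_inputs(input_dir)

    occ = dedup_grid(occ, config.dedup_cellsize)
    groups = list(dict.fromkeys(occ.df["group"]))
    env_vars = [n for n in stack.names if n.startswith("env")]
    model_vars = env_vars + [n for n in ("dem", "slo", "ndvi") if n in stack]

    # ------------------------------------------------------------- screening
    screening_rows = []
    kept_vars: dict[str, list[str]] = {}
    prelim_contrib: dict[str, dict[str, float]] = {}
    with stage("screen"):
        rng_names = sorted(occ.species)
        for sp in rng_names:
            occ_sp = occ.for_species(sp)
            s = stage_seed(config.seed, "screen", sp)
            rng = np.random.default_rng(s)
            valid = stack.finite_mask(model_vars)
            bg = sample_background(stack.grid, valid, config.n_background, rng)
            pr, pc = occ_sp.unique_cells(stack.grid)
            on = valid[pr, pc]
            pr, pc = pr[on], pc[on]
            fs = build_features(stack, (pr, pc), bg, config.feature_classes, model_vars)
            f_bg = fs.transform(stack.values_at_cells(bg[0], bg[1], fs.variables))
            f_pr = fs.transform(stack.values_at_cells(pr, pc, fs.variables))
            mdl = fit(fs, f_pr, f_bg, beta_multiplier=config.beta_multiplier)
            contrib = percent_contribution(mdl)
            prelim_contrib[sp] = contrib
            corr = pearson_at_points(stack, occ_sp, list(contrib))
            res = select_variables(contrib, corr, config.r_threshold)
            kept_vars[sp] = res.kept
            df = res.to_frame()
            df.insert(0, "species", sp)
            screening_rows.append(df)
        screening_df = pd.concat(screening_rows, ignore_index=True)
        screening_df.to_csv(out / "screening.csv", index=False)
    results["screening"] = screening_df

    # ------------------------------------------------------------- fit
    reports = {}
    with stage("fit"):
        eval_rows = []
        contrib_rows = []
        jack_rows = []
        for sp in sorted(occ.species):
            occ_sp = occ.for_species(sp)
            rep = evaluate_subsample(
                stack,
                occ_sp,
                variables=kept_vars[sp],
                n_background=config.n_background,
                train_fraction=config.train_fraction,
                n_replicates=config.n_replicates,
                seed=stage_seed(config.seed, "fit", sp),
                classes=config.feature_classes,
                beta_multiplier=config.beta_multiplier,
                auc_min=config.auc_min,
                cv_max=config.cv_max,
            )
            reports[sp] = rep
            eval_rows.append(
                dict(species=sp, auc_mean=rep.auc_mean, auc_sd=rep.auc_sd, cv=rep.cv,
                     n_presence_cells=rep.n_presence_cells, excluded=rep.excluded)
            )
            for v, c in sorted(rep.contributions.items()):
                contrib_rows.append(dict(species=sp, variable=v, contribution=c))
            for v, (g_only, g_without) in sorted(rep.jackknife.items()):
                jack_rows.append(
                    dict(species=sp, variable=v, gain_with_only=g_only, gain_without=g_without)
                )
            if write_rasters:
                write_ascii_grid(rep.mean_map, out / f"suitability_{sp}.asc")
        eval_df = pd.DataFrame(eval_rows)
        eval_df.to_csv(out / "evaluation.csv", index=False)
        pd.DataFrame(contrib_rows).to_csv(out / "contributions.csv", index=False)
        pd.DataFrame(jack_rows).to_csv(out / "jackknife.csv", index=False)
    results["evaluation"] = eval_df
    results["reports"] = reports
    excluded = set(eval_df.loc[eval_df["excluded"], "species"])

    # ------------------------------------------------------------- stack
    group_suit = {}
    with stage("stack"):
        sp_to_group = dict(zip(occ.df["species"], occ.df["group"]))
        for grp in groups:
            maps = {
                sp: reports[sp].mean_map
                for sp in reports
                if sp_to_group.get(sp) == grp and sp not in excluded
            }
            if not maps:
                continue
            group_suit[grp] = build_group_suitability(
                grp, maps, density_window=config.density_window,
                seed=stage_seed(config.seed, "stack", grp),
            )
            if write_rasters:
                gs = group_suit[grp]
                write_ascii_grid(gs.richness, out / f"richness_{grp}.asc")
                write_ascii_grid(gs.hotspot3, out / f"hotspot3_{grp}.asc")
                write_ascii_grid(gs.suitable_mask, out / f"suitable_{grp}.asc")
                write_ascii_grid(gs.density, out / f"density_{grp}.asc")
        if group_suit:
            all_binaries = [gs.suitable_mask for gs in group_suit.values()]
            overall_richness = stack_richness(
                [b for gs in group_suit.values() for b in gs.species_binary.values()]
            )
            overall_hotspot = classify_hotspots(
                overall_richness, seed=stage_seed(config.seed, "stack", "overall")
            )
            uniq, uniq_codes = unique_group_cells(
                {g: gs.suitable_mask for g, gs in group_suit.items()}
            )
            if write_rasters:
                write_ascii_grid(overall_richness, out / "richness_overall.asc")
                write_ascii_grid(overall_hotspot, out / "hotspot3_overall.asc")
                write_ascii_grid(uniq, out / "unique_groups.asc")
            results["overall_richness"] = overall_richness
            results["overall_hotspot"] = overall_hotspot
    results["group_suitability"] = group_suit

    # ------------------------------------------------------------- importance
    importance_rows = []
    with stage("importance"):
        sp_to_group = dict(zip(occ.df["species"], occ.df["group"]))
        for grp, gs in group_suit.items():
            contribs = [
                reports[sp].contributions
                for sp in reports
                if sp_to_group.get(sp) == grp and sp not in excluded
            ]
            vars_over = sorted(
                {
                    v
                    for c in contribs
                    for v, pct in c.items()
                    if v in env_vars and pct > config.contribution_threshold
                }
            )
            if not vars_over:
                # fall back to the two highest-contribution climate variables
                pooled: dict[str, float] = {}
                for c in contribs:
                    for v, pct in c.items():
                        if v in env_vars:
                            pooled[v] = pooled.get(v, 0.0) + pct
                vars_over = sorted(pooled, key=pooled.get, reverse=True)[:2]
            try:
                design = assemble_design(
                    gs.suitable_mask, stack, vars_over,
                    sample_cap=config.gbt_sample_cap,
                    seed=stage_seed(config.seed, "importance", grp), group=grp,
                )
                report = fit_gbt(
                    design, split=config.gbt_split, cv_folds=config.gbt_folds,
                    seed=stage_seed(config.seed, "importance-fit", grp),
                )
            except ValueError as err:
                importance_rows.append(
                    dict(group=grp, variable="", gain_mean=np.nan, gain_sd=np.nan,
                         overall_accuracy=np.nan, note=str(err))
                )
                continue
            for v in vars_over:
                importance_rows.append(
                    dict(group=grp, variable=v, gain_mean=report.gain_mean[v],
                         gain_sd=report.gain_sd[v],
                         overall_accuracy=report.overall_accuracy, note="")
                )
            results.setdefault("importance_reports", {})[grp] = report
        pd.DataFrame(importance_rows).to_csv(out / "importance.csv", index=False)
    results["importance"] = pd.DataFrame(importance_rows)

    # ------------------------------------------------------------- preference
    with stage("preference"):
        pref_frames = []
        for grp, gs in group_suit.items():
            if "lc" in stack:
                pref_frames.append(rf_index(occ, gs.suitable_mask, stack["lc"], grp))
        pref_df = pd.concat(pref_frames, ignore_index=True) if pref_frames else pd.DataFrame()
        pref_df.to_csv(out / "preference.csv", index=False)
        terrain_layers = {n: stack[n] for n in ("dem", "slo", "asp", "ndvi") if n in stack}
        prof_df = terrain_profiles(
            {g: gs.suitable_mask for g, gs in group_suit.items()}, terrain_layers
        )
        prof_df.to_csv(out / "terrain_profiles.csv", index=False)
    results["preference"] = pref_df
    results["terrain_profiles"] = prof_df

    # ------------------------------------------------------------- landscape
    with stage("landscape"):
        if "lc" in stack:
            wm = shannon_window(stack["lc"], config.window_edge, config.shei_basis)
            if write_rasters:
                write_ascii_grid(wm.shdi, out / "shdi.asc")
                write_ascii_grid(wm.shei, out / "shei.asc")
            results["window_metrics"] = wm
        exp_frames = []
        masks = {g: gs.suitable_mask for g, gs in group_suit.items()}
        for ind in ("net", "pop"):
            if ind in stack and masks:
                exp_frames.append(exposure_summary(stack[ind], masks))
        exp_df = pd.concat(exp_frames, ignore_index=True) if exp_frames else pd.DataFrame()
        exp_df.to_csv(out / "exposure.csv", index=False)
    results["exposure"] = exp_df

    # ------------------------------------------------------------- gaps
    with stage("gaps"):
        if group_suit:
            union = np.zeros(stack.grid.shape)
            for gs in group_suit.values():
                union = np.maximum(union, np.nan_to_num(gs.suitable_mask.values))
            union_layer = RasterLayer(stack.grid, "suitable_all", union, "categorical")
            gap_df = regional_overlay(union_layer, reserves, regions)
        else:
            gap_df = pd.DataFrame()
        gap_df.to_csv(out / "gap_report.csv", index=False)
    results["gap_report"] = gap_df

    manifest["excluded_species"] = sorted(excluded)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    results["stack"] = stack
    results["occurrences"] = occ
    if bundle is not None:
        results["bundle"] = bundle
    return results
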