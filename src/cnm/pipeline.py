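"""End-to-end orchestration of the niche-modelling workflow.

One configuration drives the whole chain: ingest (or synthesize) occurrences
and climate stacks, filter urban records, thin by overlapping buffers,
extract environments, prune correlated variables, calibrate the bootstrap
ensemble, project and classify every scenario, screen with MESS, and run the
identity-line regression test. A single master seed derives every stage seed
through a stable hashing scheme, so a rerun with the same configuration
reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data
from .change_analysis import ols_fit, pair_probabilities, regression_table, test_against_theory
from .evaluation_ensemble import (
    EnsembleConfig,
    jackknife_gains,
    permutation_contribution,
    run_ensemble,
)
from .grids import EnvGrid, GridStack, extract_values, read_grid, write_grid
from .occurrences import (
    count_presences_per_decile,
    filter_urban,
    read_occurrences,
    retained_points,
    thin_buffers,
)
from .scenario_analysis import (
    ScenarioResult,
    analyse_scenario,
    class_fractions,
    classify,
    scenario_summary,
    zonal_overlap,
)
from .variable_selection import select_variables, spearman_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Stage seed from the master seed: stable under stage insertion."""
    digest = hashlib.sha256(f"{master_seed}|{stage}|{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``synthetic`` (generator settings) and ``paths`` (input
    file locations) must be given. Defaults follow the standard protocol:
    2.5-km thinning, |rho| > 0.60 pruning, 75/25 bootstrap splits, 100 runs,
    0.1/0.5 habitat thresholds, 10 000 regression points, alpha 0.05.
    """

    synthetic: dict[str, Any] | None = None
    paths: dict[str, Any] | None = None
    thin_radius_km: float = 2.5
    corr_threshold: float = 0.60
    use_absolute: bool = True
    n_runs: int = 100
    train_fraction: float = 0.75
    background_n: int = 10000
    reg_multiplier: float = 1.0
    feature_kinds: tuple[str, ...] | None = None
    replicate_mode: str = "bootstrap"
    t_low: float = 0.1
    t_high: float = 0.5
    change_n: int = 10000
    alpha: float = 0.05
    run_mess: bool = True
    run_jackknife: bool = True
    grid_format: str = "esri_ascii"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'paths' must be configured"
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0.0 < self.t_low < self.t_high < 1.0):
            raise ValueError("need 0 < t_low < t_high < 1")
        if self.thin_radius_km <= 0:
            raise ValueError("thin_radius_km must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "feature_kinds" in doc and doc["feature_kinds"] is not None:
            doc["feature_kinds"] = tuple(doc["feature_kinds"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["feature_kinds"] is not None:
            d["feature_kinds"] = list(d["feature_kinds"])
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    occurrences: pd.DataFrame
    selected_variables: list[str]
    ensemble: Any
    current: ScenarioResult
    scenarios: list[ScenarioResult]
    regression: pd.DataFrame
    manifest: dict


def _load_world(config: PipelineConfig) -> synthetic_data.SyntheticWorld:
    spec = dict(config.synthetic or {})
    spec.setdefault("seed", derive_seed(config.master_seed, "world"))
    return synthetic_data.make_world(**spec)


def _load_inputs(config: PipelineConfig):
    """Current stack, scenario stacks, zones, urban mask and raw occurrences."""
    if config.synthetic is not None:
        world = _load_world(config)
        scen = [
            (d.label, d.forcing, stack) for d, stack in world.futures
        ]
        return (world.current, scen, world.zones, world.urban_mask,
                world.occurrences, world)
    paths = config.paths or {}
    current = GridStack(
        {name: read_grid(p) for name, p in paths["current_layers"].items()}
    )
    scen = []
    for s in paths.get("scenarios", []):
        stack = GridStack({name: read_grid(p) for name, p in s["layers"].items()})
        scen.append((s["label"], s.get("forcing"), stack))
    zones = read_grid(paths["zones"]) if "zones" in paths else None
    urban = read_grid(paths["urban_mask"]) if "urban_mask" in paths else None
    occ = read_occurrences(
        paths["occurrences"],
        lon_column=paths.get("lon_column", "decimalLongitude"),
        lat_column=paths.get("lat_column", "decimalLatitude"),
    )
    return current, scen, zones, urban, occ, None


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute every stage in order and write grids, CSV reports, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".asc" if config.grid_format == "esri_ascii" else ".tif"
    stage = "ingest"
    try:
        current, scenario_stacks, zones, urban, occ, world = _load_inputs(config)

        stage = "filter_urban"
        if urban is not None:
            occ = filter_urban(occ, urban)

        stage = "thin"
        occ = thin_buffers(
            occ, config.thin_radius_km, seed=derive_seed(config.master_seed, "thin")
        )
        occ.to_csv(out / "occurrences_cleaned.csv", index=False)
        logger.info(
            "occurrences: %d retained of %d", int(occ["retained"].sum()), len(occ)
        )

        stage = "extract"
        values = extract_values(current, retained_points(occ))

        stage = "select"
        corr = spearman_matrix(values)
        corr.to_frame().to_csv(out / "correlation_matrix.csv")
        selected, sel_report = select_variables(
            corr, config.corr_threshold, config.use_absolute
        )
        sel_report.to_csv(out / "selection_report.csv", index=False)
        logger.info("selected variables: %s", selected)

        stage = "ensemble"
        ens_config = EnsembleConfig(
            n_runs=config.n_runs,
            train_fraction=config.train_fraction,
            background_n=config.background_n,
            reg_multiplier=config.reg_multiplier,
            feature_kinds=config.feature_kinds,
            replicate_mode=config.replicate_mode,
        )
        ensemble = run_ensemble(
            occ, current, selected, ens_config,
            seed=derive_seed(config.master_seed, "ensemble"),
        )
        ensemble.report().to_csv(out / "ensemble_report.csv", index=False)
        write_grid(ensemble.integrated, out / f"probability_current{suffix}",
                   config.grid_format)

        stage = "importance"
        ref_model = ensemble.runs[0].model
        contrib = permutation_contribution(
            ref_model,
            ensemble.presence_table.reset_index(drop=True),
            ensemble.background_table[selected],
            seed=derive_seed(config.master_seed, "importance"),
        )
        contrib.to_csv(out / "contributions.csv", index=False)
        if config.run_jackknife and len(selected) >= 2:
            jk = jackknife_gains(
                occ, current, selected, ens_config,
                seed=derive_seed(config.master_seed, "jackknife"),
            )
            jk_df = jk.per_variable.copy()
            jk_df["full_gain"] = jk.full_gain
            jk_df.to_csv(out / "jackknife.csv", index=False)

        stage = "classify_current"
        current_result = analyse_scenario(
            ensemble, current.subset(selected), "current", None,
            config.t_low, config.t_high, run_mess=False,
        )
        write_grid(current_result.classes, out / f"classes_current{suffix}",
                   config.grid_format)
        deciles = count_presences_per_decile(occ, current_result.probability)
        deciles.to_csv(out / "presence_deciles.csv", index=False)
        if zones is not None:
            zo = zonal_overlap(current_result.classes, zones)
            zo.to_csv(out / "zonal_overlap_current.csv", index=False)

        stage = "scenarios"
        results: list[ScenarioResult] = []
        for label, forcing, stack in scenario_stacks:
            res = analyse_scenario(
                ensemble, stack.subset(selected), label, forcing,
                config.t_low, config.t_high, run_mess=config.run_mess,
            )
            tag = label.replace(" ", "_")
            write_grid(res.probability, out / f"probability_{tag}{suffix}",
                       config.grid_format)
            write_grid(res.classes, out / f"classes_{tag}{suffix}",
                       config.grid_format)
            if res.mess_mean is not None:
                write_grid(res.mess_mean, out / f"mess_{tag}{suffix}",
                           config.grid_format)
            results.append(res)
        summary = scenario_summary([current_result] + results)
        summary.to_csv(out / "scenario_summary.csv", index=False)

        stage = "change_test"
        change_seed = derive_seed(config.master_seed, "change")
        reports = {}
        decisions = {}
        for res in results:
            pairs = pair_probabilities(
                current_result.probability, res.probability,
                n=config.change_n, seed=change_seed,
            )
            rep = ols_fit(pairs)
            reports[res.label] = rep
            decisions[res.label] = test_against_theory(
                rep, alpha=config.alpha,
                mean_pc=float(pairs["p_current"].mean()),
            )
        reg_table = regression_table(reports, alpha=config.alpha)
        reg_table["expansion"] = [
            decisions[lab]["expansion"] for lab in reg_table["scenario"]
        ]
        reg_table.to_csv(out / "regression_table.csv", index=False)

        stage = "manifest"
        outputs = sorted(
            p.name for p in out.iterdir()
            if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "config": config.to_dict(),
            "master_seed": config.master_seed,
            "stage_seeds": {
                s: derive_seed(config.master_seed, s)
                for s in ("world", "thin", "ensemble", "importance",
                          "jackknife", "change")
            },
            "selected_variables": selected,
            "n_retained_presences": int(occ["retained"].sum()),
            "auc_mean": ensemble.auc_mean,
            "auc_se": ensemble.auc_se,
            "output_hashes": {name: _hash_file(out / name) for name in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        out_dir=out,
        occurrences=occ,
        selected_variables=selected,
        ensemble=ensemble,
        current=current_result,
        scenarios=results,
        regression=reg_table,
        manifest=manifest,
    )
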