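"""End-to-end orchestration: simulate -> screen -> split -> grid-search ->
calibrate -> validate -> correlate -> report.

A run is driven by a :class:`RunConfig` (YAML/JSON on disk).  Every stage
writes plain CSV/JSON artifacts into the run's output directory, and a
single run manifest records the config hash, the per-stage seeds (derived
deterministically from the master seed) and the SHA-256 of every artifact,
so any numeric table can be regenerated bit-identically from the manifest
alone.  One trait = one independent single-response model run, matching the
per-row structure of conventional calibration tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nirscal import synthgen
from nirscal.correlate import DEFAULT_FEATURES, DEFAULT_YIELDS, correlation_panel
from nirscal.datasets import InputError, SpectraDataset
from nirscal.modelstats import (
    evaluate_recipe,
    external_validate,
    grid_search,
    split_calibration_validation,
)
from nirscal.outliers import DEFAULT_SCREEN_RECIPE, ModelRecipe, screen
from nirscal.preprocess import DEFAULT_DERIVATIVE_CODES, DEFAULT_RANGES, apply_recipe
from nirscal.modelstats import DEFAULT_SCATTER_METHODS

log = logging.getLogger("nirscal")

_STAGES = ("simulate", "screen", "split", "cv_folds", "correlate")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    output_dir: str = "nirscal_run"
    # either a simulation block or input CSV paths
    simulation: dict | None = dataclasses.field(
        default_factory=lambda: {"n": 247, "n_outliers": 7, "outlier_magnitude": 6.0}
    )
    input: dict | None = None           # {"spectra": path, "traits": path}
    screening: dict = dataclasses.field(
        default_factory=lambda: {
            "gh_cutoff": 3.0,
            "variance_target": 0.9981,
            "recipe": DEFAULT_SCREEN_RECIPE.token(),
        }
    )
    split: dict = dataclasses.field(default_factory=lambda: {"n_validation": 93})
    traits: list[str] = dataclasses.field(default_factory=lambda: list(DEFAULT_YIELDS) + list(DEFAULT_FEATURES))
    grid: dict = dataclasses.field(
        default_factory=lambda: {
            "derivatives": [list(c) for c in DEFAULT_DERIVATIVE_CODES],
            "scatter_methods": list(DEFAULT_SCATTER_METHODS),
            "ranges": [list(r) for r in DEFAULT_RANGES],
        }
    )
    cv: dict = dataclasses.field(default_factory=lambda: {"n_groups": 4, "max_factors": 15})
    correlation: dict = dataclasses.field(
        default_factory=lambda: {"features": list(DEFAULT_FEATURES), "yields": list(DEFAULT_YIELDS)}
    )

    def validate(self) -> None:
        if self.simulation is None and self.input is None:
            raise InputError("config needs a simulation block or input paths")
        if not self.traits:
            raise InputError("config trait list is empty")
        if not (self.grid.get("derivatives") and self.grid.get("scatter_methods")
                and self.grid.get("ranges")):
            raise InputError("pretreatment grid must be non-empty")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds spawned deterministically from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STAGES, children)
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_simulate(config: RunConfig, seeds: dict, outdir: Path) -> SpectraDataset:
    if config.input is not None:
        ds = SpectraDataset.from_csv(config.input["spectra"], config.input.get("traits"))
        log.info("loaded %d samples x %d wavelengths", ds.n_samples, ds.n_wavelengths)
        return ds
    sim = config.simulation
    ds = synthgen.simulate_population(
        n=sim.get("n", 247),
        n_outliers=sim.get("n_outliers", 7),
        outlier_magnitude=sim.get("outlier_magnitude", 6.0),
        seed=seeds["simulate"],
    )
    ds.to_csv(
        outdir / "spectra.csv",
        traits_path=outdir / "traits.csv",
        sidecar_path=outdir / "simulation.json",
        meta={"seed": seeds["simulate"], "config_hash": config.config_hash(),
              "injected_outliers": sorted(ds.outlier_truth)},
    )
    log.info("simulated %d samples (%d injected outliers)", ds.n_samples, sim.get("n_outliers", 7))
    return ds


def run_full(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest (also written)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "artifacts": {},
        "stages": {},
    }

    def _register(path: Path) -> None:
        manifest["artifacts"][path.name] = _sha256(path)

    def _stage(name):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        return t0

    try:
        # ---- simulate / load
        t0 = _stage("simulate")
        ds = _load_or_simulate(config, seeds, outdir)
        manifest["stages"]["simulate"] = {"seconds": round(time.perf_counter() - t0, 3),
                                          "n_samples": ds.n_samples}

        # ---- screen
        t0 = _stage("screen")
        scr = config.screening
        kept, report = screen(
            ds,
            recipe=ModelRecipe.from_token(scr.get("recipe", DEFAULT_SCREEN_RECIPE.token())),
            gh_cutoff=scr.get("gh_cutoff", 3.0),
            variance_target=scr.get("variance_target", 0.9981),
        )
        report.table.to_csv(outdir / "outlier_report.csv")
        _register(outdir / "outlier_report.csv")
        manifest["stages"]["screen"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_components": report.n_components,
            "eliminated": report.eliminated_ids,
            "n_kept": kept.n_samples,
        }
        log.info("screen kept %d of %d samples (GH > %.1f eliminated %d)",
                 kept.n_samples, ds.n_samples, report.cutoff, len(report.eliminated_ids))

        # ---- split
        t0 = _stage("split")
        cal, val, summary = split_calibration_validation(
            kept, config.split.get("n_validation", 93), seed=seeds["split"]
        )
        summary.to_csv(outdir / "split_summary.csv", index=False)
        _register(outdir / "split_summary.csv")
        manifest["stages"]["split"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_calibration": cal.n_samples,
            "n_validation": val.n_samples,
            "validation_ids": list(val.ids),
        }

        # ---- per-trait grid search + external validation
        t0 = _stage("train/validate")
        grid = config.grid
        cv = config.cv
        winners = []
        for trait in config.traits:
            table = grid_search(
                cal, trait,
                derivative_codes=[tuple(c) for c in grid["derivatives"]],
                scatter_methods=tuple(grid["scatter_methods"]),
                ranges=[tuple(r) for r in grid["ranges"]],
                max_factors=cv.get("max_factors", 15),
                n_groups=cv.get("n_groups", 4),
                seed=seeds["cv_folds"],
            )
            table.to_csv(outdir / f"grid_{trait}.csv", index=False)
            _register(outdir / f"grid_{trait}.csv")
            best = table[table.status == "ok"].iloc[0]
            recipe = ModelRecipe.from_token(best["recipe"])
            stats, model, state = evaluate_recipe(
                cal, recipe, trait,
                max_factors=cv.get("max_factors", 15),
                n_groups=cv.get("n_groups", 4),
                seed=seeds["cv_folds"],
            )
            r2ev, sep, rpd_ev = external_validate(
                model, val, trait, recipe, state=state, calibration_ids=set(cal.ids)
            )
            stats.r2ev, stats.sep, stats.rpd_ev = r2ev, sep, rpd_ev
            model.to_json(outdir / f"model_{trait}.json")
            _register(outdir / f"model_{trait}.json")
            # external-validation scatter data (reference vs predicted)
            pre, _ = apply_recipe(val, recipe, state=state)
            pd.DataFrame(
                {"sample_id": val.ids,
                 "reference": val.traits[trait].to_numpy(float),
                 "predicted": model.predict(pre.X)}
            ).to_csv(outdir / f"validation_scatter_{trait}.csv", index=False)
            _register(outdir / f"validation_scatter_{trait}.csv")
            winners.append({"trait": trait, **stats.as_row()})
            log.info("%s: %s Terms=%d R2cv=%.3f RPD=%.2f R2ev=%.3f",
                     trait, recipe.token(), stats.terms, stats.r2cv, stats.rpd, r2ev)
        pd.DataFrame(winners).to_csv(outdir / "calibration_table.csv", index=False)
        _register(outdir / "calibration_table.csv")
        manifest["stages"]["train_validate"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_traits": len(config.traits),
        }

        # ---- correlation panel
        t0 = _stage("correlate")
        corr = config.correlation
        if kept.traits is not None:
            panel = correlation_panel(
                kept.traits,
                features=tuple(corr.get("features", DEFAULT_FEATURES)),
                yields=tuple(corr.get("yields", DEFAULT_YIELDS)),
            )
            panel.to_long().to_csv(outdir / "correlation_panel.csv", index=False)
            _register(outdir / "correlation_panel.csv")
        manifest["stages"]["correlate"] = {"seconds": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "simulate"
        log.error("run aborted after stage %r: %s", stage, exc)
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def integrative_recalibrate(config: RunConfig, prior_dir) -> dict:
    """Merge a prior run's calibration and validation sets and recalibrate.

    Repeats the grid search and cross validation per trait on the pooled
    samples (no external validation stage — there is no held-out set left).
    """
    prior = Path(prior_dir)
    manifest_path = prior / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json under {prior}; run the pipeline first")
    prior_manifest = json.loads(manifest_path.read_text())
    if not (prior / "spectra.csv").exists():
        raise InputError(f"prior run at {prior} kept no spectra.csv artifact")
    ds = SpectraDataset.from_csv(prior / "spectra.csv", prior / "traits.csv")
    eliminated = set(prior_manifest["stages"]["screen"]["eliminated"])
    merged = ds.subset([i for i in ds.ids if i not in eliminated])
    log.info("integrative recalibration on %d pooled samples", merged.n_samples)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    grid, cv = config.grid, config.cv
    rows = []
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "prior_run": str(prior),
        "stage_seeds": seeds,
        "n_merged": merged.n_samples,
        "artifacts": {},
    }
    for trait in config.traits:
        table = grid_search(
            merged, trait,
            derivative_codes=[tuple(c) for c in grid["derivatives"]],
            scatter_methods=tuple(grid["scatter_methods"]),
            ranges=[tuple(r) for r in grid["ranges"]],
            max_factors=cv.get("max_factors", 15),
            n_groups=cv.get("n_groups", 4),
            seed=seeds["cv_folds"],
        )
        table.to_csv(outdir / f"integrative_grid_{trait}.csv", index=False)
        manifest["artifacts"][f"integrative_grid_{trait}.csv"] = _sha256(
            outdir / f"integrative_grid_{trait}.csv"
        )
        best = table[table.status == "ok"].iloc[0].to_dict()
        rows.append(best)
    pd.DataFrame(rows).to_csv(outdir / "integrative_calibration_table.csv", index=False)
    manifest["artifacts"]["integrative_calibration_table.csv"] = _sha256(
        outdir / "integrative_calibration_table.csv"
    )
    (outdir / "integrative_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
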