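"""Configuration and end-to-end orchestration.

A pipeline run executes: task build -> capacity-grid solve -> cohort
synthesis (or cohort CSV ingest) -> per-subject grid-search fits ->
group comparison -> behavioral-prediction regression, writing tidy CSV
tables, JSON summaries and a manifest with content hashes.  The same
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (SubjectSpec, cohort_from_frame, generate_cohort,
                     write_cohort)
from .information import Hypothesis, capacity_grid
from .regression import (behavior_correlation, compare_group,
                         fits_to_frame, grid_search_fit, loocv)
from .solver import SolverOptions
from .task import Condition, PanelGeometry, build_task


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.record = {"stage": stage, "error": str(cause)}


@dataclass
class PipelineConfig:
    task: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    output_dir: str = "runs/out"
    seed: int = 0

    @classmethod
    def from_file(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw):
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def resolved(self):
        return {
            "task": self.task, "solver": self.solver, "grid": self.grid,
            "cohort": self.cohort, "fitting": self.fitting,
            "output_dir": self.output_dir, "seed": self.seed,
            "version": __version__,
        }


def geometry_from_config(cfg):
    if not cfg:
        return PanelGeometry()
    kwargs = {}
    if "n_panels" in cfg:
        kwargs["n_panels"] = int(cfg["n_panels"])
    if "offsets_per_half" in cfg:
        kwargs["offsets_per_half"] = {
            int(d): tuple(tuple(o) for o in offs)
            for d, offs in cfg["offsets_per_half"].items()}
    if "conditions" in cfg:
        kwargs["conditions"] = tuple(
            Condition(str(cT), int(cS)) for cT, cS in cfg["conditions"])
    return PanelGeometry(**kwargs)


def solver_options_from_config(cfg):
    return SolverOptions(**(cfg or {}))


SMOKE_CONFIG = {
    "task": {
        "n_panels": 2,
        "offsets_per_half": {2: [[1, 1]]},
        "conditions": [["1", 2], ["11", 2], ["2", 2]],
    },
    "solver": {"tol": 1e-10, "max_iter": 5000},
    "grid": {"beta1_values": [5.0, 500.0], "beta2_values": [5.0, 500.0]},
    "cohort": {
        "n_subjects": 5, "hypothesis": "H1_prospective",
        "beta1": 500.0, "beta2": 500.0,
        "alpha0": 0.1, "alpha1": 1.0, "alpha2": 0.5,
        "link": "linear", "noise_sd": 0.05, "n_trials": 120,
    },
    "fitting": {"links": ["linear"], "n_shuffles": 200},
    "output_dir": "runs/smoke",
    "seed": 7,
}

DEFAULT_CONFIG = {
    "task": {},
    "solver": {"tol": 1e-9, "max_iter": 3000},
    "grid": {"beta1_values": [2.0, 20.0, 500.0],
             "beta2_values": [2.0, 20.0, 500.0]},
    "cohort": {
        "n_subjects": 19, "hypothesis": "H1_prospective",
        "beta1": 20.0, "beta2": 20.0,
        "alpha0": 0.1, "alpha1": 0.05, "alpha2": 0.01,
        "link": "linear", "noise_sd": "auto", "n_trials": 120,
    },
    "fitting": {"links": ["linear"], "n_shuffles": 2000},
    "output_dir": "runs/default",
    "seed": 1,
}


def _sha256(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_cohort_specs(cfg, seed):
    """Subject specs from the cohort config section (one hypothesis, one
    grid point by default; per-subject seeds derived from the run seed)."""
    n = int(cfg.get("n_subjects", 19))
    hyp = Hypothesis(cfg.get("hypothesis", "H1_prospective"))
    specs = []
    for i in range(n):
        specs.append(SubjectSpec(
            subject_id=f"sub-{i + 1:02d}", hypothesis=hyp,
            beta1=float(cfg.get("beta1", 500.0)),
            beta2=float(cfg.get("beta2", 500.0)),
            alpha0=float(cfg.get("alpha0", 0.0)),
            alpha1=float(cfg.get("alpha1", 1.0)),
            alpha2=float(cfg.get("alpha2", 1.0)),
            link=cfg.get("link", "linear"),
            noise_sd=float(cfg.get("noise_sd", 0.0)),
            n_trials=int(cfg.get("n_trials", 120)),
            seed=int(seed) * 10_000 + i,
            roi_label=cfg.get("roi_label", "synthetic-roi")))
    return specs


def resolve_noise_sd(cfg, grid):
    """'auto' noise = 25% of the across-condition spread of the
    noiseless betas at the cohort's generating grid point."""
    if cfg.get("noise_sd") != "auto":
        return cfg
    from .cohort import noiseless_betas
    probe = build_cohort_specs({**cfg, "noise_sd": 0.0}, seed=0)[0]
    profile = grid.get(probe.hypothesis, probe.beta1, probe.beta2)
    spread = float(np.std(noiseless_betas(probe, profile)))
    out = dict(cfg)
    out["noise_sd"] = 0.25 * spread
    return out


def run_pipeline(config, cohort_csv=None):
    """Execute every stage; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(config.resolved(), indent=1, sort_keys=True))

    try:
        geometry = geometry_from_config(config.task)
        task = build_task(geometry)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("task", e) from e

    try:
        opts = solver_options_from_config(config.solver)
        grid = capacity_grid(
            task, config.grid.get("beta1_values", [500.0]),
            config.grid.get("beta2_values", [500.0]),
            opts=opts, cache_dir=config.grid.get("cache_dir"))
        grid.to_frame().to_csv(out / "grid_profiles.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("grid", e) from e

    try:
        if cohort_csv:
            import pandas as pd
            records = cohort_from_frame(pd.read_csv(cohort_csv))
            manifest_subjects = {"ingested_from": str(cohort_csv)}
        else:
            cohort_cfg = resolve_noise_sd(config.cohort, grid)
            specs = build_cohort_specs(cohort_cfg, config.seed)
            records, manifest_subjects = generate_cohort(specs, grid)
        write_cohort(records, manifest_subjects,
                     out / "cohort.csv", out / "cohort_manifest.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cohort", e) from e

    try:
        links = config.fitting.get("links", ["linear"])
        fits, rows_eu = {h: [] for h in Hypothesis}, {}
        for rec in records:
            for hyp in Hypothesis:
                best_link = None
                for link in links:
                    res = grid_search_fit(rec, grid, hyp, link)
                    if best_link is None or res.best.R2 > best_link.best.R2:
                        best_link = res
                best_link.best.loocv_mse = loocv(
                    rec, grid.get(hyp, best_link.best.beta1,
                                  best_link.best.beta2),
                    best_link.best.link)
                fits[hyp].append(best_link)
            rows_eu[rec.subject_id] = rec.error_rate
        all_fits = [r.best for h in Hypothesis for r in fits[h]] + \
                   [r.not_bounded for h in Hypothesis for r in fits[h]
                    if r.not_bounded is not None]
        fits_to_frame(all_fits).to_csv(out / "fits.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", e) from e

    try:
        comparisons = {}
        h0b = [r.best for r in fits[Hypothesis.H0_DELAYED]]
        h1b = [r.best for r in fits[Hypothesis.H1_PROSPECTIVE]]
        comparisons["H1_vs_H0_R2"] = compare_group(
            h1b, h0b, method="paired_rmANOVA").__dict__
        nb = [r.not_bounded for r in fits[Hypothesis.H1_PROSPECTIVE]
              if r.not_bounded is not None]
        if len(nb) == len(h1b):
            comparisons["H1_bounded_vs_notbounded_R2"] = compare_group(
                h1b, nb, method="paired_rmANOVA").__dict__
        (out / "group_comparisons.json").write_text(
            json.dumps(comparisons, indent=1, sort_keys=True, default=str))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("compare", e) from e

    try:
        eu_pred = [grid.get(Hypothesis.H1_PROSPECTIVE, r.best.beta1,
                            r.best.beta2).EU
                   for r in fits[Hypothesis.H1_PROSPECTIVE]]
        errs = [rows_eu[r.best.subject_id]
                for r in fits[Hypothesis.H1_PROSPECTIVE]]
        n_shuffles = int(config.fitting.get("n_shuffles", 0))
        if np.ptp(eu_pred) > 0 and np.ptp(errs) > 0:
            bc = behavior_correlation(eu_pred, errs, n_shuffles=n_shuffles,
                                      seed=config.seed).__dict__
        else:
            bc = {"skipped": "degenerate predicted/observed variance"}
        (out / "behavior_correlation.json").write_text(
            json.dumps(bc, indent=1, sort_keys=True))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("predict-behavior", e) from e

    files = sorted(p.name for p in out.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "version": __version__, "seed": config.seed,
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
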