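"""End-to-end pipeline: phantom -> quantify -> cobb -> raters/reliability -> cohort analysis.

Driven by a single JSON config with one explicit top-level seed; every
stage's randomness is derived from it (or from explicit per-stage seeds in
the config).  Rerunning the same config reproduces all numeric outputs
bit-for-bit.  The run directory is append-only: no stage touches another
stage's files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cobb import cobb_angle, cobb_from_arc
from .cohort import ExclusionRules, apply_exclusions, run_table, summarize_fat
from .fatquant import FatQuantConfig, quantify_all
from .phantom import (CohortSpec, PhantomSpec, RaterNoiseSpec, generate_cohort,
                      generate_phantom, simulate_raters, write_phantom)
from .reliability import bland_altman, bootstrap_ci, per_case_sd, rater_summary

log = logging.getLogger("trunkct.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


def load_config(path: str | Path) -> dict:
    cfg = json.loads(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Fail fast, before any compute."""
    if "seed" not in cfg:
        raise ValueError("config must carry an explicit top-level 'seed'")
    if not isinstance(cfg["seed"], int):
        raise ValueError("'seed' must be an integer")
    for key in ("phantom", "cohort", "raters", "fat_quant", "exclusions", "bootstrap"):
        if key in cfg and not isinstance(cfg[key], dict):
            raise ValueError(f"config block {key!r} must be an object")


def _spec_from(cfg: dict, key: str, cls, seed_offset: int, base_seed: int):
    block = dict(cfg.get(key, {}))
    block.setdefault("seed", base_seed + seed_offset)
    if "per_group_fat_fraction" in block:
        block["per_group_fat_fraction"] = {
            k: float(v) for k, v in block["per_group_fat_fraction"].items()}
    if "grid_shape" in block:
        block["grid_shape"] = tuple(block["grid_shape"])
    if "spacing" in block:
        block["spacing"] = tuple(block["spacing"])
    for dict_key in ("per_muscle_fat_mean", "per_muscle_fat_sd", "per_muscle_loading"):
        if dict_key in block:
            block[dict_key] = {k: float(v) for k, v in block[dict_key].items()}
    if "per_rater_bias" in block and block["per_rater_bias"] is not None:
        block["per_rater_bias"] = tuple(block["per_rater_bias"])
    return cls(**block)


def _versions_manifest() -> dict:
    import nibabel
    import scipy
    return {
        "trunkct": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Execute every stage; returns the run directory."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    (out / "versions.json").write_text(json.dumps(_versions_manifest(), indent=2))

    base_seed = cfg["seed"]
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings[name] = dt
                if exc is not None:
                    log.error("stage %s: FAILED after %.2fs: %s", name, dt, exc)
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, dt)
        return _Timer()

    fat_cfg = FatQuantConfig(**cfg.get("fat_quant", {}))
    rules = ExclusionRules(**cfg.get("exclusions", {}))

    with stage("phantom"):
        pspec = _spec_from(cfg, "phantom", PhantomSpec, 1, base_seed)
        phantom = generate_phantom(pspec)
        write_phantom(phantom, out / "phantom")

    with stage("quantify"):
        metrics = quantify_all(phantom.volume, phantom.labels, fat_cfg)
        metrics.insert(0, "case_id", "phantom_1")
        metrics.to_csv(out / "metrics.csv", index=False)

    with stage("cobb"):
        measured = cobb_angle(phantom.endplates)
        planted = cobb_from_arc(phantom.arc_length_mm, phantom.arc_radius_mm)
        pd.DataFrame([{
            "case_id": "phantom_1",
            "cobb_measured_deg": measured.angle_deg,
            "cobb_planted_deg": planted,
            "superior_inclination_deg": measured.superior_inclination_deg,
            "inferior_inclination_deg": measured.inferior_inclination_deg,
        }]).to_csv(out / "cobb.csv", index=False)

    with stage("cohort"):
        cspec = _spec_from(cfg, "cohort", CohortSpec, 2, base_seed)
        cohort = generate_cohort(cspec)

    with stage("raters"):
        rspec = _spec_from(cfg, "raters", RaterNoiseSpec, 3, base_seed)
        matrix = simulate_raters(cohort["cobb_true"].to_numpy(), rspec)
        cohort = cohort.copy()
        cohort["cobb_mean"] = matrix.values.mean(axis=1)
        frame = matrix.to_frame()
        frame["case_id"] = cohort["case_id"].to_numpy()
        frame.to_csv(out / "raters.csv", index=False)
        cohort.to_csv(out / "cohort.csv", index=False)

    with stage("reliability"):
        boot = cfg.get("bootstrap", {})
        icc = bootstrap_ci(matrix,
                           n_bootstrap=int(boot.get("n_bootstrap", 2000)),
                           level=float(boot.get("level", 0.95)),
                           seed=base_seed + 4)
        ba = bland_altman(matrix)
        mean_sd, sd_sd = per_case_sd(matrix)
        payload = dataclasses.asdict(icc)
        payload.update({
            "bland_altman": {"bias": ba.bias, "loa_low": ba.loa_low,
                             "loa_high": ba.loa_high,
                             "sd_differences": ba.sd_differences},
            "per_case_sd_mean": mean_sd,
            "per_case_sd_sd": sd_sd,
            "rater_summary": rater_summary(matrix).to_dict(orient="records"),
        })
        (out / "reliability.json").write_text(json.dumps(payload, indent=2))

    with stage("analysis"):
        table = run_table(cohort, rules)
        table.to_csv(out / "correlations.csv", index=False)
        summarize_fat(cohort).to_csv(out / "fat_summary.csv", index=False)
        _kept, excl_log = apply_exclusions(cohort, rules)
        excl_log.to_csv(out / "exclusion_log.csv", index=False)

    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    log.removeHandler(handler)
    handler.close()
    return out
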