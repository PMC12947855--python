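"""End-to-end pipeline: simulate -> preprocess -> fit-learning -> fit-history
-> stats -> report, with deterministic per-stage seeding and a config hash
stamped into every artifact."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, history, io, learning, vigorstats

log = logging.getLogger("reachvigor")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything a full run needs; JSON-serializable."""

    seed: int = 0
    n_subjects: int = 22
    mode: str = "learned"
    hyper: dict = field(default_factory=dict)       # PopulationHyperParams overrides
    kinematics: dict = field(default_factory=dict)  # KinematicGenParams overrides
    learning_method: str = "map"
    mcmc_steps: int = 2500
    alpha_grid_step: float = 0.01
    out_dir: str = "reachvigor_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.to_dict())
    manifest: dict = {"config_hash": chash, "stages": {}}

    def fail(stage: str, err: Exception):
        manifest["stages"][stage] = f"FAILED: {err}"
        (out / f"manifest_{chash}.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed") from err

    # --- simulate -----------------------------------------------------------
    try:
        hyper = cohort.PopulationHyperParams(**config.hyper)
        kin = cohort.KinematicGenParams(**config.kinematics)
        records, _ = cohort.simulate_cohort(
            n_subjects=config.n_subjects, hyper=hyper, kin=kin,
            mode=config.mode, seed=stage_seed(config.seed, "simulate"))
        rec_path = io.write_trial_records(records, out / f"trials_{chash}.csv")
        manifest["stages"]["simulate"] = str(rec_path)
        log.info("simulate: %d trials, %d subjects", len(records), config.n_subjects)
    except Exception as err:
        fail("simulate", err)

    # --- preprocess ---------------------------------------------------------
    try:
        from .kinematics import apply_exclusions

        records = apply_exclusions(records)
        n_excl = int(records.excluded.sum())
        manifest["stages"]["preprocess"] = f"{n_excl} trials excluded"
        log.info("preprocess: %d excluded", n_excl)
    except Exception as err:
        fail("preprocess", err)

    # --- fit-learning -------------------------------------------------------
    fit_summary = {}
    if config.mode == "learned":
        try:
            data = learning.ChoiceData.from_records(records)
            fit = learning.fit_hierarchical(
                data, method=config.learning_method,
                seed=stage_seed(config.seed, "fit-learning"),
                n_steps=config.mcmc_steps, n_burn=config.mcmc_steps // 2)
            fit_summary = fit.to_dict()
            (out / f"learning_fit_{chash}.json").write_text(
                json.dumps(fit_summary, indent=2))
            manifest["stages"]["fit-learning"] = fit_summary
        except Exception as err:
            fail("fit-learning", err)

    # --- fit-history --------------------------------------------------------
    try:
        alphas = np.arange(0.0, 1.0 + 1e-9, config.alpha_grid_step)
        alpha_hat, profile = history.fit_alpha(records, alphas=alphas)
        profile.to_csv(out / f"alpha_profile_{chash}.csv", index=False)
        hist_reg = history.history_regression(records, alpha_hat)
        manifest["stages"]["fit-history"] = dict(alpha=alpha_hat, **hist_reg)
    except Exception as err:
        fail("fit-history", err)

    # --- stats --------------------------------------------------------------
    try:
        spec = vigorstats.RegressionSpec(
            response="out_peak_vel",
            fixed=["e_r", "C(target)", "block", "trial"]
            if config.mode == "instructed" else
            ["value", "C(target)", "block", "trial"],
        )
        table = vigorstats.fit_vigor_model(records, spec)
        table.to_csv(out / f"vigor_regression_{chash}.csv", index=False)
        vdm = vigorstats.velocity_difference_model(records, "rpe")
        manifest["stages"]["stats"] = dict(
            vigor_terms={r.term: r.beta for r in table.itertuples()},
            vdiff_beta_rpe=vdm["beta_predictor"], vdiff_p_rpe=vdm["p_predictor"])
    except Exception as err:
        fail("stats", err)

    # --- report -------------------------------------------------------------
    (out / f"manifest_{chash}.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
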