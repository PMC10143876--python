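"""End-to-end pipeline: generate -> shift -> screen -> qualitative -> semiquant.

Thin orchestration over the library modules.  Each stage logs its wall time;
a stage failure halts the run with the stage name while artifacts written so
far stay on disk.  Qualitative recognition runs before the per-pesticide
semi-quantitative studies, matching the two-step workflow (is there a
pesticide and which one; then how much of it).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import run_comparison_study, run_sweep_study, screen_features
from .io import RunConfig, write_manifest
from .simulate import (
    PESTICIDES,
    DomainShiftParams,
    SensorResponseModel,
    calibrate_shift,
    generate_domain_dataset,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger("enose_transfer")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Artifacts: ``screening.csv``, ``qualitative_sweep.csv``,
    ``qualitative_compare.csv``, ``semiquant_sweep.csv``,
    ``semiquant_compare.csv``, ``summary.json`` (plus per-sample CSVs and a
    manifest when ``write_data`` is on).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("run config hash %s, root seed %d", config.config_hash(), config.seed)

    acq = config.acquisition()
    design = config.dataset_design()
    model = SensorResponseModel.default(acq)
    root = np.random.default_rng(config.seed)
    # Named child streams, drawn in fixed order.
    seeds = {
        name: int(s)
        for name, s in zip(
            ("calibration", "source", "target", "experiments"),
            root.integers(2**31, size=4),
        )
    }
    summary: dict = {"config_hash": config.config_hash(), "stages": {}}

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                summary["stages"][name] = round(dt, 2)
                if exc is not None:
                    (out / "summary.json").write_text(json.dumps(summary, indent=2))
                    raise StageFailure(name, exc) from exc
                logger.info("stage %s done in %.1fs", name, dt)

        return _Timer()

    with stage("shift"):
        if config.shift_mode == "calibrate":
            shift = calibrate_shift(
                model,
                acq,
                config.within_floor,
                config.cross_ceiling,
                np.random.default_rng(seeds["calibration"]),
                design=design,
            )
        else:
            shift = DomainShiftParams.from_magnitude(config.shift_magnitude, acq.n_sensors)
        summary["shift_magnitude"] = shift.magnitude

    with stage("generate"):
        source = generate_domain_dataset(design, "source", model, shift, acq, seeds["source"])
        target = generate_domain_dataset(design, "target", model, shift, acq, seeds["target"])
        if config.write_data:
            write_manifest(source + target, out / "data")

    feature_kwargs = {
        "rate_hz": acq.rate_hz,
        "n_coeffs": config.n_coeffs,
        "wt_basis": config.wt_basis,
        "wt_level": config.wt_level,
    }

    with stage("screen"):
        screening = screen_features(source, target, feature_kwargs=feature_kwargs)
        screening.to_csv(out / "screening.csv", index=False)

    exp_seeds = range(seeds["experiments"] % 2**16, seeds["experiments"] % 2**16 + config.n_seeds)
    with stage("qualitative"):
        sweep = run_sweep_study(
            model, shift, acq, design,
            task="qualitative", feature_method=config.qualitative_method,
            N_grid=config.N_grid, Tt=config.Tt, C=config.C, seeds=exp_seeds,
        )
        sweep.to_csv(out / "qualitative_sweep.csv", index=False)
        compare = run_comparison_study(
            model, shift, acq, design,
            task="qualitative", feature_method=config.qualitative_method,
            N=config.N, Tt=config.Tt, C=config.C, seeds=exp_seeds,
        )
        compare.to_csv(out / "qualitative_compare.csv", index=False)
        summary["qualitative_mean_accuracy"] = (
            compare.groupby("method").accuracy.mean().round(4).to_dict()
        )

    with stage("semiquant"):
        sweeps, compares = [], []
        for pesticide in PESTICIDES:
            sw = run_sweep_study(
                model, shift, acq, design,
                task="semiquant", feature_method=config.semiquant_method,
                pesticide=pesticide, N_grid=config.N_grid,
                Tt=min(config.Tt, design.n_per_class_per_domain // 2),
                C=config.C_semiquant, seeds=exp_seeds,
            )
            sw["pesticide"] = pesticide
            sweeps.append(sw)
            cp = run_comparison_study(
                model, shift, acq, design,
                task="semiquant", feature_method=config.semiquant_method,
                pesticide=pesticide, N=config.N,
                Tt=min(config.Tt, design.n_per_class_per_domain // 2),
                C=config.C_semiquant, seeds=exp_seeds,
            )
            cp["pesticide"] = pesticide
            compares.append(cp)
        pd.concat(sweeps, ignore_index=True).to_csv(out / "semiquant_sweep.csv", index=False)
        semi = pd.concat(compares, ignore_index=True)
        semi.to_csv(out / "semiquant_compare.csv", index=False)
        summary["semiquant_mean_accuracy"] = {
            p: df.groupby("method").accuracy.mean().round(4).to_dict()
            for p, df in semi.groupby("pesticide")
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
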