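"""End-to-end orchestration: data -> features -> split -> fit -> sensitivity.

A run is driven by a plain serializable config (nested dicts, YAML-friendly);
the resolved config is written next to the outputs so a run can be repeated
byte-for-byte.  Seeds are mandatory parts of the config — there is no
wall-clock seeding anywhere.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import yaml

from . import io as rio
from .errors import ConfigError, RumenZetaError
from .features import FeatureConfig, assemble_integrated_dataset, split_train_validation
from .models import (
    fit_linear,
    fit_mlp,
    fit_rbf,
    fit_report,
    save_model,
    select_best_model,
)
from .sensitivity import rank_variables
from .synthetic import GeneratorConfig, generate_blocks

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline"]

logger = logging.getLogger("rumenzeta.pipeline")

DEFAULT_CONFIG: dict = {
    "inputs": {"t1": None, "t2": None},   # CSV paths; None => generator
    "generator": {"enabled": False, "seed": 0},
    "features": {
        "include_optional": None,
        "condition_matched": False,
        "grouping_overrides": {},
    },
    "split": {"ratio": 0.75, "seed": 0},
    "models": [
        {"family": "linear"},
        {"family": "rbf", "hidden": 120, "knn_k": 2, "seed": 0},
    ],
    "sensitivity": {"subset": "training"},
    "output": {"dir": "rumenzeta_run"},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def resolve_config(config: dict | None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


def _stage(name):
    logger.info("[%s] start", name)


def _load_blocks(cfg: dict):
    gen = cfg["generator"]
    inputs = cfg["inputs"]
    if gen.get("enabled"):
        gc = GeneratorConfig(seed=int(gen.get("seed", 0)))
        t1, t2, truth = generate_blocks(gc)
        return t1, t2
    if inputs.get("t1") == "bundled" and inputs.get("t2") == "bundled":
        return rio.load_t1_means(), rio.load_t2_means()
    if not (inputs.get("t1") and inputs.get("t2")):
        raise ConfigError(
            "either generator.enabled must be true or inputs.t1/t2 must be set"
        )
    return (rio.read_t1_table(inputs["t1"]), rio.read_t2_table(inputs["t2"]))


def _fit_one(spec: dict, train, validation):
    family = spec.get("family")
    if family == "linear":
        return fit_linear(train)
    if family == "mlp":
        return fit_mlp(
            train,
            hidden=int(spec.get("hidden", 5)),
            epochs_bp=int(spec.get("epochs_bp", 100)),
            epochs_cg=int(spec.get("epochs_cg", 500)),
            seed=int(spec.get("seed", 0)),
            manifest=spec.get("inputs"),
        )
    if family == "rbf":
        return fit_rbf(
            train,
            hidden=int(spec.get("hidden", 120)),
            knn_k=int(spec.get("knn_k", 2)),
            seed=int(spec.get("seed", 0)),
            manifest=spec.get("inputs"),
        )
    raise ConfigError(f"unknown model family '{family}'")


def run_pipeline(config: dict | None = None, outdir=None) -> Path:
    """Execute all stages; returns the run directory.

    Stage errors propagate as package exceptions with the stage name prefixed
    to the message.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir or cfg["output"]["dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("rumenzeta")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "config"
    try:
        (outdir / "resolved_config.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=True)
        )

        stage = "data"
        _stage(stage)
        t1, t2 = _load_blocks(cfg)
        logger.info("[data] %d t1 cases, %d t2 cases", len(t1), len(t2))

        stage = "featurize"
        _stage(stage)
        fc = cfg["features"]
        dataset = assemble_integrated_dataset(t1, t2, FeatureConfig(
            include_optional=fc.get("include_optional"),
            grouping_overrides=fc.get("grouping_overrides") or {},
            condition_matched=bool(fc.get("condition_matched")),
        ))
        dataset.save(outdir / "dataset.csv")
        logger.info("[featurize] %d integrated cases, %d features",
                    dataset.n, len(dataset.manifest))

        stage = "split"
        _stage(stage)
        train, validation = split_train_validation(
            dataset,
            ratio=float(cfg["split"].get("ratio", 0.75)),
            seed=int(cfg["split"].get("seed", 0)),
        )
        logger.info("[split] train %d / validation %d (seed %s)",
                    train.n, validation.n, cfg["split"].get("seed"))

        stage = "fit"
        _stage(stage)
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        reports = {}
        models = {}
        for spec in cfg["models"]:
            name = spec.get("name") or spec["family"]
            model = _fit_one(spec, train, validation)
            report = fit_report(model, train, validation)
            models[name] = model
            reports[name] = report
            save_model(model, models_dir / f"{name}.json")
            report.to_frame().to_csv(outdir / f"fit_report_{name}.csv", index=False)
            logger.info(
                "[fit] %s: train r=%.3f, validation r=%.3f", name,
                report.training.correlation, report.validation.correlation,
            )

        stage = "sensitivity"
        _stage(stage)
        sens_subset = {"training": train, "validation": validation,
                       "all": dataset}[cfg["sensitivity"].get("subset", "training")]
        sens_rows = {}
        for name, model in models.items():
            sens = rank_variables(model, sens_subset)
            sens_rows[name] = sens.ratios()
        import pandas as pd

        pd.DataFrame(sens_rows).T.to_csv(outdir / "sensitivity.csv")

        best = select_best_model(reports)
        (outdir / "summary.json").write_text(json.dumps({
            "n_t1": len(t1), "n_t2": len(t2), "n_integrated": dataset.n,
            "best_model": best,
            "reports": {
                name: {
                    "training_correlation": r.training.correlation,
                    "validation_correlation": r.validation.correlation,
                }
                for name, r in reports.items()
            },
        }, indent=1))
        logger.info("[done] best model by validation correlation: %s", best)
    except RumenZetaError as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
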