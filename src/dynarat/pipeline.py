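"""End-to-end pipeline runner driven by a JSON run configuration.

Config schema (validated before any computation)::

    {
      "seed": 7,                       # required; all randomness flows from it
      "out_dir": "runs/example",       # required
      "simulate": {"n_subjects": 450, "mode": "realistic"},
      "fit":      {"model": "model4_safe", "method": "REML"},
      "cv":       {"k": 5, "repetitions": 2},          # optional stage
      "compare":  {"models": ["model4_safe", "model5_time"]}   # optional
    }

Randomness is split into named substreams (simulation, folds) derived from
the single seed, so stages are individually reproducible.  Every artifact
directory gets a ``run_info.json`` with the config, seed and version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .cohort import CohortConfig, cohort_summary, generate_cohort
from .design import model_spec
from .evaluation import compare_models, crossvalidate, summarize_errors
from .io import save_model, write_cohort
from .lmm import filter_decliners, filter_fitting_set

__all__ = ["run_pipeline", "validate_config", "substream"]

logger = logging.getLogger(__name__)

_MODEL_IDS = ("model1", "model2", "model3", "model4_safe", "model5_time")


class ConfigSchemaError(ValueError):
    """Run configuration fails validation."""


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the master seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_config(config: dict) -> None:
    for key in ("seed", "out_dir", "simulate", "fit"):
        if key not in config:
            raise ConfigSchemaError(f"config missing required field {key!r}")
    if not isinstance(config["seed"], int):
        raise ConfigSchemaError("seed must be an integer")
    sim = config["simulate"]
    if "n_subjects" not in sim or int(sim["n_subjects"]) < 1:
        raise ConfigSchemaError("simulate.n_subjects must be >= 1")
    fit = config["fit"]
    if fit.get("model", "model4_safe") not in _MODEL_IDS:
        raise ConfigSchemaError(f"fit.model must be one of {_MODEL_IDS}")
    for mid in config.get("compare", {}).get("models", []):
        if mid not in _MODEL_IDS:
            raise ConfigSchemaError(f"compare.models entry {mid!r} unknown")


def run_pipeline(config: dict) -> dict:
    """Execute simulate -> fit -> (cv, compare) per the config.

    Returns the paths of the artifacts written.
    """
    validate_config(config)
    seed = config["seed"]
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    cohort_cfg = CohortConfig(
        n_subjects=int(config["simulate"]["n_subjects"]),
        mode=config["simulate"].get("mode", "realistic"),
        seed=substream(seed, "simulation"),
    )
    cohort = generate_cohort(cohort_cfg)
    artifacts.update({f"cohort_{k}": str(v) for k, v in write_cohort(cohort, out_dir).items()})
    (out_dir / "cohort_summary.json").write_text(
        json.dumps(cohort_summary(cohort), indent=1)
    )
    artifacts["cohort_summary"] = str(out_dir / "cohort_summary.json")

    included, excluded = filter_fitting_set(cohort)
    retained, declined = filter_decliners(included)
    logger.info(
        "fitting filters: %d included, %d excluded (<3 visits or <12-week span), "
        "%d decliners removed from fitting",
        included.n_subjects, excluded.n_subjects, declined.n_subjects,
    )
    spec = model_spec(config["fit"].get("model", "model4_safe"))
    method = config["fit"].get("method", "REML")
    from .evaluation import fit_for_training

    fitted = fit_for_training(cohort, spec, method=method)
    model_path = out_dir / "model.json"
    save_model(fitted, model_path)
    artifacts["model"] = str(model_path)

    if "cv" in config:
        cv_cfg = config["cv"]
        records = crossvalidate(
            cohort, spec,
            k=int(cv_cfg.get("k", 5)),
            repetitions=int(cv_cfg.get("repetitions", 10)),
            seed=substream(seed, "folds"),
            method=method,
        )
        records.to_csv(out_dir / "cv_records.csv", index=False)
        summarize_errors(records, group_by="m").to_csv(
            out_dir / "cv_summary_by_m.csv", index=False
        )
        artifacts["cv_records"] = str(out_dir / "cv_records.csv")
        artifacts["cv_summary"] = str(out_dir / "cv_summary_by_m.csv")

    if "compare" in config:
        specs = [model_spec(mid) for mid in config["compare"]["models"]]
        table = compare_models(
            cohort, specs,
            k=int(config["compare"].get("k", 5)),
            repetitions=int(config["compare"].get("repetitions", 1)),
            seed=substream(seed, "folds"),
            method=method,
        )
        table.to_json(out_dir / "model_comparison.json", orient="records", indent=1)
        artifacts["comparison"] = str(out_dir / "model_comparison.json")

    run_info = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "config": config,
        "artifacts": artifacts,
    }
    (out_dir / "run_info.json").write_text(json.dumps(run_info, indent=1))
    artifacts["run_info"] = str(out_dir / "run_info.json")
    return artifacts
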