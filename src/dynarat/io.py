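"""CSV and JSON contracts: cohort readers/writers and model artifacts.

Data travel as two long-format CSVs — one measurements row per visit
(``subject_id, t_days, arat, sa, fe, fmue``) and one covariates row per
subject — mirroring the simple text-file contract a bedside prediction tool
ingests.  Fitted models are a single JSON artifact (spec, knots, beta, the
lower triangle of G, sigma^2, log-likelihood, method, version) so a
prediction can be reproduced without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ARAT_MAX,
    COVARIATE_COLUMNS,
    MEASUREMENT_COLUMNS,
    Cohort,
)
from .design import ModelSpec
from .lmm import ArmRecoveryModel

__all__ = ["ValidationError", "read_cohort", "write_cohort", "save_model", "load_model"]


class ValidationError(ValueError):
    """Input file violates the data contract; the message names the rows."""


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write measurements/covariates (and truth, if present) CSVs.
    Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out_dir / "measurements.csv",
        "covariates": out_dir / "covariates.csv",
    }
    cohort.measurements.to_csv(paths["measurements"], index=False)
    cohort.covariates.to_csv(paths["covariates"], index=False)
    if cohort.truth is not None:
        paths["truth"] = out_dir / "truth.csv"
        cohort.truth.to_csv(paths["truth"], index=False)
    return paths


def read_cohort(measurements_csv, covariates_csv=None, truth_csv=None,
                strict: bool = True, time_unit: str = "days") -> Cohort:
    """Read and validate a long-format cohort.

    ``strict`` enforces the clinical ranges (ARAT integer 0–57, FE in
    {0,1,2}); disable it for model-faithful data, which are real-valued and
    unbounded.  Missing optional covariate columns load as missing values;
    model structures that need them fail later with a clear error.
    ``time_unit='weeks'`` multiplies times by 7 on ingest.
    """
    meas = pd.read_csv(measurements_csv)
    required = ["subject_id", "t_days", "arat"]
    missing = [c for c in required if c not in meas.columns]
    if missing:
        raise ValidationError(f"measurements file lacks required columns {missing}")
    for col in MEASUREMENT_COLUMNS:
        if col not in meas.columns:
            meas[col] = np.nan
    if time_unit == "weeks":
        meas["t_days"] = meas["t_days"] * 7.0
    elif time_unit != "days":
        raise ValidationError(f"unknown time unit {time_unit!r}")

    if strict:
        bad = meas.index[(meas["arat"] < 0) | (meas["arat"] > ARAT_MAX)].tolist()
        if bad:
            raise ValidationError(
                f"ARAT outside [0, {ARAT_MAX}] at measurement rows {bad}"
            )
        fe = meas["fe"].dropna()
        bad = fe.index[~fe.isin([0, 1, 2])].tolist()
        if bad:
            raise ValidationError(f"FE outside {{0,1,2}} at measurement rows {bad}")
    dup = meas.duplicated(subset=["subject_id", "t_days"])
    if dup.any():
        raise ValidationError(
            f"duplicate (subject, time) at measurement rows {meas.index[dup].tolist()}"
        )
    meas = meas.sort_values(["subject_id", "t_days"]).reset_index(drop=True)

    if covariates_csv is not None:
        cov = pd.read_csv(covariates_csv)
        if "subject_id" not in cov.columns:
            raise ValidationError("covariates file lacks subject_id")
        for col in COVARIATE_COLUMNS:
            if col not in cov.columns:
                cov[col] = np.nan
    else:
        cov = pd.DataFrame({"subject_id": sorted(meas["subject_id"].unique())})
        for col in COVARIATE_COLUMNS[1:]:
            cov[col] = np.nan

    truth = pd.read_csv(truth_csv) if truth_csv is not None else None
    cohort = Cohort(meas, cov, truth)
    if strict:
        cohort.validate()
    return cohort


def save_model(fitted: ArmRecoveryModel, path) -> None:
    """Serialize a fitted model to a JSON artifact."""
    G = np.asarray(fitted.G_)
    tril = G[np.tril_indices(G.shape[0])].tolist()
    artifact = {
        "format": "dynarat-model",
        "version": __version__,
        "spec": fitted.spec_.to_dict(),
        "method": fitted.method,
        "beta": np.asarray(fitted.beta_).tolist(),
        "G_lower_triangle": tril,
        "sigma2": float(fitted.sigma2_),
        "loglik": float(fitted.loglik_),
        "cov_beta": np.asarray(fitted.cov_beta_).tolist(),
        "theta": np.asarray(getattr(fitted, "theta_", [])).tolist(),
        "cov_eta": np.asarray(
            getattr(fitted, "cov_eta_", np.zeros((0, 0)))
        ).tolist(),
        "converged": bool(fitted.converged_),
        "columns": list(fitted.columns_),
        "blocks": fitted.blocks_,
        "n_subjects": int(fitted.n_subjects_),
        "n_obs": int(fitted.n_obs_),
    }
    Path(path).write_text(json.dumps(artifact, indent=1))


def load_model(path) -> ArmRecoveryModel:
    """Reconstruct a fitted model from its JSON artifact."""
    artifact = json.loads(Path(path).read_text())
    if artifact.get("format") != "dynarat-model":
        raise ValidationError(f"{path} is not a model artifact")
    spec = ModelSpec.from_dict(artifact["spec"])
    model = ArmRecoveryModel(spec=spec, method=artifact["method"])
    q = spec.n_random
    G = np.zeros((q, q))
    G[np.tril_indices(q)] = artifact["G_lower_triangle"]
    G = G + np.tril(G, -1).T
    model.spec_ = spec
    model.beta_ = np.asarray(artifact["beta"], dtype=float)
    model.G_ = G
    model.sigma2_ = float(artifact["sigma2"])
    model.psi_ = G / model.sigma2_
    model.loglik_ = float(artifact["loglik"])
    model.cov_beta_ = np.asarray(artifact["cov_beta"], dtype=float)
    theta = np.asarray(artifact.get("theta", []), dtype=float)
    cov_eta = np.asarray(artifact.get("cov_eta", []), dtype=float)
    if theta.size:
        model.theta_ = theta
    if cov_eta.size:
        model.cov_eta_ = cov_eta
    model.converged_ = bool(artifact["converged"])
    model.columns_ = list(artifact["columns"])
    model.blocks_ = artifact["blocks"]
    model.n_subjects_ = int(artifact["n_subjects"])
    model.n_obs_ = int(artifact["n_obs"])
    return model
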