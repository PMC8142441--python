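"""Model specifications and design-matrix construction.

Five fixed-effect structures are compared for the ARAT recovery model, all
sharing a natural-cubic-spline time course and subject-level random effects
(random intercept plus a smaller random spline of time):

* ``model1`` — every candidate covariate, main effect and interaction with
  the spline of time (most extensive model);
* ``model2`` — all main effects, but only the *significant* time
  interactions (obtained by pruning ``model1``);
* ``model3`` — only significant main effects and significant interactions;
* ``model4_safe`` — shoulder abduction and finger extension only, each with
  its time interaction (the SAFE model, the final prediction model);
* ``model5_time`` — time course only (minimal model).

A fixed-effects row at time ``t`` is ``[1, ns(t), c1, ..., c1*ns(t), ...]``;
a random-effects row is ``[1, ns_re(t)]``.  Categorical covariates are
dummy-coded against their first level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .splines import Knots, default_re_knots, default_time_knots, ns_eval

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "DataError",
    "build_design",
    "design_columns",
    "model_spec",
    "ALL_COVARIATES",
]


class DataError(ValueError):
    """Missing or unusable covariate data for the requested design."""


#: covariate name -> (source, kind, levels-or-None)
#: source: "measurement" (time-varying) or "subject" (baseline table)
_COVARIATE_INFO = {
    "age": ("subject", "numeric", None),
    "sex": ("subject", "categorical", ["female", "male"]),
    "affected_side": ("subject", "categorical", ["left", "right"]),
    "dominant_side": ("subject", "categorical", ["left", "right"]),
    "bamford": ("subject", "categorical", ["LACI", "PACI", "TACI"]),
    "rtpa": ("subject", "boolean", None),
    "nihss": ("subject", "numeric", None),
    "nihss_item8": ("subject", "numeric", None),
    "nihss_item11": ("subject", "numeric", None),
    "neglect": ("subject", "boolean", None),
    "fmue": ("measurement", "numeric", None),
    "fe": ("measurement", "categorical", [0, 1, 2]),
    "sa": ("measurement", "categorical", [0, 1, 2, 3, 4, 5]),
}

ALL_COVARIATES = list(_COVARIATE_INFO)

MAIN = "main"
MAIN_AND_INTERACTION = "main+time_interaction"


@dataclass(frozen=True)
class ModelSpec:
    """One fixed-effect structure plus spline and random-effects config."""

    id: str
    covariates: tuple = ()  # tuple of (name, role)
    time_knots: Knots = field(default_factory=default_time_knots)
    re_knots: Knots | None = field(default_factory=default_re_knots)
    covariate_policy: str = "last_observed"
    prune_alpha: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple((n, r) for n, r in self.covariates))
        for name, role in self.covariates:
            if name not in _COVARIATE_INFO:
                raise DataError(f"unknown covariate {name!r}")
            if role not in (MAIN, MAIN_AND_INTERACTION):
                raise DataError(f"unknown covariate role {role!r}")
        if self.covariate_policy not in ("baseline", "last_observed"):
            raise DataError(f"unknown covariate_policy {self.covariate_policy!r}")

    @property
    def n_fixed(self) -> int:
        return len(design_columns(self)[0])

    @property
    def n_random(self) -> int:
        # random intercept only when no random-effects spline is configured
        return 1 if self.re_knots is None else self.re_knots.df + 1

    def with_(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "covariates": [list(c) for c in self.covariates],
            "time_knots": self.time_knots.to_dict(),
            "re_knots": None if self.re_knots is None else self.re_knots.to_dict(),
            "covariate_policy": self.covariate_policy,
            "prune_alpha": self.prune_alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            id=d["id"],
            covariates=tuple((n, r) for n, r in d["covariates"]),
            time_knots=Knots.from_dict(d["time_knots"]),
            re_knots=None if d["re_knots"] is None else Knots.from_dict(d["re_knots"]),
            covariate_policy=d.get("covariate_policy", "last_observed"),
            prune_alpha=d.get("prune_alpha", 0.05),
        )


def model_spec(model_id: str, **kwargs) -> ModelSpec:
    """Build one of the five named model structures.

    ``model2``/``model3`` start from the full covariate set; their pruning
    to significant terms is performed by :func:`dynarat.lmm.prune_by_significance`.
    """
    if model_id in ("model1", "model2", "model3"):
        covs = tuple((name, MAIN_AND_INTERACTION) for name in ALL_COVARIATES)
    elif model_id == "model4_safe":
        covs = (("sa", MAIN_AND_INTERACTION), ("fe", MAIN_AND_INTERACTION))
    elif model_id == "model5_time":
        covs = ()
    else:
        raise DataError(f"unknown model id {model_id!r}")
    return ModelSpec(id=model_id, covariates=covs, **kwargs)


@dataclass
class DesignMatrices:
    """Per-subject stacked design: X (fixed), Z (random), y (ARAT), with the
    row-to-subject mapping and fixed-effect column metadata."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    subject_ids: list
    groups: np.ndarray  # integer subject index per row
    columns: list
    blocks: dict  # covariate -> {"main": [col idx], "interaction": [col idx]}


def _covariate_values(name, meas: pd.DataFrame, cov: pd.Series | None, policy: str):
    """Resolve one covariate to per-row columns (before spline interaction).

    Returns (values array of shape (n_rows, n_cols), column names).
    """
    source, kind, levels = _COVARIATE_INFO[name]
    n = len(meas)
    if source == "measurement":
        if name not in meas.columns or meas[name].isna().any():
            raise DataError(f"missing time-varying covariate {name!r}")
        raw = meas[name]
        if policy == "baseline":
            raw = pd.Series(np.repeat(raw.iloc[0], n), index=meas.index)
    else:
        if cov is None or name not in cov or pd.isna(cov[name]):
            raise DataError(f"missing subject covariate {name!r}")
        raw = pd.Series(np.repeat(cov[name], n), index=meas.index)

    if kind == "numeric":
        return raw.to_numpy(dtype=float)[:, None], [name]
    if kind == "boolean":
        return raw.astype(bool).to_numpy(dtype=float)[:, None], [name]
    # categorical: dummies against the first level
    vals = raw.to_numpy()
    cols, names = [], []
    for lvl in levels[1:]:
        cols.append((vals == lvl).astype(float))
        names.append(f"{name}[{lvl}]")
    return np.column_stack(cols), names


def design_columns(spec: ModelSpec):
    """Fixed-effect column names and per-covariate column blocks."""
    K = spec.time_knots.df
    columns = ["intercept"] + [f"ns(t){j}" for j in range(1, K + 1)]
    blocks: dict = {}
    for name, role in spec.covariates:
        _, kind, levels = _COVARIATE_INFO[name]
        base_names = (
            [f"{name}[{lvl}]" for lvl in levels[1:]] if kind == "categorical" else [name]
        )
        main_idx = list(range(len(columns), len(columns) + len(base_names)))
        columns.extend(base_names)
        inter_idx: list[int] = []
        if role == MAIN_AND_INTERACTION:
            for bn in base_names:
                inter_idx.extend(range(len(columns), len(columns) + K))
                columns.extend(f"{bn}:ns(t){j}" for j in range(1, K + 1))
        blocks[name] = {"main": main_idx, "interaction": inter_idx}
    return columns, blocks


def build_subject_design(meas: pd.DataFrame, cov: pd.Series | None, spec: ModelSpec):
    """X and Z rows for one subject's measurement frame."""
    if meas.empty:
        raise DataError("subject has no measurements")
    t = meas["t_days"].to_numpy(dtype=float)
    ns_t = ns_eval(t, spec.time_knots)
    parts = [np.ones((len(meas), 1)), ns_t]
    for name, role in spec.covariates:
        vals, _ = _covariate_values(name, meas, cov, spec.covariate_policy)
        parts.append(vals)
        if role == MAIN_AND_INTERACTION:
            # interleave per base column to match design_columns ordering
            for j in range(vals.shape[1]):
                parts.append(vals[:, j : j + 1] * ns_t)
    X = np.concatenate(parts, axis=1)
    if spec.re_knots is None:
        Z = np.ones((len(meas), 1))
    else:
        Z = np.concatenate([np.ones((len(meas), 1)), ns_eval(t, spec.re_knots)], axis=1)
    return X, Z


def build_design(cohort, spec: ModelSpec) -> DesignMatrices:
    """Stack per-subject design matrices for a whole cohort."""
    columns, blocks = design_columns(spec)
    X_list, Z_list, y_list, groups, sids = [], [], [], [], []
    cov_by_id = cohort.covariates.set_index("subject_id")
    for gi, (sid, meas) in enumerate(
        cohort.measurements.groupby("subject_id", sort=True)
    ):
        meas = meas.sort_values("t_days")
        cov = cov_by_id.loc[sid] if sid in cov_by_id.index else None
        X, Z = build_subject_design(meas, cov, spec)
        X_list.append(X)
        Z_list.append(Z)
        y_list.append(meas["arat"].to_numpy(dtype=float))
        groups.append(np.full(len(meas), gi))
        sids.append(sid)
    X = np.concatenate(X_list, axis=0)
    if X.shape[1] != len(columns):  # pragma: no cover - internal consistency
        raise DataError("design column mismatch")
    return DesignMatrices(
        X=X,
        Z=np.concatenate(Z_list, axis=0),
        y=np.concatenate(y_list),
        subject_ids=sids,
        groups=np.concatenate(groups),
        columns=columns,
        blocks=blocks,
    )
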