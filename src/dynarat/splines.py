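"""Natural cubic spline bases for the post-stroke time dimension.

A natural cubic spline is piecewise cubic between its knots, twice
continuously differentiable everywhere, and constrained to be *linear*
outside its boundary knots.  That boundary behaviour is what makes it a
sensible recovery-curve basis: extrapolation beyond the observed follow-up
window degrades gracefully instead of exploding cubically.

With ``K`` internal knots the basis spans ``K + 2`` dimensions including the
constant function; the constant is excluded here (models carry an explicit
intercept), so a ``Knots`` object with ``K`` internal knots yields ``K + 1``
basis columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["Knots", "KnotError", "make_knots", "ns_eval", "NaturalSplineBasis"]

#: Default manual internal knots (days post-stroke) for the 6-knot time basis,
#: concentrating flexibility in the first weeks where most change happens.
DEFAULT_MANUAL_KNOTS = (5.0, 9.0, 14.0, 21.0, 42.0, 91.0)
DEFAULT_BOUNDARY = (0.0, 200.0)


class KnotError(ValueError):
    """Invalid knot configuration (unordered, duplicated or out of bounds)."""


@dataclass(frozen=True)
class Knots:
    """Internal and boundary knots, in days post-stroke.

    Invariant: ``boundary[0] < internal[0] <= ... <= internal[-1] < boundary[1]``.
    """

    internal: tuple[float, ...]
    boundary: tuple[float, float] = field(default=DEFAULT_BOUNDARY)

    def __post_init__(self) -> None:
        internal = tuple(float(k) for k in self.internal)
        boundary = (float(self.boundary[0]), float(self.boundary[1]))
        object.__setattr__(self, "internal", internal)
        object.__setattr__(self, "boundary", boundary)
        if not internal:
            raise KnotError("at least one internal knot is required")
        if not all(np.isfinite(internal)) or not all(np.isfinite(boundary)):
            raise KnotError("knots must be finite")
        if boundary[0] >= boundary[1]:
            raise KnotError(f"boundary knots must be increasing, got {boundary}")
        if any(b > a for a, b in zip(internal[1:], internal[:-1])):
            raise KnotError(f"internal knots must be sorted: {internal}")
        if len(set(internal)) != len(internal):
            raise KnotError(f"internal knots must be distinct: {internal}")
        if internal[0] <= boundary[0] or internal[-1] >= boundary[1]:
            raise KnotError(
                f"internal knots {internal} must lie strictly inside boundary {boundary}"
            )

    @property
    def df(self) -> int:
        """Number of basis columns (intercept excluded)."""
        return len(self.internal) + 1

    @property
    def all_knots(self) -> np.ndarray:
        """Boundary-low, internal knots, boundary-high — the full knot sequence."""
        return np.asarray([self.boundary[0], *self.internal, self.boundary[1]])

    def to_dict(self) -> dict:
        return {"internal": list(self.internal), "boundary": list(self.boundary)}

    @classmethod
    def from_dict(cls, d: dict) -> "Knots":
        return cls(internal=tuple(d["internal"]), boundary=tuple(d["boundary"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Knots":
        return cls.from_dict(json.loads(s))


def _quantile(sorted_x: np.ndarray, p: float) -> float:
    # plotting-position (k-1)/(n-1) convention == numpy's default "linear"
    return float(np.quantile(sorted_x, p, method="linear"))


def make_knots(
    times,
    n_internal: int,
    placement: str = "quantile",
    manual_knots=None,
    boundary: tuple[float, float] | None = None,
) -> Knots:
    """Place internal knots on the pooled measurement times.

    Quantile placement puts ``n_internal`` knots at equally spaced empirical
    quantiles — the median for 1 knot, tertiles for 2, quartiles for 3 —
    with boundary knots at the min/max pooled time.  Manual placement
    validates user-supplied knots against the boundary.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise KnotError("times must be non-empty")
    if placement not in ("quantile", "quartile", "manual"):
        raise KnotError(f"unknown placement {placement!r}")
    if boundary is None:
        boundary = (float(times.min()), float(times.max()))
    if placement == "manual":
        if manual_knots is None:
            raise KnotError("manual placement requires manual_knots")
        manual_knots = tuple(float(k) for k in manual_knots)
        if len(manual_knots) != n_internal:
            raise KnotError(
                f"expected {n_internal} manual knots, got {len(manual_knots)}"
            )
        return Knots(internal=manual_knots, boundary=boundary)
    probs = np.arange(1, n_internal + 1) / (n_internal + 1)
    xs = np.sort(times)
    internal = tuple(_quantile(xs, p) for p in probs)
    if len(set(internal)) != len(internal):
        raise KnotError(
            f"quantile knots collapsed to duplicates {internal}; "
            "times too concentrated for this many knots"
        )
    return Knots(internal=internal, boundary=boundary)


def ns_eval(t, knots: Knots) -> np.ndarray:
    """Evaluate the natural cubic spline basis at times ``t``.

    Returns an ``(len(t), knots.df)`` matrix.  The construction is the
    truncated-power one: with full knot sequence ``z_1 < ... < z_M``
    (boundaries included) and

        d_k(t) = [(t - z_k)^3_+ - (t - z_M)^3_+] / (z_M - z_k),

    the columns are ``t / h`` and ``(d_k(t) - d_{M-1}(t)) / h^2`` for
    ``k = 1..M-2``, where ``h`` is the boundary span.  The ``1/h`` powers
    rescale every column to O(1) over the boundary interval (an affine
    reparameterization of the same spline space, so fitted values are
    unchanged while the numerics are well conditioned).  Each column is
    exactly linear below ``z_1`` and above ``z_M``, so extrapolation beyond
    the boundary knots is linear by construction.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    z = knots.all_knots
    M = len(z)
    h = z[-1] - z[0]

    def dk(k: int) -> np.ndarray:
        num = np.maximum(t - z[k], 0.0) ** 3 - np.maximum(t - z[M - 1], 0.0) ** 3
        return num / (z[M - 1] - z[k])

    d_last = dk(M - 2)
    cols = [t / h] + [(dk(k) - d_last) / h**2 for k in range(M - 2)]
    return np.column_stack(cols)


class NaturalSplineBasis(TransformerMixin, BaseEstimator):
    """Natural cubic spline features of time, as a scikit-learn transformer.

    ``fit`` learns knot locations from the pooled times (quantile placement)
    or validates manual knots; ``transform`` evaluates the basis.

    Parameters
    ----------
    n_internal : int
        Number of internal knots (1, 2, 3 and 6 are the structures used in
        model comparison, but any positive count works).
    placement : {"quantile", "manual"}
        Knot placement rule.
    manual_knots : sequence of float, optional
        Internal knots for manual placement.
    boundary : (low, high), optional
        Boundary knots; defaults to the min/max of the fitted times
        (quantile) or ``(0, 200)`` days (manual).
    """

    def __init__(
        self,
        n_internal: int = 3,
        placement: str = "quantile",
        manual_knots=None,
        boundary=None,
    ):
        self.n_internal = n_internal
        self.placement = placement
        self.manual_knots = manual_knots
        self.boundary = boundary

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).ravel()
        boundary = self.boundary
        if self.placement == "manual" and boundary is None:
            boundary = DEFAULT_BOUNDARY
        self.knots_ = make_knots(
            t,
            n_internal=self.n_internal,
            placement=self.placement,
            manual_knots=self.manual_knots,
            boundary=boundary,
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "knots_")
        t = np.asarray(X, dtype=float).ravel()
        return ns_eval(t, self.knots_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "knots_")
        return np.asarray([f"ns{i}" for i in range(1, self.knots_.df + 1)])


def default_time_knots() -> Knots:
    """The 6-knot manual time basis used by the final recovery model."""
    return Knots(internal=DEFAULT_MANUAL_KNOTS, boundary=DEFAULT_BOUNDARY)


def default_re_knots() -> Knots:
    """Smaller 2-knot basis for the random-effects spline (4 random effects
    with the random intercept)."""
    return Knots(internal=(14.0, 42.0), boundary=DEFAULT_BOUNDARY)
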