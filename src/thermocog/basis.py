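"""Temperature-response basis construction.

Four candidate functional forms for the nonlinear temperature term: raw
polynomial, cubic B-spline, and natural cubic splines with 3 or 5 knots. All
bases exclude the intercept column (absorbed by the model's common intercept)
and are centered: column means over the construction grid are stored on the
:class:`BasisMatrix` so the same affine columns can be re-evaluated on any
temperature grid (pointwise-consistent evaluation for response curves).

Natural cubic splines are built as the span of cardinal natural interpolating
splines (zero second derivative at the boundary knots, linear continuation
beyond them), which makes the linear-tail property exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline, CubicSpline

__all__ = ["BasisSpec", "BasisMatrix", "make_basis", "place_knots"]

KINDS = ("polynomial", "bspline", "ncs3", "ncs5")


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of one temperature basis.

    ``knots`` may be an explicit sorted tuple of temperatures or the string
    ``"quantile"`` (resolved against the data by :func:`place_knots` at
    construction time). Degree applies to polynomial and bspline only.
    """

    kind: str
    degree: int = 3
    knots: object = "quantile"  # tuple of floats or "quantile"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}; expected one of {KINDS}")
        if self.kind in ("polynomial", "bspline") and self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def n_knots(self) -> int:
        if self.kind == "ncs3":
            return 3
        if self.kind == "ncs5":
            return 5
        if self.kind == "bspline":
            return 3 if self.knots == "quantile" else len(self.knots)
        return 0

    def to_dict(self) -> dict:
        return {"kind": self.kind, "degree": self.degree,
                "knots": self.knots if isinstance(self.knots, str) else list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        knots = d.get("knots", "quantile")
        if not isinstance(knots, str):
            knots = tuple(float(k) for k in knots)
        return cls(kind=d["kind"], degree=int(d.get("degree", 3)), knots=knots)


@dataclass
class BasisMatrix:
    """Evaluated basis columns plus everything needed to re-evaluate them."""

    temperatures: np.ndarray
    columns: np.ndarray  # (n, k), centered, no intercept
    spec: BasisSpec       # with knots resolved to explicit values
    centers: np.ndarray   # column means subtracted at construction

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    def evaluate(self, temperatures) -> np.ndarray:
        """Evaluate the same centered columns on a new temperature grid."""
        t = np.atleast_1d(np.asarray(temperatures, dtype=float))
        raw = _raw_columns(t, self.spec)
        return raw - self.centers


def place_knots(temperatures, k: int) -> tuple:
    """Knots at equally spaced empirical quantiles spanning the 5th–95th
    percentiles (k=3 → {5, 50, 95}th; k=5 → {5, 27.5, 50, 72.5, 95}th),
    linear interpolation between order statistics."""
    t = np.asarray(temperatures, dtype=float)
    if k not in (3, 5):
        raise ValueError("k must be 3 or 5")
    if np.unique(t).size < k:
        raise ValueError(f"need at least {k} distinct temperatures")
    probs = np.linspace(5, 95, k)
    knots = np.percentile(t, probs)
    if np.unique(knots).size < k:
        raise ValueError("degenerate temperature distribution: tied knots")
    return tuple(float(x) for x in knots)


def _ncs_raw(t: np.ndarray, knots) -> np.ndarray:
    """Cardinal natural-spline columns (k knots → k-1 non-constant columns).

    Column j interpolates the j-th unit vector at the knots with natural
    boundary conditions, extended linearly beyond the boundary knots; the
    first cardinal function is dropped (with the intercept it is redundant:
    the cardinal functions sum to 1 at the knots and, being natural splines
    through constant data, sum to 1 everywhere).
    """
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    cols = np.empty((t.size, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = 1.0
        cs = CubicSpline(knots, e, bc_type="natural")
        v = cs(t)
        # linear continuation beyond boundary knots
        lo, hi = knots[0], knots[-1]
        left = t < lo
        right = t > hi
        if left.any():
            v[left] = cs(lo) + cs(lo, 1) * (t[left] - lo)
        if right.any():
            v[right] = cs(hi) + cs(hi, 1) * (t[right] - hi)
        cols[:, j] = v
    return cols[:, 1:]


def _bspline_raw(t: np.ndarray, spec: BasisSpec, knots) -> np.ndarray:
    """Full cubic (or degree-d) B-spline basis; first column dropped for the
    intercept. Interior knots from ``knots``; boundary knots padded at the
    knot range ends (clamped), evaluation clamped to the boundary."""
    deg = spec.degree
    knots = np.asarray(knots, dtype=float)
    inner = knots[1:-1]
    lo, hi = knots[0], knots[-1]
    tk = np.r_[[lo] * (deg + 1), inner, [hi] * (deg + 1)]
    tc = np.clip(t, lo, hi)
    dm = BSpline.design_matrix(tc, tk, deg).toarray()
    return dm[:, 1:]


def _raw_columns(t: np.ndarray, spec: BasisSpec) -> np.ndarray:
    if spec.kind == "polynomial":
        return np.column_stack([t ** p for p in range(1, spec.degree + 1)])
    knots = spec.knots
    if isinstance(knots, str):
        raise ValueError("spec knots must be resolved before evaluation")
    if spec.kind in ("ncs3", "ncs5"):
        return _ncs_raw(t, knots)
    if spec.kind == "bspline":
        return _bspline_raw(t, spec, knots)
    raise ValueError(spec.kind)


def make_basis(temperatures, spec: BasisSpec, centers=None) -> BasisMatrix:
    """Evaluate ``spec`` on ``temperatures``.

    Quantile knot rules are resolved against the data here; explicit knots
    must lie inside the observed range. ``centers`` overrides the centering
    constants (used to reproduce a previously constructed basis on new data);
    by default columns are centered at their means over ``temperatures``.
    """
    t = np.atleast_1d(np.asarray(temperatures, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("temperatures must be finite")
    resolved = spec
    if spec.kind in ("ncs3", "ncs5", "bspline"):
        k = spec.n_knots
        if isinstance(spec.knots, str):
            if spec.kind == "bspline":
                # boundary knots at the data range so the basis spans linear
                # functions over all observed temperatures; interior at quantiles
                inner = place_knots(t, 3)
                resolved = replace(spec, knots=(float(t.min()), *inner,
                                                float(t.max())))
            else:
                resolved = replace(spec, knots=place_knots(t, k))
        else:
            knots = np.asarray(spec.knots, dtype=float)
            if np.any(np.diff(knots) <= 0):
                raise ValueError("knots must be strictly increasing")
            if spec.kind in ("ncs3", "ncs5") and len(knots) != k:
                raise ValueError(f"{spec.kind} requires exactly {k} knots")
            if knots[0] < t.min() or knots[-1] > t.max():
                raise ValueError("explicit knots outside the observed temperature range")
    raw = _raw_columns(t, resolved)
    if centers is None:
        centers = raw.mean(axis=0)
    centers = np.asarray(centers, dtype=float)
    return BasisMatrix(temperatures=t, columns=raw - centers, spec=resolved,
                       centers=centers)
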