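"""Bivariate spline model of insert factors over (width, P/A).

The insert factor for a cutout is interpolated from a small set of measured
factors laid out in the two-dimensional parameter space of equivalent-ellipse
width (cm) and perimeter-to-area ratio (1/cm).  A separate model is fitted
per (machine, energy, applicator, SSD) key, from a hard floor of eight
measurements.

Fitting
-------
Training coordinates are standardized to unit ranges (the two axes differ in
scale by roughly 10×), then a tensor-product B-spline surface is fitted by
least squares:

* degrees default to (2, 1) — quadratic along width, where small-field
  output falloff is curved, linear along P/A, where the dependence is
  gentler;
* knot vectors are clamped with interior knots (none by default) placed at
  data quantiles;
* ``smoothing = 0`` (the default) is a plain least-squares fit; positive
  values add a ridge penalty of that weight on the coefficients.

With the default configuration the basis has 3 × 2 = 6 coefficients, so
eight measurements already overdetermine the surface, and any polynomial of
degree ≤ (2, 1) is reproduced exactly.  Records are canonically sorted
before fitting, so the fit is deterministic and permutation-invariant.

Prediction inside the convex hull of the training points is interpolation;
outside it the polynomial extension is still evaluated but flagged (and
logged) as extrapolation — never silently clamped, since the caller must
see the flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.spatial import Delaunay, QhullError

from .database import MeasurementRecord
from .errors import DegenerateDesignError, InsufficientDataError
from .geometry import EquivalentEllipse

__all__ = [
    "SplineModel",
    "fit_model",
    "predict",
    "PredictionResult",
    "loo_errors",
    "LooResult",
    "save_model",
    "load_model",
    "MIN_TRAINING_POINTS",
]

logger = logging.getLogger(__name__)

#: hard floor on training-set size, independent of the basis dimension
MIN_TRAINING_POINTS = 8

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class SplineModel:
    """Fitted insert-factor surface for one (machine, energy, cone, SSD) key."""

    key: tuple[str, float, float, float]
    degrees: tuple[int, int]
    smoothing: float
    training_points: np.ndarray = field(repr=False)  # (n, 3): width, P/A, factor
    knots_width: np.ndarray = field(repr=False)      # standardized coords
    knots_pa: np.ndarray = field(repr=False)
    coefficients: np.ndarray = field(repr=False)     # (n_w_basis, n_pa_basis)
    width_range: tuple[float, float] = (0.0, 1.0)
    pa_range: tuple[float, float] = (0.0, 1.0)

    @property
    def n_training(self) -> int:
        return len(self.training_points)

    def _standardize(self, width, pa):
        w0, w1 = self.width_range
        p0, p1 = self.pa_range
        return (np.asarray(width, float) - w0) / (w1 - w0), (
            np.asarray(pa, float) - p0
        ) / (p1 - p0)

    def evaluate(self, width, pa):
        """Surface value at (width, P/A); vectorized, extrapolates freely."""
        u, v = self._standardize(width, pa)
        u, v = np.atleast_1d(u), np.atleast_1d(v)
        kx, ky = self.degrees
        bx = BSpline.design_matrix(u, self.knots_width, kx, extrapolate=True).toarray()
        by = BSpline.design_matrix(v, self.knots_pa, ky, extrapolate=True).toarray()
        out = np.einsum("ni,ij,nj->n", bx, self.coefficients, by)
        return out if out.size > 1 else float(out[0])

    def in_hull(self, width: float, pa: float) -> bool:
        """Is the query inside the convex hull of the training points?"""
        u, v = self._standardize(self.training_points[:, 0], self.training_points[:, 1])
        qu, qv = self._standardize(width, pa)
        try:
            tri = Delaunay(np.column_stack([u, v]))
        except QhullError:
            return False
        return bool(tri.find_simplex(np.array([qu, qv])) >= 0)


@dataclass(frozen=True)
class PredictionResult:
    insert_factor: float
    extrapolated: bool


def _clamped_knots(values: np.ndarray, degree: int, n_interior: int) -> np.ndarray:
    """Clamped knot vector on [0, 1] with interior knots at data quantiles."""
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(values, qs)
    else:
        interior = np.array([])
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _design_matrix(u, v, tx, ty, kx, ky):
    bx = BSpline.design_matrix(u, tx, kx, extrapolate=True).toarray()
    by = BSpline.design_matrix(v, ty, ky, extrapolate=True).toarray()
    # row-wise tensor product: column (i, j) = bx[:, i] * by[:, j]
    return (bx[:, :, None] * by[:, None, :]).reshape(len(u), -1)


def fit_model(
    records,
    degrees: tuple[int, int] = (2, 1),
    smoothing: float = 0.0,
    interior_knots: tuple[int, int] = (0, 0),
) -> SplineModel:
    """Fit the insert-factor surface to one group of measurements.

    Parameters
    ----------
    records : iterable of MeasurementRecord
        At least :data:`MIN_TRAINING_POINTS` records sharing one
        (machine, energy, applicator, SSD) key.
    degrees : (int, int)
        Spline degrees along width and P/A.
    smoothing : float
        Ridge weight on the coefficients; 0 is the closest (plain
        least-squares) fit.
    interior_knots : (int, int)
        Number of interior knots per axis, placed at data quantiles.

    Raises
    ------
    InsufficientDataError
        Fewer than eight records (the floor holds regardless of how small
        the chosen basis is).
    DegenerateDesignError
        Rank-deficient design, e.g. all records at a single width.
    """
    records = list(records)
    keys = {r.key for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span several model keys: {sorted(keys)}")
    if len(records) < MIN_TRAINING_POINTS:
        key = next(iter(keys)) if keys else None
        raise InsufficientDataError(
            f"model for key {key} needs at least {MIN_TRAINING_POINTS} measured "
            f"insert factors, got {len(records)}"
        )
    if smoothing < 0:
        raise ValueError(f"smoothing must be >= 0, got {smoothing}")

    # canonical order makes the fit independent of input permutation
    records.sort(key=lambda r: (r.width_cm, r.pa_ratio_per_cm, r.shape_id))
    width = np.array([r.width_cm for r in records])
    pa = np.array([r.pa_ratio_per_cm for r in records])
    factor = np.array([r.insert_factor for r in records])

    w_range = (float(width.min()), float(width.max()))
    p_range = (float(pa.min()), float(pa.max()))
    if w_range[1] - w_range[0] < 1e-12 or p_range[1] - p_range[0] < 1e-12:
        raise DegenerateDesignError(
            "training design is degenerate: zero spread along "
            + ("width" if w_range[1] - w_range[0] < 1e-12 else "P/A")
        )
    u = (width - w_range[0]) / (w_range[1] - w_range[0])
    v = (pa - p_range[0]) / (p_range[1] - p_range[0])

    kx, ky = degrees
    tx = _clamped_knots(u, kx, interior_knots[0])
    ty = _clamped_knots(v, ky, interior_knots[1])
    n_bx = len(tx) - kx - 1
    n_by = len(ty) - ky - 1

    design = _design_matrix(u, v, tx, ty, kx, ky)
    if np.linalg.matrix_rank(design) < n_bx * n_by:
        raise DegenerateDesignError(
            f"design matrix is rank-deficient for degrees {degrees} with "
            f"{len(records)} points; measurements do not spread over the "
            "(width, P/A) plane"
        )
    if smoothing > 0:
        a = design.T @ design + smoothing * np.eye(design.shape[1])
        coef = np.linalg.solve(a, design.T @ factor)
    else:
        coef, *_ = np.linalg.lstsq(design, factor, rcond=None)

    return SplineModel(
        key=records[0].key,
        degrees=(kx, ky),
        smoothing=float(smoothing),
        training_points=np.column_stack([width, pa, factor]),
        knots_width=tx,
        knots_pa=ty,
        coefficients=coef.reshape(n_bx, n_by),
        width_range=w_range,
        pa_range=p_range,
    )


def predict(model: SplineModel, ellipse) -> PredictionResult:
    """Insert factor for a parameterized shape, with an extrapolation flag.

    ``ellipse`` may be an :class:`EquivalentEllipse` or a ``(width, pa)``
    pair.  Queries outside the training hull still return a value but are
    flagged and logged as extrapolation.
    """
    if isinstance(ellipse, EquivalentEllipse):
        width, pa = ellipse.width_cm, ellipse.pa_ratio_per_cm
    else:
        width, pa = map(float, ellipse)
    value = float(model.evaluate(width, pa))
    inside = model.in_hull(width, pa)
    if not inside:
        logger.warning(
            "query (width=%.3f cm, P/A=%.3f /cm) lies outside the training hull "
            "of model %s: factor %.4f is an extrapolation", width, pa, model.key, value,
        )
    return PredictionResult(insert_factor=value, extrapolated=not inside)


@dataclass(frozen=True)
class LooResult:
    shape_id: str
    measured: float
    predicted: float
    percent_difference: float  # 100·(predicted − measured)/measured


def loo_errors(records, **fit_kwargs) -> tuple[list[LooResult], float]:
    """Leave-one-out refit errors, a desk-scale uncertainty estimate.

    Each record is withheld in turn, the model refitted on the rest (which
    must still satisfy the eight-point floor, hence nine records minimum),
    and the withheld factor predicted.  Returns the per-record results and
    the mean absolute percent difference.
    """
    records = list(records)
    if len(records) < MIN_TRAINING_POINTS + 1:
        raise InsufficientDataError(
            f"leave-one-out needs at least {MIN_TRAINING_POINTS + 1} records so each "
            f"fold keeps {MIN_TRAINING_POINTS}, got {len(records)}"
        )
    results = []
    for i, held_out in enumerate(records):
        fold = records[:i] + records[i + 1:]
        model = fit_model(fold, **fit_kwargs)
        pred = predict(model, (held_out.width_cm, held_out.pa_ratio_per_cm))
        pct = 100.0 * (pred.insert_factor - held_out.insert_factor) / held_out.insert_factor
        results.append(
            LooResult(
                shape_id=held_out.shape_id,
                measured=held_out.insert_factor,
                predicted=pred.insert_factor,
                percent_difference=pct,
            )
        )
    mean_abs = float(np.mean([abs(r.percent_difference) for r in results]))
    return results, mean_abs


# ---------------------------------------------------------------------------
# serialization: versioned JSON, exact round-trip

def save_model(model: SplineModel, path) -> None:
    doc = {
        "format": "insertfactors-spline-model",
        "version": _SERIAL_VERSION,
        "key": list(model.key),
        "degrees": list(model.degrees),
        "smoothing": model.smoothing,
        "width_range": list(model.width_range),
        "pa_range": list(model.pa_range),
        "knots_width": model.knots_width.tolist(),
        "knots_pa": model.knots_pa.tolist(),
        "coefficients": model.coefficients.tolist(),
        "training_points": model.training_points.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> SplineModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "insertfactors-spline-model":
        raise ValueError(f"{path}: not a spline-model document")
    if doc.get("version") != _SERIAL_VERSION:
        raise ValueError(f"{path}: unsupported model version {doc.get('version')}")
    key = doc["key"]
    return SplineModel(
        key=(str(key[0]), float(key[1]), float(key[2]), float(key[3])),
        degrees=tuple(doc["degrees"]),
        smoothing=float(doc["smoothing"]),
        training_points=np.array(doc["training_points"], float),
        knots_width=np.array(doc["knots_width"], float),
        knots_pa=np.array(doc["knots_pa"], float),
        coefficients=np.array(doc["coefficients"], float),
        width_range=tuple(doc["width_range"]),
        pa_range=tuple(doc["pa_range"]),
    )
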