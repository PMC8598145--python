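"""Measurement database and measurement-plan design.

One spline model exists per (machine, energy, applicator, SSD) combination,
so measured insert factors are stored grouped under that key.  The database
is a plain CSV (UTF-8, '.' decimal, header required) with columns::

    machine_id, energy_mev, applicator_cm, ssd_cm, shape_id,
    width_cm, length_cm, insert_factor, dmax_cm (optional),
    polygon_file (optional)

``pa_ratio_per_cm`` is always derived from (width, length) via the
equivalent-ellipse perimeter, so stored factors can never drift from their
coordinates.  When a row carries a ``polygon_file``, the polygon is
re-parameterized and a warning is logged if it disagrees with the stored
width/length by more than 1 %.

``design_measurement_shapes`` produces the recommended *bounding* set of
shapes to measure for a cone: ellipses whose length equals the practical
maximum diagonal of the cone with varying widths, plus circles over the
same width range — these trace the boundary of the reachable
(width, P/A) region.  For the 15 and 20 cm cones, interior shapes
(a mid-space ellipse and rectangles) are added by default, which improves
prediction accuracy in the middle of the parameter space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import DatabaseParseError, RecordValidationError
from .geometry import (
    EquivalentEllipse,
    Polygon2D,
    circle_polygon,
    ellipse_perimeter,
    ellipse_polygon,
    parameterize_shape,
    read_polygon_file,
    rectangle_polygon,
)
from .rtplan import BeamContext

__all__ = [
    "MeasurementRecord",
    "MeasurementDatabase",
    "load_database",
    "save_database",
    "design_measurement_shapes",
    "coverage_report",
    "CoverageReport",
    "DEFAULT_FACTOR_BOUNDS",
    "MAX_LENGTH_LOOKUP",
]

logger = logging.getLogger(__name__)

#: sanity bounds on a measured insert factor (dimensionless)
DEFAULT_FACTOR_BOUNDS = (0.5, 1.2)

#: practical maximum insert length per cone side (cm): slightly below the
#: geometric cone diagonal projected to 100 cm, the longest shape that can
#: actually be cut and mounted.
MAX_LENGTH_LOOKUP = {6.0: 7.0, 10.0: 13.0, 15.0: 19.0, 20.0: 21.0}

_CSV_COLUMNS = [
    "machine_id", "energy_mev", "applicator_cm", "ssd_cm", "shape_id",
    "width_cm", "length_cm", "insert_factor", "dmax_cm", "polygon_file",
]
_REQUIRED_COLUMNS = _CSV_COLUMNS[:8]


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured insert factor with its equivalent-ellipse coordinates."""

    context: BeamContext
    shape_id: str
    width_cm: float
    length_cm: float
    insert_factor: float
    pa_ratio_per_cm: float = field(default=float("nan"))
    dmax_cm: float | None = None

    def __post_init__(self) -> None:
        if self.width_cm > self.length_cm * (1.0 + 1e-9):
            raise RecordValidationError(
                f"{self.shape_id!r}: width {self.width_cm} exceeds length {self.length_cm}"
            )
        if math.isnan(self.pa_ratio_per_cm):
            area = math.pi * (self.width_cm / 2.0) * (self.length_cm / 2.0)
            object.__setattr__(
                self, "pa_ratio_per_cm",
                ellipse_perimeter(self.width_cm, self.length_cm) / area,
            )

    def validate_factor(self, bounds=DEFAULT_FACTOR_BOUNDS) -> "MeasurementRecord":
        lo, hi = bounds
        if not (lo < self.insert_factor < hi):
            raise RecordValidationError(
                f"{self.shape_id!r}: insert factor {self.insert_factor} outside ({lo}, {hi})"
            )
        return self

    @property
    def key(self) -> tuple[str, float, float, float]:
        return self.context.key


class MeasurementDatabase:
    """Measurement records grouped by (machine, energy, applicator, SSD)."""

    def __init__(self, records=()) -> None:
        self._groups: dict[tuple, list[MeasurementRecord]] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: MeasurementRecord) -> None:
        group = self._groups.setdefault(record.key, [])
        if any(r.shape_id == record.shape_id for r in group):
            raise RecordValidationError(
                f"duplicate shape_id {record.shape_id!r} in group {record.key}"
            )
        group.append(record)

    def keys(self):
        return self._groups.keys()

    def group(self, key) -> list[MeasurementRecord]:
        if isinstance(key, BeamContext):
            key = key.key
        return list(self._groups[key])

    def groups(self):
        return {k: list(v) for k, v in self._groups.items()}

    def records(self) -> list[MeasurementRecord]:
        return [r for g in self._groups.values() for r in g]

    def __len__(self) -> int:
        return sum(len(g) for g in self._groups.values())

    def __contains__(self, key) -> bool:
        if isinstance(key, BeamContext):
            key = key.key
        return key in self._groups


def load_database(
    path,
    factor_bounds=DEFAULT_FACTOR_BOUNDS,
    polygon_mismatch_tol: float = 0.01,
) -> MeasurementDatabase:
    """Parse a measurement database CSV; see module docstring for the dialect.

    Raises :class:`DatabaseParseError` with the offending line number on
    malformed rows and :class:`RecordValidationError` on invariant
    violations (out-of-bounds factor, width > length, duplicate shape ids).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise DatabaseParseError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatabaseParseError(f"{path}: missing required columns {missing}")

    db = MeasurementDatabase()
    for idx, row in frame.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            ctx = BeamContext(
                machine_id=str(row["machine_id"]),
                energy_mev=float(row["energy_mev"]),
                applicator_cm=float(row["applicator_cm"]),
                ssd_cm=float(row["ssd_cm"]),
            )
            dmax = row.get("dmax_cm")
            rec = MeasurementRecord(
                context=ctx,
                shape_id=str(row["shape_id"]),
                width_cm=float(row["width_cm"]),
                length_cm=float(row["length_cm"]),
                insert_factor=float(row["insert_factor"]),
                dmax_cm=None if pd.isna(dmax) else float(dmax),
            ).validate_factor(factor_bounds)
        except RecordValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise DatabaseParseError(f"{path}:{lineno}: {exc}") from exc

        polygon_file = row.get("polygon_file")
        if isinstance(polygon_file, str) and polygon_file.strip():
            poly = read_polygon_file(path.parent / polygon_file.strip())
            ellipse = parameterize_shape(poly)
            for name, stored, recomputed in (
                ("width", rec.width_cm, ellipse.width_cm),
                ("length", rec.length_cm, ellipse.length_cm),
            ):
                if abs(recomputed - stored) > polygon_mismatch_tol * stored:
                    logger.warning(
                        "%s:%d: stored %s %.4g disagrees with polygon-derived %.4g by >%g%%",
                        path, lineno, name, stored, recomputed,
                        100 * polygon_mismatch_tol,
                    )
        db.add(rec)
    return db


def save_database(db: MeasurementDatabase, path) -> None:
    """Write the CSV dialect back out; numeric text at 6 significant digits."""
    rows = []
    for rec in db.records():
        ctx = rec.context
        rows.append({
            "machine_id": ctx.machine_id,
            "energy_mev": f"{ctx.energy_mev:.6g}",
            "applicator_cm": f"{ctx.applicator_cm:.6g}",
            "ssd_cm": f"{ctx.ssd_cm:.6g}",
            "shape_id": rec.shape_id,
            "width_cm": f"{rec.width_cm:.6g}",
            "length_cm": f"{rec.length_cm:.6g}",
            "insert_factor": f"{rec.insert_factor:.6g}",
            "dmax_cm": "" if rec.dmax_cm is None else f"{rec.dmax_cm:.6g}",
            "polygon_file": "",
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# measurement-plan design

def max_practical_length(applicator_cm: float) -> float:
    """Longest insert length (cm) worth measuring for a cone.

    Looked up for the standard cones; otherwise the cone diagonal at the
    applicator end (95 cm) projected to 100 cm, rounded down to 0.5 cm.
    """
    if applicator_cm in MAX_LENGTH_LOOKUP:
        return MAX_LENGTH_LOOKUP[applicator_cm]
    diagonal = applicator_cm * math.sqrt(2.0) * (100.0 / 95.0)
    return math.floor(2.0 * diagonal) / 2.0


def design_measurement_shapes(
    applicator_cm: float,
    n_widths: int = 4,
    augment: bool | None = None,
    min_width_cm: float = 2.5,
    max_length_cm: float | None = None,
) -> list[tuple[str, Polygon2D]]:
    """Recommended (label, polygon) measurement set for one cone.

    The boundary of the reachable (width, P/A) space is traced by
    ``n_widths`` maximum-length ellipses and ``n_widths`` circles whose
    widths span ``[min_width_cm, applicator]``.  With ``augment`` (default:
    on for cones ≥ 15 cm) interior shapes are added: a mid-space ellipse
    and two rectangles, giving the model support in the middle of the
    parameter space where boundary-only designs are least accurate.
    """
    if applicator_cm <= 0:
        raise ValueError(f"applicator side must be positive, got {applicator_cm}")
    if n_widths < 4:
        raise ValueError(f"n_widths must be at least 4, got {n_widths}")
    if augment is None:
        augment = applicator_cm >= 15.0

    max_len = max_length_cm if max_length_cm is not None else max_practical_length(applicator_cm)
    max_width = min(applicator_cm, max_len)
    widths = np.linspace(min_width_cm, max_width, n_widths)

    shapes: list[tuple[str, Polygon2D]] = []
    for w in widths:
        shapes.append((f"ellipse_{w:g}x{max_len:g}", ellipse_polygon(w, max_len)))
    for w in widths:
        shapes.append((f"circle_{w:g}", circle_polygon(w)))

    if augment:
        w_mid = (min_width_cm + max_width) / 2.0
        l_mid = (w_mid + max_len) / 2.0
        shapes.append((f"ellipse_{w_mid:g}x{l_mid:g}", ellipse_polygon(w_mid, l_mid)))
        shapes.append((f"rect_{w_mid:g}x{l_mid:g}", rectangle_polygon(w_mid, l_mid)))
        w_big = round(0.55 * applicator_cm * 2.0) / 2.0
        shapes.append((f"rect_{w_big:g}x{applicator_cm:g}",
                       rectangle_polygon(w_big, applicator_cm)))
    return shapes


# ---------------------------------------------------------------------------
# coverage diagnostics

@dataclass(frozen=True)
class CoverageReport:
    """Where a query sits relative to a model's training support."""

    in_hull: bool
    nearest_distance: float          # normalized (width, P/A) units
    distances: np.ndarray = field(repr=False)  # per training point


def coverage_report(records, query: EquivalentEllipse) -> CoverageReport:
    """Hull membership and nearest-training-point distance for a query shape.

    Width and P/A are each scaled to unit range over the training group, so
    the two axes (cm and 1/cm) contribute comparably to distances.
    """
    records = list(records)
    if not records:
        raise ValueError("coverage_report needs a nonempty training group")
    pts = np.array([(r.width_cm, r.pa_ratio_per_cm) for r in records])
    q = np.array([query.width_cm, query.pa_ratio_per_cm])

    span = pts.max(axis=0) - pts.min(axis=0)
    span[span <= 0] = 1.0
    pts_n = (pts - pts.min(axis=0)) / span
    q_n = (q - pts.min(axis=0)) / span

    try:
        tri = Delaunay(pts_n)
        in_hull = bool(tri.find_simplex(q_n) >= 0)
    except QhullError:
        # degenerate (collinear) training set: fall back to segment test
        in_hull = False
    distances = np.linalg.norm(pts_n - q_n, axis=1)
    return CoverageReport(
        in_hull=in_hull,
        nearest_distance=float(distances.min()),
        distances=distances,
    )
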