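"""Equivalent-ellipse parameterization of electron cutout shapes.

An electron insert (cutout) is a patient-specific aperture cast in Cerrobend
and mounted in the applicator; its shape is drawn in the beam's-eye-view
(BEV) plane at 100 cm from the source, in cm.  The output perturbation the
insert causes — loss of lateral scatter for narrow fields, extra scatter off
the insert edge — correlates with two scalars of the shape's *equivalent
ellipse*:

* ``width``: the diameter of the largest circle fully enclosed by the shape,
* ``length``: chosen so the ellipse with those axes has the same area as the
  shape (``length = 4·area / (π·width)``).

The spline model downstream works in ``(width, P/A)`` where ``P/A`` is the
perimeter-to-area ratio of the equivalent ellipse.  The ellipse perimeter is
evaluated with Ramanujan's first approximation, which is accurate to well
below 0.05 % for clinical aspect ratios and makes the ``P/A`` axis
reproducible bit-for-bit.

The largest inscribed circle is found by iterative grid refinement over the
polygon interior (pole-of-inaccessibility search, via ``shapely``), which is
robust for the non-convex outlines real cutouts have.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.ops import polylabel as _polylabel

from .errors import InvalidShapeError

__all__ = [
    "Polygon2D",
    "EquivalentEllipse",
    "polygon_area",
    "polygon_perimeter",
    "largest_inscribed_circle",
    "parameterize_shape",
    "ellipse_perimeter",
    "circle_polygon",
    "ellipse_polygon",
    "rectangle_polygon",
    "read_polygon_file",
    "write_polygon_file",
]

#: default inscribed-circle tolerance, cm
DEFAULT_TOL = 0.005

#: vertices closer than this (cm) are treated as duplicates
_DUPLICATE_TOL = 1e-9


@dataclass(frozen=True)
class Polygon2D:
    """A simple closed polygon in the BEV plane at 100 cm, coordinates in cm.

    The first vertex is implicitly joined to the last; a trailing duplicate
    of the first vertex is dropped and consecutive duplicate vertices are
    merged on construction.  Orientation is irrelevant (areas are absolute).
    """

    vertices: np.ndarray = field(repr=False)

    def __init__(self, vertices) -> None:
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidShapeError(
                f"vertices must be an (n, 2) array of (x, y) cm pairs, got shape {arr.shape}"
            )
        if len(arr) >= 2 and np.allclose(arr[0], arr[-1], atol=_DUPLICATE_TOL, rtol=0.0):
            arr = arr[:-1]
        if len(arr) >= 2:
            keep = np.ones(len(arr), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(arr, axis=0), axis=1) > _DUPLICATE_TOL
            arr = arr[keep]
        if len(arr) < 3:
            raise InvalidShapeError("polygon needs at least 3 distinct vertices")
        shp = _ShapelyPolygon(arr)
        if not shp.is_valid:
            raise InvalidShapeError(
                "polygon must be simple (non-self-intersecting) with nonzero area"
            )
        if shp.area <= 0.0:
            raise InvalidShapeError("polygon encloses zero area")
        arr.setflags(write=False)
        object.__setattr__(self, "vertices", arr)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "Polygon2D":
        return Polygon2D(self.vertices + np.array([dx, dy]))

    def rotated(self, angle_rad: float, about: tuple[float, float] = (0.0, 0.0)) -> "Polygon2D":
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        origin = np.asarray(about, dtype=float)
        return Polygon2D((self.vertices - origin) @ rot.T + origin)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class EquivalentEllipse:
    """Equivalent-ellipse parameters of a cutout shape.

    ``width_cm`` is the diameter of the largest enclosed circle;
    ``length_cm`` satisfies the area equivalence
    ``π·(width/2)·(length/2) = area_cm2``; ``pa_ratio_per_cm`` is the
    Ramanujan perimeter of the (width, length) ellipse divided by the area.
    """

    width_cm: float
    length_cm: float
    area_cm2: float
    pa_ratio_per_cm: float

    def __post_init__(self) -> None:
        if not self.width_cm > 0.0:
            raise InvalidShapeError(f"width must be positive, got {self.width_cm}")
        # a hair of slack for the float round-trip length = 4A/(pi w)
        if self.length_cm < self.width_cm * (1.0 - 1e-12):
            raise InvalidShapeError(
                f"length ({self.length_cm}) cannot be smaller than width ({self.width_cm}): "
                "the inscribed circle's area cannot exceed the shape area"
            )
        ellipse_area = math.pi * (self.width_cm / 2.0) * (self.length_cm / 2.0)
        if not math.isclose(ellipse_area, self.area_cm2, rel_tol=1e-9):
            raise InvalidShapeError(
                f"area equivalence violated: ellipse area {ellipse_area} vs shape area {self.area_cm2}"
            )
        if not self.pa_ratio_per_cm > 0.0:
            raise InvalidShapeError("perimeter-to-area ratio must be positive")


def polygon_area(poly: Polygon2D) -> float:
    """Enclosed area in cm² (shoelace magnitude, orientation-independent)."""
    return float(poly.to_shapely().area)


def polygon_perimeter(poly: Polygon2D) -> float:
    """Boundary length of the polygon itself, cm (diagnostic only)."""
    return float(poly.to_shapely().exterior.length)


def largest_inscribed_circle(
    poly: Polygon2D, tol: float = DEFAULT_TOL
) -> tuple[tuple[float, float], float]:
    """Center and diameter (cm) of the largest circle enclosed by ``poly``.

    Iterative grid refinement over the interior: the returned center
    maximizes the distance to the polygon boundary to within ``tol``.
    """
    if not tol > 0.0:
        raise ValueError(f"tol must be positive, got {tol}")
    shp = poly.to_shapely()
    center = _polylabel(shp, tolerance=tol)
    radius = shp.exterior.distance(center)
    return (float(center.x), float(center.y)), 2.0 * float(radius)


def ellipse_perimeter(width_cm: float, length_cm: float) -> float:
    """Perimeter of the ellipse with the given full axes, cm.

    Ramanujan's first approximation,
    ``P ≈ π[3(a+b) − √((3a+b)(a+3b))]`` with semi-axes ``a = length/2`` and
    ``b = width/2``.  No closed form exists; this approximation is used so
    the P/A coordinate is a deterministic, documented function of
    (width, length).
    """
    a = length_cm / 2.0
    b = width_cm / 2.0
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def parameterize_shape(poly: Polygon2D, tol: float = DEFAULT_TOL) -> EquivalentEllipse:
    """Map a cutout polygon to its equivalent ellipse.

    Width is the largest-inscribed-circle diameter; length is fixed by area
    equivalence; P/A is the Ramanujan perimeter of the resulting ellipse
    over the shape area.  Invariant under translation and rigid rotation of
    the polygon (to within ``tol``).
    """
    area = polygon_area(poly)
    _, width = largest_inscribed_circle(poly, tol=tol)
    length = 4.0 * area / (math.pi * width)
    perimeter = ellipse_perimeter(width, length)
    return EquivalentEllipse(
        width_cm=width,
        length_cm=length,
        area_cm2=area,
        pa_ratio_per_cm=perimeter / area,
    )


# ---------------------------------------------------------------------------
# shape constructors (measurement-plan ellipses/circles, test shapes)

def ellipse_polygon(
    width_cm: float,
    length_cm: float,
    n_vertices: int = 128,
    center: tuple[float, float] = (0.0, 0.0),
    angle_rad: float = 0.0,
) -> Polygon2D:
    """Polygonal approximation of an ellipse, width along x, length along y."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    xy = np.column_stack(
        [(width_cm / 2.0) * np.cos(theta), (length_cm / 2.0) * np.sin(theta)]
    )
    if angle_rad:
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        xy = xy @ np.array([[c, s], [-s, c]])
    return Polygon2D(xy + np.asarray(center))


def circle_polygon(
    diameter_cm: float, n_vertices: int = 128, center: tuple[float, float] = (0.0, 0.0)
) -> Polygon2D:
    return ellipse_polygon(diameter_cm, diameter_cm, n_vertices, center)


def rectangle_polygon(
    width_cm: float, length_cm: float, center: tuple[float, float] = (0.0, 0.0)
) -> Polygon2D:
    """Axis-aligned rectangle, width along x, length along y."""
    hw, hl = width_cm / 2.0, length_cm / 2.0
    cx, cy = center
    return Polygon2D(
        [(cx - hw, cy - hl), (cx + hw, cy - hl), (cx + hw, cy + hl), (cx - hw, cy + hl)]
    )


# ---------------------------------------------------------------------------
# plain-text polygon files: one "x,y" (cm) per line, '#' comments

def read_polygon_file(path) -> Polygon2D:
    vertices = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise InvalidShapeError(
                    f"{path}:{lineno}: expected 'x,y', got {raw.strip()!r}"
                )
            try:
                vertices.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise InvalidShapeError(f"{path}:{lineno}: {exc}") from exc
    return Polygon2D(vertices)


def write_polygon_file(poly: Polygon2D, path, comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cutout outline, x,y in cm at the 100 cm BEV plane\n")
        if comment:
            fh.write(f"# {comment}\n")
        for x, y in poly.vertices:
            fh.write(f"{x:.6g},{y:.6g}\n")
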