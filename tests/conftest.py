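import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial import ConvexHull

from insertfactors import BeamContext, MeasurementRecord, Polygon2D
from insertfactors.geometry import ellipse_perimeter

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ctx():
    return BeamContext("TrueBeam", 12.0, 10.0, 100.0)


def pa_of(width, length):
    """P/A ratio of the ellipse with the given full axes."""
    area = math.pi * (width / 2.0) * (length / 2.0)
    return ellipse_perimeter(width, length) / area


def make_record(ctx, shape_id, width, length, factor):
    return MeasurementRecord(
        context=ctx, shape_id=shape_id, width_cm=width, length_cm=length,
        insert_factor=factor,
    )


def records_from_surface(ctx, f, dims):
    """Records with factor = f(width, pa) at the given (width, length) dims."""
    records = []
    for i, (w, l) in enumerate(dims):
        pa = pa_of(w, l)
        records.append(make_record(ctx, f"s{i:02d}", w, l, f(w, pa)))
    return records


#: a well-conditioned 10-point design: 5 widths at two length levels
WELL_CONDITIONED_DIMS = [
    (2.5, 2.5), (2.5, 13.0),
    (4.0, 4.0), (4.0, 12.0),
    (5.5, 5.5), (5.5, 11.0),
    (7.0, 7.0), (7.0, 11.0),
    (9.0, 9.0), (9.0, 13.0),
]


def random_convex_polygon(rng, n_points=14, r_min=1.0, r_max=4.5):
    """Convex hull of random points in an annulus — a generic convex cutout."""
    while True:
        ang = rng.uniform(0.0, 2.0 * np.pi, n_points)
        rad = rng.uniform(r_min, r_max, n_points)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        hull = ConvexHull(pts)
        if len(hull.vertices) >= 4:
            return Polygon2D(pts[hull.vertices])


def grid_inscribed_diameter(poly, pitch):
    """Brute-force largest-inscribed-circle diameter: dense interior grid,
    min distance to the boundary at each grid point, take the best."""
    import shapely

    shp = poly.to_shapely()
    minx, miny, maxx, maxy = shp.bounds
    xs = np.arange(minx, maxx + pitch, pitch)
    ys = np.arange(miny, maxy + pitch, pitch)
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    inside = shapely.contains(shp, pts)
    if not inside.any():
        return 0.0
    dists = shapely.distance(shp.exterior, pts[inside])
    return 2.0 * float(dists.max())
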