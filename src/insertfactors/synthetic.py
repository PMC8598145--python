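"""Synthetic output-factor surfaces for end-to-end testing.

No public dataset pairs the recommended model-input shapes with their
measured insert factors, so the pipeline is exercised against a synthetic
ground truth instead: a smooth surface

    f(w, r) = plateau − a·exp(−w / w0) − b·(r − r0)·[r > r0]

over width ``w`` (cm) and equivalent-ellipse P/A ratio ``r`` (1/cm).  The
exponential term emulates the loss of lateral scatter for narrow fields
(output drops steeply once the width shrinks toward the electron scatter
range), and the hinge term a mild extra-edge-scatter penalty for shapes
with large perimeter relative to area.  With the default parameters the
surface stays within (0.5, 1.1) over the clinical domain
``w ∈ [2, 20] cm, r ∈ [0.2, 2.0] /cm`` and reproduces the qualitative
ordering seen clinically: small narrow inserts around 0.86–0.95, large
inserts near 1.00.

Measurement noise is homoscedastic Gaussian on the factor (repeated
100 MU chamber readings are averaged upstream, so a normal desk-scale
stand-in is reasonable); the generator is NumPy's default PCG64, fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .database import (
    MeasurementDatabase,
    MeasurementRecord,
    design_measurement_shapes,
)
from .geometry import ellipse_perimeter, parameterize_shape
from .model import fit_model
from .rtplan import BeamContext

__all__ = [
    "SyntheticSurface",
    "sample_measurements",
    "synthetic_database",
    "recovery_experiment",
    "RecoveryResult",
]

#: chamber-repeatability scale used in end-to-end tests (absolute factor units)
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class SyntheticSurface:
    """Parametric ground-truth insert-factor surface with seeded noise."""

    plateau: float = 1.0
    amplitude: float = 0.25       # small-field falloff depth
    width_scale_cm: float = 2.5   # e-folding width of the falloff
    pa_slope: float = 0.05        # edge-scatter penalty per (1/cm) above threshold
    pa_threshold: float = 0.6     # P/A below which no penalty applies
    noise_sd: float = 0.0
    seed: int = 0

    def factor(self, width_cm, pa_ratio_per_cm):
        """Noise-free surface value; vectorized."""
        w = np.asarray(width_cm, dtype=float)
        r = np.asarray(pa_ratio_per_cm, dtype=float)
        out = (
            self.plateau
            - self.amplitude * np.exp(-w / self.width_scale_cm)
            - self.pa_slope * np.where(r > self.pa_threshold, r - self.pa_threshold, 0.0)
        )
        return out if out.ndim else float(out)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SyntheticSurface":
        return replace(self, seed=seed)


def sample_measurements(
    surface,
    shapes,
    context: BeamContext,
) -> list[MeasurementRecord]:
    """Simulated measurement session: parameterize each shape, read a factor.

    ``shapes`` is a list of ``(shape_id, Polygon2D)``; each polygon goes
    through the real parameterization path, and its factor is the surface
    value plus seeded Gaussian noise of ``surface.noise_sd``.
    """
    rng = surface.rng()
    records = []
    for shape_id, poly in shapes:
        ellipse = parameterize_shape(poly)
        factor = float(surface.factor(ellipse.width_cm, ellipse.pa_ratio_per_cm))
        if surface.noise_sd > 0:
            factor += float(rng.normal(0.0, surface.noise_sd))
        records.append(
            MeasurementRecord(
                context=context,
                shape_id=shape_id,
                width_cm=ellipse.width_cm,
                length_cm=ellipse.length_cm,
                insert_factor=factor,
                pa_ratio_per_cm=ellipse.pa_ratio_per_cm,
            )
        )
    return records


def synthetic_database(
    surface=None,
    applicators=(6.0, 10.0, 15.0, 20.0),
    machine_id: str = "SYNTH-TB",
    energy_mev: float = 12.0,
    ssd_cm: float = 100.0,
) -> MeasurementDatabase:
    """A full synthetic measurement database (one group per applicator)."""
    surface = surface or SyntheticSurface(noise_sd=DEFAULT_NOISE_SD)
    db = MeasurementDatabase()
    for i, app in enumerate(applicators):
        ctx = BeamContext(machine_id, energy_mev, app, ssd_cm)
        shapes = design_measurement_shapes(app)
        for rec in sample_measurements(surface.with_seed(surface.seed + i), shapes, ctx):
            db.add(rec)
    return db


def _interior_probes(shapes, n_grid: int = 12):
    """(width, P/A) probe points inside a design's training hull, built from
    realistic ellipse dimensions rather than free parameter pairs."""
    from scipy.spatial import Delaunay

    ellipses = [parameterize_shape(poly) for _, poly in shapes]
    widths = np.array([e.width_cm for e in ellipses])
    lengths = np.array([e.length_cm for e in ellipses])
    pts = np.array([(e.width_cm, e.pa_ratio_per_cm) for e in ellipses])
    tri = Delaunay(pts)

    probes = []
    for w in np.linspace(widths.min(), widths.max(), n_grid):
        for l in np.linspace(w, lengths.max(), n_grid):
            area = np.pi * (w / 2) * (l / 2)
            pa = ellipse_perimeter(w, l) / area
            if tri.find_simplex(np.array([w, pa])) >= 0:
                probes.append((w, pa))
    return np.array(probes)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-design prediction-error statistics from a recovery experiment."""

    design: str
    n_shapes: int
    n_probes: int
    bias: float              # mean signed error over probes and replicates
    rmse: float
    max_abs_error: float     # worst probe over all replicates
    mean_max_abs_error: float  # per-replicate max, averaged over replicates
    per_replicate_max: np.ndarray


def _run_design(surface, shapes, context, probes, n_replicates, seed, **fit_kwargs):
    errors = []
    for rep in range(n_replicates):
        rep_surface = surface.with_seed(seed + rep)
        records = sample_measurements(rep_surface, shapes, context)
        model = fit_model(records, **fit_kwargs)
        pred = model.evaluate(probes[:, 0], probes[:, 1])
        truth = surface.factor(probes[:, 0], probes[:, 1])
        errors.append(np.atleast_1d(pred) - np.atleast_1d(truth))
    err = np.array(errors)  # (replicates, probes)
    return RecoveryResult(
        design="",
        n_shapes=len(shapes),
        n_probes=probes.shape[0],
        bias=float(err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        max_abs_error=float(np.abs(err).max()),
        mean_max_abs_error=float(np.abs(err).max(axis=1).mean()),
        per_replicate_max=np.abs(err).max(axis=1),
    )


def recovery_experiment(
    surface=None,
    applicator_cm: float = 10.0,
    n_replicates: int = 20,
    seed: int = 42,
    **fit_kwargs,
) -> dict[str, RecoveryResult]:
    """Paired boundary-only vs augmented design comparison.

    For each replicate, a fresh noisy measurement set is drawn for the
    boundary-only (8-shape) and augmented (≥ 10-shape) designs of the given
    applicator, models are fitted, and predictions are compared with the
    noise-free surface at interior probe points common to both designs.
    Interior augmentation is expected to not worsen — and for larger cones
    to improve — the replicate-averaged maximum interior error.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    surface = surface if surface is not None else SyntheticSurface(noise_sd=DEFAULT_NOISE_SD)
    context = BeamContext("SYNTH", 12.0, applicator_cm, 100.0)

    boundary = design_measurement_shapes(applicator_cm, augment=False)
    augmented = design_measurement_shapes(applicator_cm, augment=True)

    # probes from the boundary design's hull: interior to both designs
    probes = _interior_probes(boundary)

    out = {}
    for name, shapes in (("boundary", boundary), ("augmented", augmented)):
        res = _run_design(surface, shapes, context, probes, n_replicates, seed, **fit_kwargs)
        out[name] = replace(res, design=name)
    return out
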