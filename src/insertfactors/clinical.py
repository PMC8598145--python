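"""Monitor-unit calculation, SSD interpolation, and prediction reports.

The monitor units delivering a prescribed dose with an electron field are

    MU = Dose / (calibration · isodose_fraction · cone_factor · insert_factor)

with the calibration output conventionally 1 cGy/MU at reference
conditions, the prescription carried to an isodose line (e.g. 0.9 for the
90 % line), the cone (applicator) factor a measured commissioning input,
and the insert factor supplied by the spline model (or by measurement).

Models exist at the commissioned SSDs of 100, 105, and 110 cm.  For an
intermediate treatment SSD the insert factor can be interpolated: predicted
factors follow a quadratic trend in SSD closely enough that the unique
second-order polynomial through the three modeled SSDs is used.  This
interpolation is preliminary and is labeled as such in reports.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .database import CoverageReport
from .geometry import EquivalentEllipse, Polygon2D
from .rtplan import BeamContext

__all__ = [
    "PrescriptionInputs",
    "compute_mu",
    "dose_for_mu",
    "interpolate_ssd",
    "ReportDiagnostics",
    "build_report",
    "round_decimal",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrescriptionInputs:
    """Everything the MU formula needs, all dimensionless except the dose."""

    dose_cgy: float
    insert_factor: float
    cone_factor: float = 1.0
    prescribed_isodose_fraction: float = 1.0
    calibration_cgy_per_mu: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "dose_cgy", "insert_factor", "cone_factor",
            "prescribed_isodose_fraction", "calibration_cgy_per_mu",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.prescribed_isodose_fraction > 1.0:
            raise ValueError(
                f"prescribed isodose fraction must be ≤ 1, got {self.prescribed_isodose_fraction}"
            )


def compute_mu(rx: PrescriptionInputs) -> float:
    """Monitor units for the prescription; strictly decreasing in each factor."""
    return rx.dose_cgy / (
        rx.calibration_cgy_per_mu
        * rx.prescribed_isodose_fraction
        * rx.cone_factor
        * rx.insert_factor
    )


def dose_for_mu(mu: float, rx: PrescriptionInputs) -> float:
    """Inverse of :func:`compute_mu`: dose (cGy) a given MU delivers."""
    return mu * (
        rx.calibration_cgy_per_mu
        * rx.prescribed_isodose_fraction
        * rx.cone_factor
        * rx.insert_factor
    )


def interpolate_ssd(
    nodes, target_ssd_cm: float, valid_range=(100.0, 110.0)
) -> tuple[float, bool]:
    """Insert factor at an arbitrary SSD from factors at three modeled SSDs.

    ``nodes`` is a sequence of exactly three ``(ssd_cm, factor)`` pairs with
    distinct SSDs (clinically 100, 105, 110).  The unique quadratic through
    them is evaluated at ``target_ssd_cm`` (Lagrange form, so each node is
    reproduced exactly).  Returns ``(factor, extrapolated)``; queries
    outside ``valid_range`` are flagged, not refused.
    """
    nodes = [(float(s), float(f)) for s, f in nodes]
    if len(nodes) != 3:
        raise ValueError(f"exactly three (ssd, factor) nodes required, got {len(nodes)}")
    ssds = [s for s, _ in nodes]
    if len(set(ssds)) != 3:
        raise ValueError(f"SSD nodes must be distinct, got {ssds}")

    t = float(target_ssd_cm)
    value = 0.0
    for i, (xi, fi) in enumerate(nodes):
        basis = 1.0
        for j, (xj, _) in enumerate(nodes):
            if j != i:
                basis *= (t - xj) / (xi - xj)
        value += fi * basis

    lo, hi = valid_range
    extrapolated = not (lo <= t <= hi)
    if extrapolated:
        logger.warning(
            "SSD %.1f cm outside the modeled range [%g, %g]: quadratic "
            "extrapolation of the insert factor", t, lo, hi,
        )
    return value, extrapolated


# ---------------------------------------------------------------------------
# report generation

def round_decimal(value: float, places: int) -> str:
    """Fixed-point text at ``places`` decimals, decimal half-up on the
    shortest decimal representation (the convention clinical calculation
    systems print; full precision is always retained internally)."""
    q = Decimal(1).scaleb(-places)
    return str(Decimal(str(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReportDiagnostics:
    """Provenance and coverage context shown alongside a prediction."""

    extrapolated: bool = False
    coverage: CoverageReport | None = None
    model_key: tuple | None = None
    database_path: str | None = None
    database_sha256: str | None = None
    ssd_interpolated: bool = False
    notes: tuple[str, ...] = ()


def database_hash(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


_SECTIONS = (
    "BEAM PARAMETERS",
    "INSERT SHAPE",
    "SHAPE PARAMETERIZATION",
    "PREDICTED INSERT FACTOR",
    "DIAGNOSTICS",
    "PROVENANCE",
)


def render_report_text(
    ctx: BeamContext,
    poly: Polygon2D,
    ellipse: EquivalentEllipse,
    insert_factor: float,
    diagnostics: ReportDiagnostics | None = None,
) -> str:
    """Plain-text prediction report (the authoritative twin of the PDF)."""
    diag = diagnostics or ReportDiagnostics()
    xs, ys = poly.vertices[:, 0], poly.vertices[:, 1]
    lines: list[str] = ["ELECTRON INSERT FACTOR REPORT", "=" * 29, ""]
    if diag.extrapolated:
        lines += [
            "*" * 62,
            "* WARNING: query lies OUTSIDE the measured parameter space — *",
            "* the insert factor below is an EXTRAPOLATION.               *",
            "*" * 62,
            "",
        ]
    lines += [
        "BEAM PARAMETERS",
        f"  machine:            {ctx.machine_id}",
        f"  nominal energy:     {ctx.energy_mev:g} MeV",
        f"  applicator (cone):  {ctx.applicator_cm:g} x {ctx.applicator_cm:g} cm",
        f"  SSD:                {ctx.ssd_cm:g} cm",
        "",
        "INSERT SHAPE",
        f"  vertices:           {len(poly)}",
        f"  extent:             {xs.max() - xs.min():.2f} x {ys.max() - ys.min():.2f} cm",
        f"  area:               {ellipse.area_cm2:.3f} cm^2",
        "",
        "SHAPE PARAMETERIZATION (equivalent ellipse)",
        f"  width:              {round_decimal(ellipse.width_cm, 3)} cm",
        f"  length:             {round_decimal(ellipse.length_cm, 3)} cm",
        f"  P/A ratio:          {round_decimal(ellipse.pa_ratio_per_cm, 4)} /cm",
        "",
        "PREDICTED INSERT FACTOR",
        f"  insert factor:      {round_decimal(insert_factor, 3)}",
        "",
        "DIAGNOSTICS",
        f"  extrapolation:      {'YES — see warning above' if diag.extrapolated else 'no'}",
    ]
    if diag.coverage is not None:
        lines += [
            f"  inside training hull: {'yes' if diag.coverage.in_hull else 'no'}",
            f"  nearest training point: {diag.coverage.nearest_distance:.3f} "
            "(normalized width/PA units)",
        ]
    if diag.ssd_interpolated:
        lines.append(
            "  SSD interpolation:  PRELIMINARY quadratic fit between modeled SSDs"
        )
    for note in diag.notes:
        lines.append(f"  note: {note}")
    lines += [
        "",
        "PROVENANCE",
        f"  model key:          {diag.model_key if diag.model_key else 'n/a'}",
        f"  database:           {diag.database_path or 'n/a'}",
        f"  database sha256:    {diag.database_sha256 or 'n/a'}",
        "",
    ]
    return "\n".join(lines)


def build_report(
    ctx: BeamContext,
    poly: Polygon2D,
    ellipse: EquivalentEllipse,
    insert_factor: float,
    diagnostics: ReportDiagnostics | None = None,
    pdf_path=None,
    text_path=None,
) -> str:
    """Render the prediction report; optionally write the PDF and text twin.

    The PDF shows the cutout outline with its equivalent ellipse overlaid
    and the same six sections as the text report.  Returns the report text.
    """
    text = render_report_text(ctx, poly, ellipse, insert_factor, diagnostics)
    if text_path is not None:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(text)
    if pdf_path is not None:
        _write_report_pdf(text, poly, ellipse, pdf_path,
                          extrapolated=bool(diagnostics and diagnostics.extrapolated))
    return text


def _write_report_pdf(text, poly, ellipse, pdf_path, extrapolated=False):
    from matplotlib.figure import Figure

    fig = Figure(figsize=(8.27, 11.69))  # A4
    ax = fig.add_axes([0.55, 0.55, 0.4, 0.35])
    xs = np.append(poly.vertices[:, 0], poly.vertices[0, 0])
    ys = np.append(poly.vertices[:, 1], poly.vertices[0, 1])
    ax.plot(xs, ys, "-", color="tab:blue", label="insert outline")
    cx, cy = poly.vertices[:, 0].mean(), poly.vertices[:, 1].mean()
    theta = np.linspace(0, 2 * np.pi, 181)
    ax.plot(
        cx + (ellipse.width_cm / 2) * np.cos(theta),
        cy + (ellipse.length_cm / 2) * np.sin(theta),
        "--", color="tab:red", label="equivalent ellipse",
    )
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.legend(fontsize=7, loc="upper right")
    ax.set_title("BEV at 100 cm", fontsize=9)

    fig.text(0.05, 0.97, text, va="top", ha="left", family="monospace", fontsize=7,
             color="firebrick" if extrapolated else "black")
    fig.savefig(pdf_path, format="pdf")
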