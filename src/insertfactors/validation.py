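"""Measured-vs-predicted agreement statistics.

Clinical acceptance of the prediction technique rests on comparing model
predictions against independently measured insert factors.  The package
ships two published clinical validation datasets as fixtures:

* ``patient_inserts.csv`` — 22 patient cutouts under treatment, measured on
  a Varian iX;
* ``standard_inserts.csv`` — 26 standard circular/elliptical cutouts,
  measured on a Varian TrueBeam.

The percent-difference convention is ``100·(predicted − measured)/measured``
(so a positive difference means the model over-predicts the output).  When
factors are printed to three decimals, a recomputed difference may disagree
with a printed one by up to 0.1, so fixture difference columns are trusted
as given unless recomputation is requested.

``summarize`` reports both signed and absolute aggregate statistics — the
two standard deviations answer different questions and are labeled
explicitly — and, when the sample is large enough, the location/scale of a
Gaussian fitted to the histogram of signed differences.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import GaussianFitError
from .rtplan import BeamContext

__all__ = [
    "ValidationPair",
    "ValidationSummary",
    "summarize",
    "fit_gaussian_histogram",
    "load_validation_pairs",
    "patient_validation_pairs",
    "standard_validation_pairs",
]


@dataclass(frozen=True)
class ValidationPair:
    """One measured/predicted insert-factor comparison."""

    label: str
    context: BeamContext
    measured_factor: float
    predicted_factor: float
    percent_difference: float

    @staticmethod
    def compute_percent_difference(measured: float, predicted: float) -> float:
        return 100.0 * (predicted - measured) / measured


@dataclass(frozen=True)
class ValidationSummary:
    """Aggregate agreement statistics over a set of validation pairs.

    ``sd_signed_pct`` is the n−1 standard deviation of the signed percent
    differences (spread of the agreement distribution); ``sd_abs_pct`` is
    the n−1 standard deviation of their absolute values (spread of the
    error magnitudes).  Neither bounds the other in general, so both are
    reported.  ``gaussian_mu``/``gaussian_sigma`` come from a least-squares
    Gaussian fit to the histogram of signed differences and are ``None``
    when the sample is too small or the histogram degenerate.
    """

    n: int
    mean_abs_pct: float
    max_abs_pct: float
    mean_signed_pct: float
    sd_signed_pct: float
    sd_abs_pct: float
    gaussian_mu: float | None = None
    gaussian_sigma: float | None = None


def summarize(
    pairs,
    recompute: bool = False,
    gaussian_bin_width: float = 0.5,
) -> ValidationSummary:
    """Aggregate a list of :class:`ValidationPair`; permutation-invariant.

    With ``recompute=True`` the percent differences are recomputed from the
    factor columns instead of trusting the stored differences.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError(
            f"at least two pairs are needed for standard deviations, got {len(pairs)}"
        )
    if recompute:
        diffs = np.array([
            ValidationPair.compute_percent_difference(p.measured_factor, p.predicted_factor)
            for p in pairs
        ])
    else:
        diffs = np.array([p.percent_difference for p in pairs])

    gaussian_mu = gaussian_sigma = None
    if len(diffs) >= 8:
        try:
            gaussian_mu, gaussian_sigma = fit_gaussian_histogram(
                diffs, bin_width=gaussian_bin_width
            )
        except GaussianFitError:
            pass

    return ValidationSummary(
        n=len(diffs),
        mean_abs_pct=float(np.mean(np.abs(diffs))),
        max_abs_pct=float(np.max(np.abs(diffs))),
        mean_signed_pct=float(np.mean(diffs)),
        sd_signed_pct=float(np.std(diffs, ddof=1)),
        sd_abs_pct=float(np.std(np.abs(diffs), ddof=1)),
        gaussian_mu=gaussian_mu,
        gaussian_sigma=gaussian_sigma,
    )


def fit_gaussian_histogram(differences, bin_width: float = 0.5) -> tuple[float, float]:
    """Location and scale of a Gaussian fitted to a histogram of differences.

    The signed differences are binned at ``bin_width`` (percent) and a
    scaled normal density ``A·exp(−(x−μ)²/2σ²)`` is least-squares fitted to
    the bin counts.  Raises :class:`GaussianFitError` when fewer than two
    bins are occupied (scale is then unidentifiable) or the fit fails.
    """
    diffs = np.asarray(list(differences), dtype=float)
    if len(diffs) < 8:
        raise GaussianFitError(f"need at least 8 differences, got {len(diffs)}")
    if bin_width <= 0:
        raise GaussianFitError(f"bin width must be positive, got {bin_width}")

    lo = bin_width * math.floor(diffs.min() / bin_width)
    hi = bin_width * math.ceil(diffs.max() / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(diffs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    if np.count_nonzero(counts) < 2:
        raise GaussianFitError(
            "histogram is degenerate (a single occupied bin); cannot fit a Gaussian"
        )

    def gauss(x, amplitude, mu, sigma):
        return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = (float(counts.max()), float(diffs.mean()), max(float(diffs.std()), bin_width / 2))
    # location constrained to the data range, scale to sensible positives:
    # keeps the fit identified when the histogram is far from Gaussian
    span = float(diffs.max() - diffs.min()) or bin_width
    bounds = (
        [0.0, float(diffs.min()), bin_width / 100.0],
        [np.inf, float(diffs.max()), 10.0 * span],
    )
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, bounds=bounds, maxfev=10_000)
    except RuntimeError as exc:
        raise GaussianFitError(f"Gaussian histogram fit did not converge: {exc}") from exc
    return float(popt[1]), abs(float(popt[2]))


# ---------------------------------------------------------------------------
# shipped validation fixtures

def load_validation_pairs(path_or_buffer) -> list[ValidationPair]:
    """Read validation pairs from a CSV with the fixture column layout."""
    frame = pd.read_csv(path_or_buffer)
    pairs = []
    for _, row in frame.iterrows():
        ctx = BeamContext(
            machine_id=str(row["machine_id"]),
            energy_mev=float(row["energy_mev"]),
            applicator_cm=float(row["applicator_cm"]),
            ssd_cm=float(row["ssd_cm"]),
        )
        pairs.append(
            ValidationPair(
                label=str(row["label"]),
                context=ctx,
                measured_factor=float(row["measured_factor"]),
                predicted_factor=float(row["calculated_factor"]),
                percent_difference=float(row["percent_difference"]),
            )
        )
    return pairs


def _load_fixture(name: str) -> list[ValidationPair]:
    ref = importlib.resources.files("insertfactors.data") / name
    with importlib.resources.as_file(ref) as path:
        return load_validation_pairs(path)


def patient_validation_pairs() -> list[ValidationPair]:
    """The 22 patient-cutout validation measurements (Varian iX)."""
    return _load_fixture("patient_inserts.csv")


def standard_validation_pairs() -> list[ValidationPair]:
    """The 26 standard-cutout validation measurements (Varian TrueBeam)."""
    return _load_fixture("standard_inserts.csv")
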