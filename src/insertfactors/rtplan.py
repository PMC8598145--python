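"""DICOM RT Plan reading/writing for electron insert extraction.

The treatment planning system exports an RT Plan whose electron beam carries
the applicator (cone) identifier, nominal energy, planned SSD, and the
insert outline as a block coordinate sequence.  This module pulls those out
into a :class:`BeamContext` plus a :class:`~insertfactors.geometry.Polygon2D`
in cm at the 100 cm plane, and can write a minimal, standards-conformant
plan back out (used heavily as a programmatic test fixture).

Block-plane assumption: when ``SourceToBlockTrayDistance`` is present, the
block coordinates are taken to lie at the tray plane and are projected to
the 100 cm plane by the ratio ``1000 mm / SBTD``; when absent, coordinates
are assumed to already be at 100 cm.  Coordinates are mm in the file, cm in
memory, in the beam-limiting-device frame.  This projection convention
should be validated against a real planning-system export before clinical
use; it is logged on every read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import AmbiguousBeamError, NoInsertError, WrongModalityError
from .geometry import Polygon2D

__all__ = [
    "BeamContext",
    "read_rtplan",
    "write_rtplan_fixture",
    "DEFAULT_APPLICATOR_MAP",
    "DEFAULT_ALLOWED_ENERGIES",
]

logger = logging.getLogger(__name__)

_RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"  # RT Plan Storage

#: applicator identifier → cone side length, cm
DEFAULT_APPLICATOR_MAP = {
    "A06": 6.0,
    "A6": 6.0,
    "A10": 10.0,
    "A15": 15.0,
    "A20": 20.0,
    "A25": 25.0,
}

#: clinically commissioned nominal electron energies, MeV
DEFAULT_ALLOWED_ENERGIES = (6.0, 9.0, 12.0, 16.0, 20.0)

#: clinical SSD range, cm
DEFAULT_SSD_BOUNDS = (100.0, 120.0)


@dataclass(frozen=True)
class BeamContext:
    """Machine / energy / applicator / SSD tuple an insert factor belongs to."""

    machine_id: str
    energy_mev: float
    applicator_cm: float
    ssd_cm: float

    def __post_init__(self) -> None:
        if self.energy_mev <= 0:
            raise ValueError(f"energy must be positive, got {self.energy_mev}")
        if self.applicator_cm <= 0:
            raise ValueError(f"applicator side must be positive, got {self.applicator_cm}")

    def validate(
        self,
        allowed_energies=DEFAULT_ALLOWED_ENERGIES,
        ssd_bounds=DEFAULT_SSD_BOUNDS,
    ) -> "BeamContext":
        if self.energy_mev not in allowed_energies:
            raise ValueError(
                f"energy {self.energy_mev} MeV not in allowed set {sorted(allowed_energies)}"
            )
        lo, hi = ssd_bounds
        if not (lo <= self.ssd_cm <= hi):
            raise ValueError(f"SSD {self.ssd_cm} cm outside [{lo}, {hi}]")
        return self

    @property
    def key(self) -> tuple[str, float, float, float]:
        return (self.machine_id, self.energy_mev, self.applicator_cm, self.ssd_cm)


def _applicator_id_for(applicator_cm: float) -> str:
    return f"A{int(round(applicator_cm)):02d}"


def read_rtplan(
    path,
    beam_index: int | None = None,
    applicator_map: dict[str, float] | None = None,
    allowed_energies=DEFAULT_ALLOWED_ENERGIES,
) -> tuple[BeamContext, Polygon2D]:
    """Extract (beam context, insert polygon) from an RT Plan file.

    Parameters
    ----------
    path : path-like
        RT Plan DICOM file.
    beam_index : int, optional
        Zero-based index into the plan's BeamSequence; required when the
        plan holds several beams.
    applicator_map : dict, optional
        Applicator ID text → cone side length cm (default
        :data:`DEFAULT_APPLICATOR_MAP`).
    allowed_energies : sequence of float
        Non-integer nominal energies are rounded to the nearest member,
        with a warning.
    """
    applicator_map = applicator_map or DEFAULT_APPLICATOR_MAP
    ds = pydicom.dcmread(path)
    beams = list(getattr(ds, "BeamSequence", []))
    if not beams:
        raise NoInsertError(f"{path}: plan contains no beams")
    if len(beams) > 1 and beam_index is None:
        raise AmbiguousBeamError(
            f"{path}: plan holds {len(beams)} beams; pass beam_index to select one"
        )
    beam = beams[beam_index or 0]

    radiation = str(getattr(beam, "RadiationType", "")).upper()
    if radiation != "ELECTRON":
        raise WrongModalityError(
            f"{path}: beam {beam.get('BeamNumber', '?')} is {radiation or 'unknown'}, "
            "expected ELECTRON"
        )

    blocks = list(getattr(beam, "BlockSequence", []))
    if not blocks:
        raise NoInsertError(f"{path}: electron beam carries no block/insert data")
    block = blocks[0]
    n_points = int(block.BlockNumberOfPoints)
    data = np.asarray([float(v) for v in block.BlockData], dtype=float).reshape(n_points, 2)

    sbtd = getattr(block, "SourceToBlockTrayDistance", None)
    if sbtd is not None and float(sbtd) > 0:
        scale = 1000.0 / float(sbtd)
        logger.info(
            "projecting block coordinates from tray plane (SBTD=%.1f mm) to 100 cm "
            "plane (factor %.4f)", float(sbtd), scale,
        )
        data = data * scale
    else:
        logger.info("no SourceToBlockTrayDistance; assuming block coordinates at 100 cm")
    poly = Polygon2D(data / 10.0)  # mm → cm

    cp = beam.ControlPointSequence[0]
    energy = float(cp.NominalBeamEnergy)
    if energy not in allowed_energies:
        nearest = min(allowed_energies, key=lambda e: abs(e - energy))
        logger.warning("nominal energy %.2f MeV not configured; using %.0f", energy, nearest)
        energy = nearest
    ssd_cm = float(cp.SourceToSurfaceDistance) / 10.0

    applicators = list(getattr(beam, "ApplicatorSequence", []))
    if not applicators:
        raise NoInsertError(f"{path}: electron beam carries no applicator")
    app_id = str(applicators[0].ApplicatorID).strip().upper()
    try:
        applicator_cm = applicator_map[app_id]
    except KeyError:
        raise NoInsertError(
            f"{path}: applicator ID {app_id!r} not in lookup {sorted(applicator_map)}"
        ) from None

    ctx = BeamContext(
        machine_id=str(getattr(beam, "TreatmentMachineName", "")) or "UNKNOWN",
        energy_mev=energy,
        applicator_cm=applicator_cm,
        ssd_cm=ssd_cm,
    )
    return ctx, poly


def write_rtplan_fixture(
    ctx: BeamContext,
    poly: Polygon2D,
    path,
    source_to_tray_mm: float | None = 950.0,
    radiation_type: str = "ELECTRON",
) -> None:
    """Write a minimal RT Plan holding one electron beam with an insert.

    ``read_rtplan ∘ write_rtplan_fixture`` is the identity on
    ``(ctx, poly)`` up to float rounding.  When ``source_to_tray_mm`` is
    given, block coordinates are stored at the tray plane (scaled down from
    the 100 cm plane); otherwise at 100 cm.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = _RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "FIXTURE^SYNTHETIC"
    ds.PatientID = "FIXTURE"
    ds.RTPlanLabel = "insert-fixture"

    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = "E1"
    beam.RadiationType = radiation_type
    beam.TreatmentMachineName = ctx.machine_id

    applicator = Dataset()
    applicator.ApplicatorID = _applicator_id_for(ctx.applicator_cm)
    applicator.ApplicatorType = "ELECTRON_SQUARE"
    beam.ApplicatorSequence = [applicator]

    xy_mm = poly.vertices * 10.0
    if source_to_tray_mm is not None:
        xy_mm = xy_mm * (source_to_tray_mm / 1000.0)
    block = Dataset()
    block.BlockNumber = 1
    block.BlockType = "APERTURE"
    if source_to_tray_mm is not None:
        block.SourceToBlockTrayDistance = source_to_tray_mm
    block.BlockNumberOfPoints = len(xy_mm)
    block.BlockData = [float(v) for v in xy_mm.ravel()]
    beam.BlockSequence = [block]

    cp = Dataset()
    cp.ControlPointIndex = 0
    cp.NominalBeamEnergy = ctx.energy_mev
    cp.SourceToSurfaceDistance = ctx.ssd_cm * 10.0
    beam.ControlPointSequence = [cp]

    ds.BeamSequence = [beam]
    ds.save_as(str(path), enforce_file_format=True)
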