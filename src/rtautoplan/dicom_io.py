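"""DICOM-RT reading and writing: CT series, RTSTRUCT, RTDOSE, RTPLAN.

Grids are required to be axis-aligned (identity direction cosines); oblique
acquisitions are rejected at load with a clear error, which matches axial
planning CTs and avoids resampling ambiguity. UIDs for written files are
derived deterministically from a seed so that a seeded case writes an
identical tree on every run.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .plan_layout import PlanLayout
from .volumetric import ContourSet, DoseGrid, SpatialGrid, StructureMask, mask_to_contours

__all__ = [
    "deterministic_uid",
    "read_ct_series",
    "read_rtstruct",
    "read_rtdose",
    "write_case",
    "write_rtstruct",
    "write_rtdose",
    "write_rtplan",
]

_UID_ROOT = "2.25."


def deterministic_uid(seed: int, tag: str) -> str:
    """A valid DICOM UID derived from (seed, tag) — stable across runs."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).hexdigest()
    return (_UID_ROOT + str(int(digest[:30], 16)))[:64]


def _check_axis_aligned(ds: Dataset) -> None:
    iop = [float(v) for v in ds.ImageOrientationPatient]
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-4):
        raise ValueError(
            f"oblique image orientation {iop} is not supported; only axis-aligned "
            "(identity direction cosine) axial grids can be loaded"
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_ct_series(directory: str | Path) -> tuple[np.ndarray, SpatialGrid, Dataset]:
    """Load an axial CT series from a directory of single-slice files.

    Returns (HU volume as (z, y, x) int array, grid, a reference dataset of
    the first slice for UID bookkeeping).
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    datasets = [pydicom.dcmread(str(f)) for f in files]
    # keep image slices of any modality; the modality check is a validation
    # (a non-CT planning image is flagged, not rejected)
    datasets = [d for d in datasets if hasattr(d, "ImagePositionPatient")]
    if not datasets:
        raise ValueError(f"no image slices found in {directory}")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = datasets[0]
    _check_axis_aligned(first)
    rows, cols = int(first.Rows), int(first.Columns)
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = [float(d.ImagePositionPatient[2]) for d in datasets]
    dz = float(np.diff(zs).mean()) if len(zs) > 1 else float(
        getattr(first, "SliceThickness", 1.0)
    )
    grid = SpatialGrid(
        origin=(
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            zs[0],
        ),
        spacing=(dx, dy, dz),
        dims=(cols, rows, len(datasets)),
    )
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    volume = np.stack([d.pixel_array for d in datasets]).astype(np.float64)
    volume = volume * slope + intercept
    return volume.astype(np.int16), grid, first


def read_rtstruct(path: str | Path) -> dict[str, ContourSet]:
    """Load ROI contours from an RT Structure Set, keyed by ROI name."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise ValueError(f"{path} is not an RT Structure Set")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out: dict[str, ContourSet] = {}
    for roi in getattr(ds, "ROIContourSequence", []):
        number = int(roi.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        color = tuple(int(c) for c in getattr(roi, "ROIDisplayColor", [255, 0, 0]))
        cs = ContourSet(structure_id=name, slices=[], color=color)
        by_z: dict[float, list[np.ndarray]] = {}
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.array([float(v) for v in contour.ContourData]).reshape(-1, 3)
            z = round(float(pts[0, 2]), 3)
            by_z.setdefault(z, []).append(pts[:, :2])
        cs.slices = sorted(by_z.items())
        out[name] = cs
    return out


def read_rtdose(path: str | Path) -> DoseGrid:
    """Load an RT Dose grid (dose grid scaling honored)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path} is not an RT Dose file")
    _check_axis_aligned(ds)
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(np.float64) * scaling
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = float(np.diff(offsets).mean()) if len(offsets) > 1 else 1.0
    grid = SpatialGrid(
        origin=tuple(float(v) for v in ds.ImagePositionPatient),
        spacing=(dx, dy, dz),
        dims=(int(ds.Columns), int(ds.Rows), int(ds.NumberOfFrames)),
    )
    return DoseGrid(grid, values, scaling_note=f"DoseGridScaling={scaling:g}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _base_dataset(path: Path, sop_class_uid: str, sop_instance_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = sop_instance_uid
    ds.ContentDate = "20240101"
    ds.ContentTime = "120000"
    ds.Manufacturer = "rtautoplan"
    ds.PatientName = "Phantom^HAWBRT"
    ds.PatientID = "PHANTOM"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    return ds


_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"


def write_ct_series(
    ct_hu: np.ndarray,
    grid: SpatialGrid,
    directory: Path,
    seed: int,
    acquisition_date: _dt.date | None = None,
) -> tuple[str, str, list[str]]:
    """Write one file per axial slice; returns (study UID, series UID, slice UIDs)."""
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = deterministic_uid(seed, "study")
    series_uid = deterministic_uid(seed, "ct-series")
    frame_uid = deterministic_uid(seed, "frame")
    date_str = (acquisition_date or _dt.date(2024, 1, 1)).strftime("%Y%m%d")
    slice_uids = []
    nz = grid.dims[2]
    for k in range(nz):
        uid = deterministic_uid(seed, f"ct-slice-{k}")
        slice_uids.append(uid)
        path = directory / f"CT_{k:04d}.dcm"
        ds = _base_dataset(path, _CT_SOP, uid)
        ds.Modality = "CT"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.StudyDate = date_str
        ds.SeriesDate = date_str
        ds.AcquisitionDate = date_str
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            grid.origin[0],
            grid.origin[1],
            grid.origin[2] + k * grid.spacing[2],
        ]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
        ds.SliceThickness = grid.spacing[2]
        ds.Rows, ds.Columns = grid.dims[1], grid.dims[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.ascontiguousarray(ct_hu[k]).astype(np.int16).tobytes()
        ds.save_as(str(path), enforce_file_format=True)
    return study_uid, series_uid, slice_uids


def write_rtstruct(
    masks: dict[str, StructureMask],
    path: Path,
    seed: int,
    study_uid: str,
    series_uid: str,
    slice_uids: list[str],
    colors: dict[str, tuple[int, int, int]] | None = None,
) -> str:
    """Write a structure set whose contours trace the given masks."""
    colors = colors or {}
    uid = deterministic_uid(seed, "rtstruct")
    ds = _base_dataset(path, _RTSTRUCT_SOP, uid)
    ds.Modality = "RTSTRUCT"
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = deterministic_uid(seed, "rtstruct-series")
    ds.StructureSetLabel = "AutoPlanStructs"
    ds.StructureSetDate = "20240101"
    ds.StructureSetTime = "120000"
    frame_uid = deterministic_uid(seed, "frame")

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    ref_study = Dataset()
    ref_study.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"
    ref_study.ReferencedSOPInstanceUID = study_uid
    ref_series = Dataset()
    ref_series.SeriesInstanceUID = series_uid
    ref_series.ContourImageSequence = []
    for s_uid in slice_uids:
        img = Dataset()
        img.ReferencedSOPClassUID = _CT_SOP
        img.ReferencedSOPInstanceUID = s_uid
        ref_series.ContourImageSequence.append(img)
    ref_study.RTReferencedSeriesSequence = [ref_series]
    ref_frame.RTReferencedStudySequence = [ref_study]
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for number, (name, mask) in enumerate(masks.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIName = name
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        contour_set = mask_to_contours(mask)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ROIDisplayColor = list(colors.get(name, (255, 0, 0)))
        rc.ContourSequence = []
        for z, polys in contour_set.slices:
            for poly in polys:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = poly.shape[0]
                data = np.column_stack([poly, np.full(poly.shape[0], z)])
                c.ContourData = [f"{v:.4f}" for v in data.ravel()]
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.ROIObservationLabel = name
        obs.RTROIInterpretedType = "ORGAN"
        ds.RTROIObservationsSequence.append(obs)
    ds.save_as(str(path), enforce_file_format=True)
    return uid


def write_rtdose(dose: DoseGrid, path: Path, seed: int, study_uid: str) -> str:
    """Write an RT Dose grid with 32-bit integers and an explicit scaling."""
    uid = deterministic_uid(seed, "rtdose")
    ds = _base_dataset(path, _RTDOSE_SOP, uid)
    ds.Modality = "RTDOSE"
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = deterministic_uid(seed, "rtdose-series")
    ds.FrameOfReferenceUID = deterministic_uid(seed, "frame")
    grid = dose.grid
    max_dose = float(dose.values.max())
    scaling = max(max_dose, 1e-6) / (2**31 - 1)
    ints = np.round(dose.values / scaling).astype(np.uint32)
    ds.DoseGridScaling = f"{scaling:.10e}"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = list(grid.origin)
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.GridFrameOffsetVector = [k * grid.spacing[2] for k in range(grid.dims[2])]
    ds.NumberOfFrames = grid.dims[2]
    ds.FrameIncrementPointer = (0x3004, 0x000C)
    ds.Rows, ds.Columns = grid.dims[1], grid.dims[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(ints).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return uid


def write_rtplan(
    layout: PlanLayout, path: Path, seed: int, study_uid: str, rtstruct_uid: str
) -> str:
    """Write the RT Plan skeleton: arcs, jaws, open MLC, no monitor units."""
    uid = deterministic_uid(seed, "rtplan")
    ds = _base_dataset(path, _RTPLAN_SOP, uid)
    ds.Modality = "RTPLAN"
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = deterministic_uid(seed, "rtplan-series")
    ds.FrameOfReferenceUID = deterministic_uid(seed, "frame")
    ds.RTPlanLabel = layout.plan_id
    ds.RTPlanDate = "20240101"
    ds.RTPlanTime = "120000"
    ds.RTPlanGeometry = "PATIENT"

    ref_ss = Dataset()
    ref_ss.ReferencedSOPClassUID = _RTSTRUCT_SOP
    ref_ss.ReferencedSOPInstanceUID = rtstruct_uid
    ds.ReferencedStructureSetSequence = [ref_ss]

    fx = Dataset()
    fx.FractionGroupNumber = 1
    fx.NumberOfFractionsPlanned = layout.fractions
    fx.NumberOfBeams = len(layout.fields)
    fx.NumberOfBrachyApplicationSetups = 0
    fx.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fx]

    ds.BeamSequence = []
    for number, f in enumerate(layout.fields, start=1):
        ref_beam = Dataset()
        ref_beam.ReferencedBeamNumber = number
        fx.ReferencedBeamSequence.append(ref_beam)

        beam = Dataset()
        beam.BeamNumber = number
        beam.BeamName = f.field_id
        beam.BeamType = "DYNAMIC" if f.technique == "arc" else "STATIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentMachineName = layout.machine_id
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.NumberOfWedges = 0
        beam.NumberOfCompensators = 0
        beam.NumberOfBoli = 0
        beam.NumberOfBlocks = 0
        beam.SourceAxisDistance = "1000.0"
        beam.NumberOfControlPoints = 2

        cp0 = Dataset()
        cp0.ControlPointIndex = 0
        cp0.CumulativeMetersetWeight = "0.0"
        cp0.NominalBeamEnergy = f.energy_label.rstrip("X")
        cp0.GantryAngle = f"{f.gantry_start:.1f}"
        cp0.GantryRotationDirection = "CW" if f.rotation_direction == "CW" else "CC"
        cp0.BeamLimitingDeviceAngle = f"{f.collimator_angle:.1f}"
        cp0.PatientSupportAngle = f"{f.couch_angle:.1f}"
        cp0.IsocenterPosition = [f"{v:.1f}" for v in layout.isocenter_mm]
        jaw_x = Dataset()
        jaw_x.RTBeamLimitingDeviceType = "ASYMX"
        jaw_x.LeafJawPositions = [f"{f.x1_mm:.1f}", f"{f.x2_mm:.1f}"]
        jaw_y = Dataset()
        jaw_y.RTBeamLimitingDeviceType = "ASYMY"
        jaw_y.LeafJawPositions = [f"{f.y1_mm:.1f}", f"{f.y2_mm:.1f}"]
        cp0.BeamLimitingDevicePositionSequence = [jaw_x, jaw_y]

        cp1 = Dataset()
        cp1.ControlPointIndex = 1
        cp1.CumulativeMetersetWeight = "1.0"
        cp1.GantryAngle = f"{f.gantry_stop:.1f}"
        cp1.GantryRotationDirection = "NONE"
        beam.ControlPointSequence = [cp0, cp1]
        ds.BeamSequence.append(beam)
    ds.save_as(str(path), enforce_file_format=True)
    return uid


def write_case(
    ct_hu: np.ndarray,
    grid: SpatialGrid,
    masks: dict[str, StructureMask],
    directory: str | Path,
    seed: int,
    dose: DoseGrid | None = None,
    layout: PlanLayout | None = None,
    acquisition_date: _dt.date | None = None,
) -> dict[str, str]:
    """Write a complete, internally cross-referenced DICOM case.

    Produces ``ct/`` (one file per slice), ``rtstruct.dcm`` and, when given,
    ``rtdose.dcm`` / ``rtplan.dcm``. Returns the written UIDs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid, series_uid, slice_uids = write_ct_series(
        ct_hu, grid, directory / "ct", seed, acquisition_date
    )
    rtstruct_uid = write_rtstruct(
        masks, directory / "rtstruct.dcm", seed, study_uid, series_uid, slice_uids
    )
    uids = {
        "study": study_uid,
        "ct_series": series_uid,
        "rtstruct": rtstruct_uid,
    }
    if dose is not None:
        uids["rtdose"] = write_rtdose(dose, directory / "rtdose.dcm", seed, study_uid)
    if layout is not None:
        uids["rtplan"] = write_rtplan(
            layout, directory / "rtplan.dcm", seed, study_uid, rtstruct_uid
        )
    return uids
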