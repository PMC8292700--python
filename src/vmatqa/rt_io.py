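"""Interchange I/O: DICOM-RT Plan / RT Dose, the delivery-log text dialect,
and a single-file HDF5 fixture container.

Only the subset of the RT modules used by this project is implemented
(no full DICOM conformance).  Conventions: patient coordinate system in
mm; leaf/jaw positions at the isocenter plane in mm; gantry/collimator on
the IEC scale with gantry kept signed in [-180, +180] so arcs round-trip
losslessly; cumulative meterset stored as absolute MU with
FinalCumulativeMetersetWeight equal to the beam meterset.  All dynamic
values produced by this package are quantized at source (1e-6 by the plan
generator, 1e-9 by the delivery simulator), which fits the 16-character
DICOM DS limit, so write -> read recovers every control-point field
bit-exactly.

The delivery-log dialect is a documented stand-in for the proprietary
4-Hz machine log format (whose internal layout is not public): '#'-prefixed
``key=value`` metadata lines, then a CSV with columns ``time_s,
gantry_deg, collimator_deg, mu_cumulative, jaw_{x1,x2,y1,y2}_mm,
leaf_a_01..80, leaf_b_01..80``.
"""

from __future__ import annotations

import io
import os

import h5py
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .delivery_log import DeliveryLog
from .exceptions import FormatError, ValidationError
from .grids import DoseGrid, PhantomVolume, StructureSet
from .plan import N_LEAF_PAIRS, ArcBeam, ControlPoint, VmatPlan

__all__ = [
    "read_rtplan", "write_rtplan", "read_dose", "write_dose",
    "read_log", "write_log", "save_case", "load_case",
    "PhantomVolume", "StructureSet", "DoseGrid",
]

_RTPLAN_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


def _ds_number(v: float) -> str:
    """Decimal-string representation within DICOM's 16-character limit."""
    s = repr(float(v))
    return s if len(s) <= 16 else f"{float(v):.10g}"


def _file_dataset(sop_class: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "SYN000"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    return ds


# ---------------------------------------------------------------------------
# RT Plan


def write_rtplan(plan: VmatPlan, path) -> None:
    """Write a plan as DICOM-RT Plan; readable back losslessly."""
    plan.validate()
    ds = _file_dataset(_RTPLAN_CLASS)
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.name[:16]
    ds.RTPlanName = plan.name
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    ds.BeamSequence = []
    ds.FractionGroupSequence = []
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(plan.beams)
    fg.ReferencedBeamSequence = []

    for bi, beam in enumerate(plan.beams, start=1):
        b = Dataset()
        b.BeamNumber = bi
        b.BeamName = beam.name
        b.BeamType = "DYNAMIC"
        b.RadiationType = "PHOTON"
        b.TreatmentMachineName = "SYNTH"
        b.PrimaryDosimeterUnit = "MU"
        b.SourceAxisDistance = _ds_number(plan.sad_mm)

        bld_x = Dataset()
        bld_x.RTBeamLimitingDeviceType = "ASYMX"
        bld_x.NumberOfLeafJawPairs = 1
        bld_y = Dataset()
        bld_y.RTBeamLimitingDeviceType = "ASYMY"
        bld_y.NumberOfLeafJawPairs = 1
        bld_m = Dataset()
        bld_m.RTBeamLimitingDeviceType = "MLCX"
        bld_m.NumberOfLeafJawPairs = N_LEAF_PAIRS
        bld_m.LeafPositionBoundaries = [
            _ds_number(v) for v in plan.leaf_boundaries_mm]
        b.BeamLimitingDeviceSequence = [bld_x, bld_y, bld_m]

        b.NumberOfControlPoints = beam.n_control_points
        b.FinalCumulativeMetersetWeight = _ds_number(beam.meterset_mu)
        b.ControlPointSequence = []
        for ci, cp in enumerate(beam.control_points):
            c = Dataset()
            c.ControlPointIndex = ci
            c.CumulativeMetersetWeight = _ds_number(cp.cumulative_mu)
            c.GantryAngle = _ds_number(cp.gantry_deg)
            c.GantryRotationDirection = "NONE"
            c.BeamLimitingDeviceAngle = _ds_number(cp.collimator_deg)
            if ci == 0:
                c.NominalBeamEnergy = _ds_number(
                    float(plan.energy.split()[0]))
                c.IsocenterPosition = [
                    _ds_number(v) for v in plan.isocenter_mm]
            px = Dataset()
            px.RTBeamLimitingDeviceType = "ASYMX"
            px.LeafJawPositions = [_ds_number(cp.jaws_mm[0]),
                                   _ds_number(cp.jaws_mm[1])]
            py = Dataset()
            py.RTBeamLimitingDeviceType = "ASYMY"
            py.LeafJawPositions = [_ds_number(cp.jaws_mm[2]),
                                   _ds_number(cp.jaws_mm[3])]
            pm = Dataset()
            pm.RTBeamLimitingDeviceType = "MLCX"
            pm.LeafJawPositions = (
                [_ds_number(v) for v in cp.leaves_a_mm]
                + [_ds_number(v) for v in cp.leaves_b_mm])
            c.BeamLimitingDevicePositionSequence = [px, py, pm]
            b.ControlPointSequence.append(c)
        ds.BeamSequence.append(b)

        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = _ds_number(beam.meterset_mu)
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence.append(fg)
    ds.save_as(os.fspath(path), enforce_file_format=True)


def read_rtplan(path) -> VmatPlan:
    """Read a DICOM-RT Plan with at least one arc beam.

    Control points are ordered by cumulative meterset weight; omitted
    per-control-point attributes inherit the previous control point's
    value, as DICOM allows.
    """
    try:
        ds = pydicom.dcmread(os.fspath(path))
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"not a readable DICOM file: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise FormatError("file is not an RT Plan")
    if not getattr(ds, "BeamSequence", None):
        raise FormatError("RT Plan contains no beams")

    metersets = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams = []
    isocenter = np.zeros(3)
    sad = 1000.0
    boundaries = None
    energy = "6 MV"
    for b in ds.BeamSequence:
        mlc = None
        for bld in getattr(b, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                mlc = bld
        if mlc is None:
            raise FormatError("beam has no MLC sequence")
        boundaries = np.array([float(v) for v in mlc.LeafPositionBoundaries])
        n_pairs = int(mlc.NumberOfLeafJawPairs)
        if n_pairs != N_LEAF_PAIRS:
            raise FormatError(f"expected {N_LEAF_PAIRS} leaf pairs, "
                              f"found {n_pairs}")
        sad = float(getattr(b, "SourceAxisDistance", sad))
        final_w = float(b.FinalCumulativeMetersetWeight)
        meterset = metersets.get(int(b.BeamNumber), final_w)
        scale = meterset / final_w if final_w > 0 else 1.0

        state = {"gantry": 0.0, "coll": 0.0, "jaws": np.zeros(4),
                 "la": np.zeros(N_LEAF_PAIRS), "lb": np.zeros(N_LEAF_PAIRS)}
        cps = []
        seq = sorted(b.ControlPointSequence,
                     key=lambda c: int(c.ControlPointIndex))
        for c in seq:
            if hasattr(c, "GantryAngle"):
                state["gantry"] = float(c.GantryAngle)
            if hasattr(c, "BeamLimitingDeviceAngle"):
                state["coll"] = float(c.BeamLimitingDeviceAngle)
            if hasattr(c, "NominalBeamEnergy"):
                energy = f"{float(c.NominalBeamEnergy):g} MV"
            if hasattr(c, "IsocenterPosition"):
                isocenter = np.array([float(v) for v in c.IsocenterPosition])
            for p in getattr(c, "BeamLimitingDevicePositionSequence", []):
                vals = np.array([float(v) for v in p.LeafJawPositions])
                if p.RTBeamLimitingDeviceType == "ASYMX":
                    state["jaws"] = np.array(
                        [vals[0], vals[1], state["jaws"][2], state["jaws"][3]])
                elif p.RTBeamLimitingDeviceType == "ASYMY":
                    state["jaws"] = np.array(
                        [state["jaws"][0], state["jaws"][1], vals[0], vals[1]])
                elif p.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                    if vals.size != 2 * N_LEAF_PAIRS:
                        raise FormatError("MLC position count mismatch")
                    state["la"] = vals[:N_LEAF_PAIRS]
                    state["lb"] = vals[N_LEAF_PAIRS:]
            cps.append(ControlPoint(
                gantry_deg=state["gantry"],
                collimator_deg=state["coll"],
                leaves_a_mm=state["la"].copy(),
                leaves_b_mm=state["lb"].copy(),
                jaws_mm=state["jaws"].copy(),
                cumulative_mu=float(c.CumulativeMetersetWeight) * scale,
            ))
        mu = np.array([cp.cumulative_mu for cp in cps])
        if np.any(np.diff(mu) < 0):
            raise ValidationError("non-monotonic cumulative meterset")
        cps.sort(key=lambda cp: cp.cumulative_mu)
        beams.append(ArcBeam(control_points=cps, meterset_mu=meterset,
                             name=str(getattr(b, "BeamName", "arc"))))

    plan = VmatPlan(beams=beams, isocenter_mm=isocenter, sad_mm=sad,
                    leaf_boundaries_mm=boundaries, energy=energy,
                    name=str(getattr(ds, "RTPlanName", "plan")))
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# RT Dose


def write_dose(grid: DoseGrid, path) -> None:
    """Write a dose grid as DICOM-RT Dose (32-bit, scaled integers).

    The quantization error is bounded by ``max_dose / 2^33`` per voxel.
    """
    grid.validate()
    ds = _file_dataset(_RTDOSE_CLASS)
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseComment = grid.uncertainty_label
    nx, ny, nz = grid.dose.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.ImagePositionPatient = [_ds_number(v) for v in grid.origin_mm]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [_ds_number(grid.spacing_mm[1]),
                       _ds_number(grid.spacing_mm[0])]
    ds.GridFrameOffsetVector = [
        _ds_number(k * grid.spacing_mm[2]) for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0

    max_dose = float(grid.dose.max())
    scaling = max_dose / (2 ** 32 - 1) if max_dose > 0 else 1.0
    ds.DoseGridScaling = _ds_number(scaling)
    pixels = np.round(grid.dose / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(
        pixels.transpose(2, 1, 0)).tobytes()
    ds.save_as(os.fspath(path), enforce_file_format=True)


def read_dose(path) -> DoseGrid:
    """Read a DICOM-RT Dose file written on a uniform rectilinear grid."""
    try:
        ds = pydicom.dcmread(os.fspath(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"not a readable DICOM file: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError("file is not an RT Dose")
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size > 1:
        dz = np.diff(offsets)
        if np.any(np.abs(dz - dz[0]) > 1e-6):
            raise FormatError("non-uniform slice spacing")
        dz = float(dz[0])
    else:
        dz = 1.0
    dose = (ds.pixel_array.astype(float) * float(ds.DoseGridScaling))
    dose = np.ascontiguousarray(dose.transpose(2, 1, 0))
    spacing = np.array([float(ds.PixelSpacing[1]),
                        float(ds.PixelSpacing[0]), dz])
    origin = np.array([float(v) for v in ds.ImagePositionPatient])
    label = str(getattr(ds, "DoseComment", "none"))
    if label not in DoseGrid.LABELS:
        label = "none"
    return DoseGrid(dose=dose, spacing_mm=spacing, origin_mm=origin,
                    uncertainty_label=label)


# ---------------------------------------------------------------------------
# delivery-log text dialect


_LOG_VERSION = "vmatqa-log v1"


def _log_columns() -> list[str]:
    return (["time_s", "gantry_deg", "collimator_deg", "mu_cumulative",
             "jaw_x1_mm", "jaw_x2_mm", "jaw_y1_mm", "jaw_y2_mm"]
            + [f"leaf_a_{i + 1:02d}" for i in range(N_LEAF_PAIRS)]
            + [f"leaf_b_{i + 1:02d}" for i in range(N_LEAF_PAIRS)])


def write_log(log: DeliveryLog, path) -> None:
    """Write a delivery log in the plain-text dialect (1e-9 precision)."""
    log.validate()
    df = pd.DataFrame(
        np.column_stack([log.time_s, log.gantry_deg, log.collimator_deg,
                         log.mu, log.jaws_mm, log.leaves_a_mm,
                         log.leaves_b_mm]),
        columns=_log_columns())
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"# {_LOG_VERSION}\n")
        fh.write(f"# rate_hz={log.rate_hz:g}\n")
        fh.write(f"# leaf_tolerance_mm={log.leaf_tolerance_mm:g}\n")
        fh.write(f"# gantry_tolerance_deg={log.gantry_tolerance_deg:g}\n")
        df.to_csv(fh, index=False, float_format="%.9f", lineterminator="\n")


def read_log(path) -> DeliveryLog:
    """Read a delivery log in the plain-text dialect; validates monotone
    time (0.25 s steps at 4 Hz) and non-decreasing cumulative MU."""
    with open(path, "r", encoding="ascii") as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError("empty log file")
    meta = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
        else:
            body_lines.append(line)
    if not body_lines:
        raise FormatError("log file has no data section")
    try:
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse log table: {exc}") from exc
    missing = set(_log_columns()) - set(df.columns)
    if missing:
        raise FormatError(f"log is missing columns: {sorted(missing)[:3]}...")
    if len(df) == 0:
        raise FormatError("log contains no records")
    la_cols = [f"leaf_a_{i + 1:02d}" for i in range(N_LEAF_PAIRS)]
    lb_cols = [f"leaf_b_{i + 1:02d}" for i in range(N_LEAF_PAIRS)]
    return DeliveryLog(
        time_s=df["time_s"].to_numpy(),
        gantry_deg=df["gantry_deg"].to_numpy(),
        collimator_deg=df["collimator_deg"].to_numpy(),
        leaves_a_mm=df[la_cols].to_numpy(),
        leaves_b_mm=df[lb_cols].to_numpy(),
        jaws_mm=df[["jaw_x1_mm", "jaw_x2_mm", "jaw_y1_mm",
                    "jaw_y2_mm"]].to_numpy(),
        mu=df["mu_cumulative"].to_numpy(),
        rate_hz=float(meta.get("rate_hz", 4.0)),
        leaf_tolerance_mm=float(meta.get("leaf_tolerance_mm", 1.0)),
        gantry_tolerance_deg=float(meta.get("gantry_tolerance_deg", 1.0)),
    )


# ---------------------------------------------------------------------------
# HDF5 fixture container (phantom + structures + plan + dose in one file)


def save_case(path, phantom: PhantomVolume | None = None,
              structures: StructureSet | None = None,
              plan: VmatPlan | None = None,
              dose: DoseGrid | None = None) -> None:
    """Store any subset of {phantom, structures, plan, dose} in one HDF5
    file.  DICOM-RT remains the interchange format; this container exists
    to keep multi-object fixtures fast and single-file."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "vmatqa-case v1"
        if phantom is not None:
            g = f.create_group("phantom")
            g.create_dataset("density", data=phantom.density)
            g.attrs["spacing_mm"] = phantom.spacing_mm
            g.attrs["origin_mm"] = phantom.origin_mm
        if structures is not None:
            g = f.create_group("structures")
            g.attrs["spacing_mm"] = structures.spacing_mm
            g.attrs["origin_mm"] = structures.origin_mm
            for name, mask in structures.masks.items():
                g.create_dataset(name, data=mask)
        if plan is not None:
            g = f.create_group("plan")
            g.attrs["isocenter_mm"] = plan.isocenter_mm
            g.attrs["sad_mm"] = plan.sad_mm
            g.attrs["energy"] = plan.energy
            g.attrs["name"] = plan.name
            g.create_dataset("leaf_boundaries_mm",
                             data=plan.leaf_boundaries_mm)
            for i, beam in enumerate(plan.beams):
                gb = g.create_group(f"beam_{i:03d}")
                gb.attrs["meterset_mu"] = beam.meterset_mu
                gb.attrs["name"] = beam.name
                gb.create_dataset("gantry_deg", data=beam.gantry_deg)
                gb.create_dataset("collimator_deg", data=beam.collimator_deg)
                gb.create_dataset("leaves_a_mm", data=beam.leaves_a_mm)
                gb.create_dataset("leaves_b_mm", data=beam.leaves_b_mm)
                gb.create_dataset("jaws_mm", data=beam.jaws_mm)
                gb.create_dataset("cumulative_mu", data=beam.cumulative_mu)
        if dose is not None:
            g = f.create_group("dose")
            g.create_dataset("dose_gy", data=dose.dose)
            g.attrs["spacing_mm"] = dose.spacing_mm
            g.attrs["origin_mm"] = dose.origin_mm
            g.attrs["uncertainty_label"] = dose.uncertainty_label


def load_case(path) -> dict:
    """Load a fixture container; returns a dict with the stored objects."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "phantom" in f:
            g = f["phantom"]
            out["phantom"] = PhantomVolume(
                density=g["density"][()], spacing_mm=g.attrs["spacing_mm"],
                origin_mm=g.attrs["origin_mm"])
        if "structures" in f:
            g = f["structures"]
            out["structures"] = StructureSet(
                masks={k: g[k][()] for k in g.keys()},
                spacing_mm=g.attrs["spacing_mm"],
                origin_mm=g.attrs["origin_mm"])
        if "plan" in f:
            g = f["plan"]
            beams = []
            for key in sorted(k for k in g.keys() if k.startswith("beam_")):
                gb = g[key]
                cps = [
                    ControlPoint(
                        gantry_deg=float(gb["gantry_deg"][i]),
                        collimator_deg=float(gb["collimator_deg"][i]),
                        leaves_a_mm=gb["leaves_a_mm"][i],
                        leaves_b_mm=gb["leaves_b_mm"][i],
                        jaws_mm=gb["jaws_mm"][i],
                        cumulative_mu=float(gb["cumulative_mu"][i]),
                    )
                    for i in range(gb["gantry_deg"].shape[0])
                ]
                beams.append(ArcBeam(control_points=cps,
                                     meterset_mu=float(gb.attrs["meterset_mu"]),
                                     name=str(gb.attrs["name"])))
            out["plan"] = VmatPlan(
                beams=beams, isocenter_mm=g.attrs["isocenter_mm"],
                sad_mm=float(g.attrs["sad_mm"]),
                leaf_boundaries_mm=g["leaf_boundaries_mm"][()],
                energy=str(g.attrs["energy"]), name=str(g.attrs["name"]))
        if "dose" in f:
            g = f["dose"]
            out["dose"] = DoseGrid(
                dose=g["dose_gy"][()], spacing_mm=g.attrs["spacing_mm"],
                origin_mm=g.attrs["origin_mm"],
                uncertainty_label=str(g.attrs["uncertainty_label"]))
    return out
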