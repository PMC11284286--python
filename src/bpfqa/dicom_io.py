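"""Plan and cine-image I/O: DICOM RT Plan / RT Image and a portable archive.

Two interchange routes are supported for cine frames:

* a DICOM RT Image series, one file per frame, with pixel intensities
  quantised to 16-bit integers under a stated rescale slope (lossless after
  that fixed quantisation);
* a portable archive -- a compressed ``.npz`` holding the raw float frames
  plus a JSON sidecar with pitch, frame indices, segment labels and gantry
  angles -- which is bit-exact and carries the frame-to-segment labels that
  plain RT Image files do not.

Only standard beam-limiting-device and image attributes are read; vendor
private tags are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .machine import MachineModel
from .plan import BPFConfig, BPFPlan, PlanKind, Segment

log = logging.getLogger(__name__)

RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"
RTIMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"
_UID_ROOT = "1.2.826.0.1.3680043.10.1487"


class DicomIOError(ValueError):
    """Raised when a file cannot be interpreted as a plan or cine series."""


# --------------------------------------------------------------------------
# in-memory cine containers


@dataclass
class CineFrame:
    """One EPID cine frame at isocenter scale."""

    pixels: np.ndarray
    pitch_mm: float
    frame_index: int = 0
    segment_label: int | None = None
    gantry_deg: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        if not np.isfinite(self.pixels).all():
            raise ValueError("frame intensities must be finite")


@dataclass
class CineSeries:
    """An ordered collection of cine frames sharing shape and pitch."""

    frames: list[CineFrame]
    machine: MachineModel | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a cine series needs at least one frame")
        shape = self.frames[0].pixels.shape
        pitch = self.frames[0].pitch_mm
        for f in self.frames:
            if f.pixels.shape != shape:
                raise ValueError(
                    f"frame {f.frame_index} shape {f.pixels.shape} != {shape}"
                )
            if abs(f.pitch_mm - pitch) > 1e-9:
                raise ValueError("frames disagree on pixel pitch")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pitch_mm(self) -> float:
        return self.frames[0].pitch_mm


# --------------------------------------------------------------------------
# RT Plan


def _uid(*entropy: str) -> str:
    return generate_uid(prefix=_UID_ROOT + ".", entropy_srcs=list(entropy))


def _ds_fmt(value: float) -> str:
    return f"{value:.4f}"


def _leaf_boundaries(machine: MachineModel) -> list[str]:
    return [_ds_fmt(v) for v in machine.leaf_edges()]


def write_rtplan(plan: BPFPlan, destination) -> None:
    """Write a BPF plan as a single-beam DICOM RT Plan.

    One control point per segment carries the MLC leaf positions (MLCX),
    asymmetric X and Y jaw positions, the gantry angle and the cumulative
    meterset weight at the start of the segment.
    """
    destination = Path(destination)
    machine = plan.machine
    cfg = plan.config
    plan_tag = f"{plan.plan_kind}-{cfg.gantry_mode}-{plan.n_segments}"

    ds = Dataset()
    ds.SOPClassUID = RTPLAN_STORAGE
    ds.SOPInstanceUID = _uid("sop", plan_tag)
    ds.StudyInstanceUID = _uid("study", plan_tag)
    ds.SeriesInstanceUID = _uid("series", plan_tag)
    ds.Modality = "RTPLAN"
    ds.Manufacturer = "bpfqa"
    ds.PatientName = "QA^BPF"
    ds.PatientID = "BPFQA"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.RTPlanLabel = f"BPF {plan.plan_kind}"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    # beam-limiting devices
    bld_x = Dataset()
    bld_x.RTBeamLimitingDeviceType = "ASYMX"
    bld_x.NumberOfLeafJawPairs = 1
    bld_y = Dataset()
    bld_y.RTBeamLimitingDeviceType = "ASYMY"
    bld_y.NumberOfLeafJawPairs = 1
    bld_mlc = Dataset()
    bld_mlc.RTBeamLimitingDeviceType = "MLCX"
    bld_mlc.NumberOfLeafJawPairs = machine.n_leaf_pairs
    bld_mlc.LeafPositionBoundaries = _leaf_boundaries(machine)

    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = "BPF"
    beam.BeamType = "DYNAMIC"
    beam.RadiationType = "PHOTON"
    beam.TreatmentMachineName = "TrueBeam"
    beam.SourceAxisDistance = _ds_fmt(machine.sid * 10.0)
    beam.TreatmentDeliveryType = "TREATMENT"
    beam.NumberOfWedges = 0
    beam.NumberOfCompensators = 0
    beam.NumberOfBoli = 0
    beam.NumberOfBlocks = 0
    beam.BeamLimitingDeviceSequence = [bld_x, bld_y, bld_mlc]
    beam.FinalCumulativeMetersetWeight = _ds_fmt(1.0)
    beam.NumberOfControlPoints = plan.n_segments

    energy = "".join(ch for ch in cfg.energy_label if ch.isdigit() or ch == ".")
    y_half = machine.y_jaw_half_field
    cps = []
    cumulative = 0.0
    for seg in plan.segments:
        cp = Dataset()
        cp.ControlPointIndex = seg.index - 1
        cp.CumulativeMetersetWeight = _ds_fmt(cumulative)
        cp.GantryAngle = _ds_fmt(seg.gantry_deg % 360.0)
        cp.GantryRotationDirection = "NONE"
        if seg.index == 1:
            cp.NominalBeamEnergy = energy or "6"
            cp.DoseRateSet = _ds_fmt(cfg.dose_rate)
            cp.BeamLimitingDeviceAngle = _ds_fmt(0.0)
            cp.PatientSupportAngle = _ds_fmt(0.0)
            cp.IsocenterPosition = [_ds_fmt(0.0)] * 3
        pos_x = Dataset()
        pos_x.RTBeamLimitingDeviceType = "ASYMX"
        pos_x.LeafJawPositions = [_ds_fmt(seg.x1), _ds_fmt(seg.x2)]
        pos_y = Dataset()
        pos_y.RTBeamLimitingDeviceType = "ASYMY"
        pos_y.LeafJawPositions = [_ds_fmt(-y_half), _ds_fmt(y_half)]
        pos_mlc = Dataset()
        pos_mlc.RTBeamLimitingDeviceType = "MLCX"
        pos_mlc.LeafJawPositions = [_ds_fmt(v) for v in seg.bank_a] + [
            _ds_fmt(v) for v in seg.bank_b
        ]
        cp.BeamLimitingDevicePositionSequence = [pos_x, pos_y, pos_mlc]
        cps.append(cp)
        cumulative += seg.mu_fraction
    beam.ControlPointSequence = cps
    ds.BeamSequence = [beam]

    ref_beam = Dataset()
    ref_beam.ReferencedBeamNumber = 1
    ref_beam.BeamMeterset = _ds_fmt(cfg.total_mu)
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = 1
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = [ref_beam]
    ds.FractionGroupSequence = [fg]

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_STORAGE
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    try:
        ds.save_as(destination, enforce_file_format=True)
    except OSError as exc:
        raise DicomIOError(f"cannot write RT Plan to {destination}: {exc}") from exc


def _positions(cp: Dataset, device_type: str) -> list[float] | None:
    for item in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        if item.RTBeamLimitingDeviceType == device_type:
            return [float(v) for v in item.LeafJawPositions]
    return None


def read_rtplan(source, machine: MachineModel | None = None) -> BPFPlan:
    """Reconstruct a :class:`BPFPlan` from a DICOM RT Plan.

    Only geometric content is recovered exactly; pattern metadata in the
    returned :class:`~bpfqa.plan.BPFConfig` (retraction, MU, dose rate,
    gantry mode) is inferred where the file allows and defaulted otherwise.
    ``plan_kind`` is inferred as ``static_jaw`` when the X jaws are
    constant across control points, else ``jaw_tracking``.
    """
    try:
        ds = pydicom.dcmread(source)
    except Exception as exc:  # pydicom raises several flavours here
        raise DicomIOError(f"cannot read RT Plan from {source}: {exc}") from exc
    beams = getattr(ds, "BeamSequence", None)
    if not beams:
        raise DicomIOError("RT Plan contains no BeamSequence")
    beam = beams[0]
    machine = machine or MachineModel()
    n_pairs = machine.n_leaf_pairs

    total_mu = None
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if getattr(rb, "BeamMeterset", None) is not None:
                total_mu = float(rb.BeamMeterset)

    cps = list(beam.ControlPointSequence)
    if not cps:
        raise DicomIOError("beam has no control points")
    final_weight = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0) or 1.0)
    cum = [float(cp.CumulativeMetersetWeight) for cp in cps]
    fractions = np.diff(np.asarray(cum + [final_weight]))
    total = fractions.sum()
    if total <= 0:
        fractions = np.full(len(cps), 1.0 / len(cps))
    else:
        fractions = fractions / total
    # zero-weight control points still describe geometry; give them an
    # equal share so Segment validation holds
    if np.any(fractions <= 0):
        fractions = np.full(len(cps), 1.0 / len(cps))

    gantry = 0.0
    dose_rate = 600.0
    energy = "6 MV"
    segments: list[Segment] = []
    upper_mask = np.array([machine.is_upper_leaf(i + 1) for i in range(n_pairs)])
    for i, cp in enumerate(cps):
        if getattr(cp, "GantryAngle", None) is not None:
            gantry = float(cp.GantryAngle)
        if getattr(cp, "DoseRateSet", None) is not None:
            dose_rate = float(cp.DoseRateSet)
        if getattr(cp, "NominalBeamEnergy", None) is not None:
            energy = f"{cp.NominalBeamEnergy} MV"
        jaws = _positions(cp, "ASYMX")
        mlc = _positions(cp, "MLCX")
        if jaws is None or mlc is None:
            raise DicomIOError(f"control point {i} lacks ASYMX or MLCX positions")
        if len(mlc) != 2 * n_pairs:
            raise DicomIOError(
                f"control point {i}: expected {2 * n_pairs} MLC values, got {len(mlc)}"
            )
        bank_a = np.asarray(mlc[:n_pairs])
        bank_b = np.asarray(mlc[n_pairs:])
        centers = (bank_a + bank_b) / 2.0
        segments.append(
            Segment(
                index=i + 1,
                upper_center=float(centers[upper_mask].mean()),
                lower_center=float(centers[~upper_mask].mean()),
                x1=jaws[0],
                x2=jaws[1],
                bank_a=bank_a,
                bank_b=bank_b,
                mu_fraction=float(fractions[i]),
                gantry_deg=gantry,
            )
        )

    angles = [seg.gantry_deg for seg in segments]
    if all(abs(a - angles[0]) < 1e-6 for a in angles):
        mode = {0.0: "static_0", 90.0: "static_90", 270.0: "static_270"}.get(
            round(angles[0], 3), "static_0"
        )
    else:
        mode = "rotation"
    widths = np.concatenate([seg.bank_b - seg.bank_a for seg in segments])
    config = BPFConfig(
        aperture_width=float(np.median(widths)),
        upper_centers=tuple(seg.upper_center for seg in segments),
        lower_centers=tuple(seg.lower_center for seg in segments),
        retraction=BPFConfig().retraction,
        total_mu=total_mu if total_mu else BPFConfig().total_mu,
        dose_rate=dose_rate,
        energy_label=energy,
        gantry_mode=mode,
    )
    x1s = [seg.x1 for seg in segments]
    x2s = [seg.x2 for seg in segments]
    static = all(abs(v - x1s[0]) < 1e-6 for v in x1s) and all(
        abs(v - x2s[0]) < 1e-6 for v in x2s
    )
    kind: PlanKind = "static_jaw" if static and len(segments) > 1 else "jaw_tracking"
    return BPFPlan(machine=machine, config=config, segments=segments, plan_kind=kind)


# --------------------------------------------------------------------------
# cine frames


def _portable_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    return path, path.with_suffix(".json")


def _write_cine_portable(series: CineSeries, path: Path) -> None:
    npz_path, json_path = _portable_paths(path)
    stack = np.stack([f.pixels.astype(np.float32, copy=False) for f in series.frames])
    np.savez_compressed(npz_path, pixels=stack)
    meta = {
        "pitch_mm": series.pitch_mm,
        "frame_index": [f.frame_index for f in series.frames],
        "segment_label": [f.segment_label for f in series.frames],
        "gantry_deg": [f.gantry_deg for f in series.frames],
        "machine": series.machine.model_dump() if series.machine else None,
    }
    json_path.write_text(json.dumps(meta, indent=1))


def _read_cine_portable(path: Path) -> CineSeries:
    npz_path, json_path = _portable_paths(path)
    if not npz_path.exists() or not json_path.exists():
        raise DicomIOError(f"portable series {npz_path} / sidecar {json_path} missing")
    meta = json.loads(json_path.read_text())
    with np.load(npz_path) as data:
        stack = data["pixels"]
    frames = [
        CineFrame(
            pixels=stack[i],
            pitch_mm=float(meta["pitch_mm"]),
            frame_index=int(meta["frame_index"][i]),
            segment_label=(
                None
                if meta["segment_label"][i] is None
                else int(meta["segment_label"][i])
            ),
            gantry_deg=(
                None if meta["gantry_deg"][i] is None else float(meta["gantry_deg"][i])
            ),
        )
        for i in range(stack.shape[0])
    ]
    machine = MachineModel(**meta["machine"]) if meta.get("machine") else None
    return CineSeries(frames=frames, machine=machine)


def _write_cine_dicom(series: CineSeries, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    vmax = max(float(f.pixels.max()) for f in series.frames)
    slope = float(f"{vmax / 65535.0:.10e}") if vmax > 0 else 1.0
    series_uid = _uid("cine-series", f"{len(series.frames)}", f"{vmax:.6e}")
    study_uid = _uid("cine-study", f"{len(series.frames)}")
    for i, frame in enumerate(series.frames):
        ints = np.clip(
            np.floor(frame.pixels.astype(np.float64) / slope + 0.5), 0, 65535
        ).astype(np.uint16)
        ds = Dataset()
        ds.SOPClassUID = RTIMAGE_STORAGE
        ds.SOPInstanceUID = _uid("cine-frame", series_uid, str(i))
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "RTIMAGE"
        ds.Manufacturer = "bpfqa"
        ds.PatientName = "QA^BPF"
        ds.PatientID = "BPFQA"
        ds.PatientBirthDate = ""
        ds.PatientSex = "O"
        ds.StudyID = "1"
        ds.SeriesNumber = 1
        ds.InstanceNumber = i + 1
        ds.ImageType = ["ORIGINAL", "PRIMARY", "PORTAL"]
        ds.RTImageLabel = f"cine {frame.frame_index}"
        ds.RTImagePlane = "NORMAL"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = ints.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.ImagePlanePixelSpacing = [_ds_fmt(frame.pitch_mm), _ds_fmt(frame.pitch_mm)]
        ds.RTImageSID = _ds_fmt(1000.0)
        ds.RadiationMachineSAD = _ds_fmt(1000.0)
        ds.RescaleSlope = f"{slope:.10e}"
        ds.RescaleIntercept = "0"
        ds.RescaleType = "US"
        if frame.gantry_deg is not None:
            ds.GantryAngle = _ds_fmt(frame.gantry_deg % 360.0)
        ds.PixelData = ints.tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = RTIMAGE_STORAGE
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.save_as(directory / f"cine_{i:04d}.dcm", enforce_file_format=True)


def _read_cine_dicom(directory: Path) -> CineSeries:
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise DicomIOError(f"no DICOM files in {directory}")
    frames = []
    for path in files:
        ds = pydicom.dcmread(path)
        spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(
            ds, "PixelSpacing", None
        )
        if spacing is None:
            raise DicomIOError(f"{path.name}: no pixel spacing")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pixels = (ds.pixel_array.astype(np.float64) * slope + intercept).astype(
            np.float32
        )
        gantry = getattr(ds, "GantryAngle", None)
        frames.append(
            CineFrame(
                pixels=pixels,
                pitch_mm=float(spacing[0]),
                frame_index=int(getattr(ds, "InstanceNumber", len(frames) + 1)) - 1,
                segment_label=None,
                gantry_deg=None if gantry is None else float(gantry),
            )
        )
    frames.sort(key=lambda f: f.frame_index)
    return CineSeries(frames=frames)


def write_cine(series: CineSeries, destination, fmt: str | None = None) -> None:
    """Write a cine series either as a DICOM directory or a portable archive.

    ``fmt`` is ``"dicom"`` or ``"portable"``; when omitted it is inferred
    from the destination (a ``.npz`` suffix selects the portable format).
    """
    destination = Path(destination)
    if fmt is None:
        fmt = "portable" if destination.suffix == ".npz" else "dicom"
    if fmt == "portable":
        _write_cine_portable(series, destination)
    elif fmt == "dicom":
        _write_cine_dicom(series, destination)
    else:
        raise ValueError(f"unknown cine format {fmt!r}")


def read_cine(source) -> CineSeries:
    """Read a cine series written by :func:`write_cine` (either format)."""
    source = Path(source)
    if source.is_dir():
        return _read_cine_dicom(source)
    return _read_cine_portable(source)
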