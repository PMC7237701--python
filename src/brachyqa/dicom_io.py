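"""DICOM readers/writers: RT Plan (read), RT Structure Set (read), RT Dose
(read + write).

Only standard attributes are touched.  RT Plan dwell times follow the DICOM
brachy control-point convention: each dwell appears as a pair of control
points at the same 3D position whose cumulative time-weight difference,
scaled by ChannelTotalTime / FinalCumulativeTimeWeight, is the dwell time in
seconds.  RT Dose pixel data are stored as uint32 scaled by DoseGridScaling;
round-tripped values are exact multiples of the scaling (quantization error
at most scaling/2).
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dose_engine import DoseVolume, GridSpec
from .errors import ParseError
from .structures_dvh import ROI, StructureSet

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"

_ROLE_BY_NAME = {
    "hr-ctv": "hrctv", "hrctv": "hrctv", "ctv": "hrctv",
    "bladder": "bladder", "rectum": "rectum", "sigmoid": "sigmoid",
    "applicator": "applicator",
}


def read_dicom_plan(path):
    """Parse a DICOM RT Plan into a :class:`~brachyqa.io_formats.PlanDocument`."""
    from .io_formats import PlanChannel, PlanDocument

    ds = pydicom.dcmread(path)
    try:
        src = ds.SourceSequence[0]
        sk = float(src.ReferenceAirKermaRate)  # uGy m^2 / h == 1 U numerically
    except (AttributeError, IndexError) as exc:
        raise ParseError(f"RT Plan {path}: missing SourceSequence/ReferenceAirKermaRate") from exc
    channels = []
    try:
        setups = ds.ApplicationSetupSequence
    except AttributeError as exc:
        raise ParseError(f"RT Plan {path}: missing ApplicationSetupSequence") from exc
    for setup in setups:
        for ch in getattr(setup, "ChannelSequence", []):
            total_time = float(ch.ChannelTotalTime)
            final_w = float(ch.FinalCumulativeTimeWeight)
            if final_w <= 0:
                raise ParseError(f"RT Plan {path}: channel {ch.ChannelNumber} has zero "
                                 "FinalCumulativeTimeWeight")
            cps = ch.BrachyControlPointSequence
            positions, times = [], []
            i = 0
            while i + 1 < len(cps):
                p0 = np.asarray([float(v) for v in cps[i].ControlPoint3DPosition])
                p1 = np.asarray([float(v) for v in cps[i + 1].ControlPoint3DPosition])
                if not np.allclose(p0, p1):
                    raise ParseError(
                        f"RT Plan {path}: control points {i}/{i + 1} of channel "
                        f"{ch.ChannelNumber} are not a dwell pair"
                    )
                w0 = float(cps[i].CumulativeTimeWeight)
                w1 = float(cps[i + 1].CumulativeTimeWeight)
                positions.append(p0)
                times.append((w1 - w0) / final_w * total_time)
                i += 2
            channels.append(PlanChannel(
                channel_id=str(ch.ChannelNumber), applicator_type="generic",
                positions_mm=np.asarray(positions), times_s=np.asarray(times),
            ))
    if not channels:
        raise ParseError(f"RT Plan {path}: no channels with control points")
    return PlanDocument(channels=channels, air_kerma_strength_U=sk,
                        source_model="ir192-generic",
                        metadata={"dicom_sop_instance": str(getattr(ds, "SOPInstanceUID", ""))})


def read_dicom_structures(path) -> StructureSet:
    """Parse a DICOM RT Structure Set (CLOSED_PLANAR contours)."""
    ds = pydicom.dcmread(path)
    names = {}
    for item in getattr(ds, "StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)
    ss = StructureSet()
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI-{number}")
        slices: dict[float, list[np.ndarray]] = {}
        for contour in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            z = float(np.round(data[:, 2].mean(), 6))
            slices.setdefault(z, []).append(data[:, :2])
        if not slices:
            continue
        role = _ROLE_BY_NAME.get(name.lower().replace(" ", ""), "other")
        ss.add(ROI(name=name, role=role, slices=slices))
    if not ss.rois:
        raise ParseError(f"RT Structure Set {path}: no contours found")
    return ss


def write_dicom_dose(dose: DoseVolume, path) -> None:
    """Write a DoseVolume as a DICOM RT Dose file (GY, uint32 pixel data)."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "FRACTION"

    nx, ny, nz = dose.grid.dims
    dx, dy, dz = dose.grid.spacing_mm
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
    ds.GridFrameOffsetVector = [i * dz for i in range(nz)]
    ds.ImagePositionPatient = list(dose.grid.origin_mm)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.FrameOfReferenceUID = generate_uid()
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0

    values_gy = dose.values / 100.0  # cGy -> Gy for the DICOM file
    vmax = float(values_gy.max())
    scaling = vmax / (2 ** 32 - 1) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.round(values_gy / scaling).astype(np.uint32)
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom_dose(path) -> DoseVolume:
    """Read a DICOM RT Dose file into a DoseVolume (values in cGy)."""
    ds = pydicom.dcmread(path)
    try:
        scaling = float(ds.DoseGridScaling)
        frames = ds.pixel_array  # (nz, ny, nx)
        origin = tuple(float(v) for v in ds.ImagePositionPatient)
        dy, dx = (float(v) for v in ds.PixelSpacing)
        offsets = [float(v) for v in ds.GridFrameOffsetVector]
    except AttributeError as exc:
        raise ParseError(f"RT Dose {path}: missing required attribute ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[None]
    dz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    grid = GridSpec(origin_mm=(origin[0], origin[1], origin[2] + offsets[0]),
                    spacing_mm=(dx, dy, dz),
                    dims=(frames.shape[2], frames.shape[1], frames.shape[0]))
    values_cgy = frames.astype(float) * scaling * 100.0
    units = str(getattr(ds, "DoseUnits", "GY"))
    if units.upper() != "GY":
        raise ParseError(f"RT Dose {path}: unsupported DoseUnits {units!r}")
    return DoseVolume(grid=grid, values=values_cgy,
                      metadata={"dicom_dose_grid_scaling": scaling})
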