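"""Load classic and enhanced DICOM and normalize both to per-frame records.

Classic files hold one frame each and are grouped by series UID; enhanced
multi-frame files are exploded so that every frame becomes one record with
shared functional-group values overridden by per-frame values. Downstream
code (part splitting, volume assembly, converter detection) never needs to
know which encoding the data came in.

Geometry: DICOM stores patient coordinates in LPS. The affine returned by
:func:`compute_affine` maps voxel index ``(i, j, k)`` — (column, row, slice)
— to RAS millimetres, i.e. the DICOM mapping with the first two coordinate
rows negated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset
from pydicom.errors import InvalidDicomError

from .core import AffineTransform
from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    GeometryError,
    InvalidRescaleError,
    NonUniformSpacingError,
)

#: per-cosine tolerance when checking orientation consistency across frames
ORIENTATION_TOL = 1e-3
#: max/min slice-gap ratio beyond which spacing is declared non-uniform
SPACING_RATIO_TOL = 1.01

#: top-level attributes copied onto each FrameRecord when present
_TAG_KEYWORDS = (
    "Modality",
    "Manufacturer",
    "ScanningSequence",
    "SequenceVariant",
    "SequenceName",
    "PulseSequenceName",
    "EchoPulseSequence",
    "SeriesDescription",
    "ImageType",
    "EchoTime",
    "RepetitionTime",
    "FlipAngle",
    "PixelBandwidth",
    "MagneticFieldStrength",
    "KVP",
    "Exposure",
    "XRayTubeCurrent",
    "ExposureTime",
    "ConvolutionKernel",
    "DetectorType",
    "RescaleSlope",
    "RescaleIntercept",
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "ImagerPixelSpacing",
    "SliceThickness",
    "SpacingBetweenSlices",
    "InstanceNumber",
    "SeriesInstanceUID",
    "SeriesNumber",
    "AcquisitionTime",
    "Rows",
    "Columns",
)

#: Scanco-style density-calibration fields, stored in a private block whose
#: creator string contains "SCANCO"; element offsets within the block.
SCANCO_PRIVATE_GROUP = 0x0029
SCANCO_FIELDS = {
    0x01: "ScancoMuScaling",
    0x02: "ScancoDensitySlope",
    0x03: "ScancoDensityIntercept",
    0x04: "ScancoMuWater",
}

#: Philips-style private tag for the native water-fat shift (pixels).
WFS_PRIVATE_GROUP = 0x2001
WFS_PRIVATE_OFFSET = 0x22


@dataclass
class FrameRecord:
    """One 2D frame: conversion-relevant tags plus stored pixel values."""

    tags: dict
    pixels: np.ndarray
    #: full source header (classic files); None for exploded enhanced frames
    dataset: Optional[Dataset] = None

    def __post_init__(self):
        iop = self.tags.get("ImageOrientationPatient")
        if iop is not None:
            iop = np.asarray(iop, dtype=float)
            if iop.shape != (6,):
                raise GeometryError("ImageOrientationPatient must have 6 cosines")
            for triplet in (iop[:3], iop[3:]):
                if abs(np.linalg.norm(triplet) - 1.0) > 1e-3:
                    raise GeometryError("orientation cosines not unit norm")
        ps = self.tags.get("PixelSpacing")
        if ps is not None and min(float(v) for v in ps) <= 0:
            raise GeometryError("pixel spacing must be strictly positive")


@dataclass
class SeriesGroup:
    """All frames of one acquisition, classic or enhanced."""

    uid: str
    frames: list[FrameRecord]
    source_kind: str  # "classic" | "enhanced"
    #: the single multi-frame source header, for enhanced input
    dataset: Optional[Dataset] = None

    def __post_init__(self):
        if not self.frames:
            raise EmptyInputError(f"series {self.uid} has no frames")
        mods = {f.tags.get("Modality") for f in self.frames}
        mans = {str(f.tags.get("Manufacturer", "")) for f in self.frames}
        if len(mods) > 1 or len(mans) > 1:
            raise GeometryError(
                f"series {self.uid}: mixed modality/manufacturer {mods}/{mans}"
            )

    @property
    def tags(self) -> dict:
        """Series-level tags (from the first frame; shared by invariant)."""
        return self.frames[0].tags

    def distinct_echo_times(self, tol_ms: float = 1e-3) -> list[float]:
        """Sorted distinct echo times, merged within ``tol_ms``."""
        times = sorted(
            float(f.tags["EchoTime"])
            for f in self.frames
            if f.tags.get("EchoTime") is not None
        )
        out: list[float] = []
        for t in times:
            if not out or t - out[-1] > tol_ms:
                out.append(t)
        return out


def _extract_tags(ds: Dataset) -> dict:
    tags = {}
    for kw in _TAG_KEYWORDS:
        value = getattr(ds, kw, None)
        if value is not None:
            tags[kw] = value
    # vendor private fields read by name
    try:
        block = ds.private_block(SCANCO_PRIVATE_GROUP, "SCANCO")
        for offset, name in SCANCO_FIELDS.items():
            if offset in block:
                tags[name] = float(block[offset].value)
    except KeyError:
        pass
    try:
        block = ds.private_block(WFS_PRIVATE_GROUP, "PHILIPS-WFS")
        if WFS_PRIVATE_OFFSET in block:
            tags["WaterFatShift"] = float(block[WFS_PRIVATE_OFFSET].value)
    except KeyError:
        pass
    return tags


def _seq_item(parent, name):
    seq = getattr(parent, name, None)
    if seq:
        return seq[0]
    return None


def explode_enhanced(ds: Dataset) -> SeriesGroup:
    """Flatten an enhanced multi-frame dataset into per-frame records.

    Per-frame functional-group values (echo time, position, frame type,
    rescale) override shared values; pixel planes are sliced from the single
    pixel buffer in declared frame order.
    """
    n_frames = int(ds.NumberOfFrames)
    shared = _seq_item(ds, "SharedFunctionalGroupsSequence")
    per_frame = list(getattr(ds, "PerFrameFunctionalGroupsSequence", []))
    if len(per_frame) not in (0, n_frames):
        raise GeometryError(
            f"{len(per_frame)} per-frame groups for {n_frames} declared frames"
        )
    pixel_array = ds.pixel_array
    if n_frames == 1 and pixel_array.ndim == 2:
        pixel_array = pixel_array[None]

    base = _extract_tags(ds)
    base.pop("ImagePositionPatient", None)

    def group_tags(fg) -> dict:
        out: dict = {}
        if fg is None:
            return out
        item = _seq_item(fg, "PixelMeasuresSequence")
        if item is not None:
            for kw in ("PixelSpacing", "SliceThickness", "SpacingBetweenSlices"):
                if getattr(item, kw, None) is not None:
                    out[kw] = getattr(item, kw)
        item = _seq_item(fg, "PlanePositionSequence")
        if item is not None and getattr(item, "ImagePositionPatient", None) is not None:
            out["ImagePositionPatient"] = item.ImagePositionPatient
        item = _seq_item(fg, "PlaneOrientationSequence")
        if item is not None and getattr(item, "ImageOrientationPatient", None) is not None:
            out["ImageOrientationPatient"] = item.ImageOrientationPatient
        item = _seq_item(fg, "MREchoSequence")
        if item is not None and getattr(item, "EffectiveEchoTime", None) is not None:
            out["EchoTime"] = float(item.EffectiveEchoTime)
        item = _seq_item(fg, "MRTimingAndRelatedParametersSequence")
        if item is not None:
            for kw in ("RepetitionTime", "FlipAngle"):
                if getattr(item, kw, None) is not None:
                    out[kw] = getattr(item, kw)
        item = _seq_item(fg, "MRImageFrameTypeSequence")
        if item is not None and getattr(item, "FrameType", None) is not None:
            out["ImageType"] = list(item.FrameType)
        item = _seq_item(fg, "PixelValueTransformationSequence")
        if item is not None:
            for kw in ("RescaleSlope", "RescaleIntercept"):
                if getattr(item, kw, None) is not None:
                    out[kw] = getattr(item, kw)
        return out

    shared_tags = group_tags(shared)
    multi_slice = n_frames > 1
    frames = []
    for i in range(n_frames):
        tags = dict(base)
        tags.update(shared_tags)
        if per_frame:
            tags.update(group_tags(per_frame[i]))
        if multi_slice and "ImagePositionPatient" not in tags:
            raise GeometryError(f"frame {i}: missing per-frame image position")
        tags.setdefault("InstanceNumber", i + 1)
        frames.append(FrameRecord(tags=tags, pixels=np.asarray(pixel_array[i])))
    return SeriesGroup(
        uid=str(ds.SeriesInstanceUID), frames=frames, source_kind="enhanced", dataset=ds
    )


def _is_enhanced(ds: Dataset) -> bool:
    return int(getattr(ds, "NumberOfFrames", 1) or 1) > 1 or hasattr(
        ds, "PerFrameFunctionalGroupsSequence"
    )


def read_dicom_tree(root) -> list[SeriesGroup]:
    """Read every DICOM file under ``root`` into series groups.

    Non-DICOM files are skipped silently; unreadable DICOM files are skipped
    with a warning. Ordering is deterministic: groups sorted by series UID,
    classic frames by instance number.
    """
    root = Path(root)
    if not root.exists():
        raise EmptyInputError(f"input directory {root} does not exist")
    classic: dict[str, list[FrameRecord]] = {}
    enhanced: list[SeriesGroup] = []
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError):
            continue
        except Exception as exc:  # unreadable dataset behind a valid preamble
            warnings.warn(f"skipping unreadable DICOM file {path}: {exc}")
            continue
        try:
            if _is_enhanced(ds):
                enhanced.append(explode_enhanced(ds))
            else:
                rec = FrameRecord(
                    tags=_extract_tags(ds), pixels=ds.pixel_array, dataset=ds
                )
                uid = str(getattr(ds, "SeriesInstanceUID", "unknown"))
                classic.setdefault(uid, []).append(rec)
        except GeometryError:
            raise
        except Exception as exc:
            warnings.warn(f"skipping unreadable DICOM file {path}: {exc}")
            continue
    groups = [
        SeriesGroup(
            uid=uid,
            frames=sorted(recs, key=lambda r: int(r.tags.get("InstanceNumber", 0))),
            source_kind="classic",
        )
        for uid, recs in classic.items()
    ]
    groups.extend(enhanced)
    groups.sort(key=lambda g: g.uid)
    if not groups:
        raise EmptyInputError(f"no readable DICOM files under {root}")
    return groups


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def slice_normal(iop) -> np.ndarray:
    """Unit normal to the image plane (row cosines x column cosines)."""
    iop = np.asarray(iop, dtype=float)
    return np.cross(iop[:3], iop[3:])


def sort_slices(frames: list[FrameRecord]) -> list[FrameRecord]:
    """Sort frames along the slice normal; ties broken by instance number."""
    iop = frames[0].tags["ImageOrientationPatient"]
    n = slice_normal(iop)

    def key(f: FrameRecord):
        pos = np.asarray(f.tags["ImagePositionPatient"], dtype=float)
        return (round(float(pos @ n), 6), int(f.tags.get("InstanceNumber", 0)))

    return sorted(frames, key=key)


def compute_affine(frames: list[FrameRecord]) -> AffineTransform:
    """RAS voxel-to-patient affine for one slice stack (frames sorted).

    Built from the DICOM LPS mapping — origin at the first slice's image
    position, in-plane axes from the orientation cosines scaled by pixel
    spacing, through-plane axis from the inter-slice displacement (or
    normal x slice thickness for a single slice) — then the first two
    coordinate rows are negated (LPS to RAS). Voxel index convention:
    ``i`` = column, ``j`` = row, ``k`` = slice.
    """
    first = frames[0].tags
    iop0 = np.asarray(first["ImageOrientationPatient"], dtype=float)
    for f in frames[1:]:
        iop = np.asarray(f.tags["ImageOrientationPatient"], dtype=float)
        if np.max(np.abs(iop - iop0)) > ORIENTATION_TOL:
            raise GeometryError("inconsistent orientation across frames")
    row_cos, col_cos = iop0[:3], iop0[3:]
    # PixelSpacing = (row spacing, column spacing): rows advance along the
    # column cosines, columns along the row cosines
    ps = [float(v) for v in first["PixelSpacing"]]
    positions = [np.asarray(f.tags["ImagePositionPatient"], dtype=float) for f in frames]

    if len(frames) > 1:
        n = slice_normal(iop0)
        proj = np.array([p @ n for p in positions])
        gaps = np.diff(proj)
        # either direction of traversal is fine, but it must be strict
        if not (np.all(gaps > 0) or np.all(gaps < 0)):
            raise GeometryError("frames not strictly ordered along slice normal")
        agaps = np.abs(gaps)
        if agaps.max() / agaps.min() > SPACING_RATIO_TOL:
            raise NonUniformSpacingError(
                f"slice gap ratio {agaps.max() / agaps.min():.4f} exceeds "
                f"{SPACING_RATIO_TOL}"
            )
        k_axis = (positions[-1] - positions[0]) / (len(frames) - 1)
    else:
        thickness = first.get("SpacingBetweenSlices") or first.get("SliceThickness")
        if thickness is None:
            raise DegenerateGeometryError("single slice with no thickness")
        k_axis = slice_normal(iop0) * float(thickness)

    lps = np.eye(4)
    lps[:3, 0] = row_cos * ps[1]  # i: along a row (column index)
    lps[:3, 1] = col_cos * ps[0]  # j: along a column (row index)
    lps[:3, 2] = k_axis
    lps[:3, 3] = positions[0]
    ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps
    return AffineTransform(ras)


def apply_rescale(stored: np.ndarray, slope: float = 1.0, intercept: float = 0.0) -> np.ndarray:
    """Elementwise ``slope * stored + intercept`` as floating point."""
    slope = float(slope)
    if slope == 0:
        raise InvalidRescaleError("rescale slope must be nonzero")
    return np.asarray(stored, dtype=np.float64) * slope + float(intercept)


__all__ = [
    "FrameRecord",
    "SeriesGroup",
    "read_dicom_tree",
    "explode_enhanced",
    "compute_affine",
    "apply_rescale",
    "sort_slices",
    "slice_normal",
    "ORIENTATION_TOL",
    "SPACING_RATIO_TOL",
    "SCANCO_PRIVATE_GROUP",
    "SCANCO_FIELDS",
    "WFS_PRIVATE_GROUP",
    "WFS_PRIVATE_OFFSET",
]
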