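"""Reconstruct DICOM from a stored volume plus its extra sidecar.

The extra sidecar keeps every non-pixel tag of the source series, so a
converted dataset can be turned back into DICOM — e.g. for uploading
processed data to a PACS. All tags are restored verbatim; pixel data are
re-derived from the voxels by inverting the rescale transform (rounded to
the nearest stored integer, exact for unmodified integer data). Fresh SOP
instance UIDs are generated so re-imported files never collide with the
originals, while study/series UIDs are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .anonymize import deserialize_extra
from .core import ImageVolume
from .dicom_reader import slice_normal
from .errors import RoundTripError, ShapeMismatchError


def _stored_plane(volume: ImageVolume, k: int, e: int, slope: float, intercept: float) -> np.ndarray:
    if volume.voxels.ndim == 4:
        plane = volume.voxels[:, :, k, e]
    elif volume.voxels.ndim == 3:
        plane = volume.voxels[:, :, k]
    else:
        plane = volume.voxels
    stored = np.rint((np.asarray(plane, dtype=np.float64) - intercept) / slope)
    return stored.astype(np.int16).T  # back to (row, col)


def _frame_indices(datasets, echo_of, slice_of):
    """(echo index, slice index) per dataset, from echo time and position."""
    return [(echo_of(ds), slice_of(ds)) for ds in datasets]


def _position_rank(positions: list[np.ndarray], iop) -> dict[tuple, int]:
    n = slice_normal(iop)
    uniq = sorted({round(float(p @ n), 6) for p in positions})
    return {u: i for i, u in enumerate(uniq)}


def _echo_rank(times: list[float | None]) -> dict[float | None, int]:
    uniq = sorted({t for t in times if t is not None})
    ranks: dict[float | None, int] = {t: i for i, t in enumerate(uniq)}
    ranks[None] = 0
    return ranks


def reconstruct_dicom(volume: ImageVolume, extra: dict, out_dir) -> list[Path]:
    """Write DICOM files reconstructing the source series of ``volume``.

    Classic sources produce one file per original frame; enhanced sources a
    single multi-frame file. The file count always equals the original.
    """
    if extra is None:
        raise RoundTripError("missing extra sidecar: cannot reconstruct DICOM")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    source_kind, datasets = deserialize_extra(extra)

    n_slices = volume.voxels.shape[2] if volume.voxels.ndim >= 3 else 1
    n_echoes = volume.n_echoes

    if source_kind == "classic":
        if len(datasets) != n_slices * n_echoes:
            raise ShapeMismatchError(
                f"{len(datasets)} stored frames vs volume {n_slices} slices x "
                f"{n_echoes} echoes"
            )
        written = []
        if n_slices > 1 or getattr(datasets[0], "ImageOrientationPatient", None):
            iop = datasets[0].ImageOrientationPatient
            n = slice_normal(iop)
            ranks = _position_rank(
                [np.asarray(ds.ImagePositionPatient, float) for ds in datasets], iop
            )
            slice_of = lambda ds: ranks[
                round(float(np.asarray(ds.ImagePositionPatient, float) @ n), 6)
            ]
        else:
            slice_of = lambda ds: 0
        eranks = _echo_rank([getattr(ds, "EchoTime", None) for ds in datasets])
        for i, ds in enumerate(datasets):
            e = eranks[getattr(ds, "EchoTime", None)]
            k = slice_of(ds)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            pixels = _stored_plane(volume, k, e, slope, intercept)
            if (int(ds.Rows), int(ds.Columns)) != pixels.shape:
                raise ShapeMismatchError(
                    f"frame {i}: stored {ds.Rows}x{ds.Columns} vs voxels {pixels.shape}"
                )
            ds.PixelData = np.ascontiguousarray(pixels).tobytes()
            ds.SOPInstanceUID = generate_uid()
            _save(ds, out_dir / f"reconstructed-{i:04d}.dcm")
            written.append(out_dir / f"reconstructed-{i:04d}.dcm")
        return written

    # enhanced: one multi-frame file
    (ds,) = datasets
    n_frames = int(ds.NumberOfFrames)
    if n_frames != n_slices * n_echoes:
        raise ShapeMismatchError(
            f"{n_frames} stored frames vs volume {n_slices} slices x {n_echoes} echoes "
            "(multi-part enhanced sources cannot be rebuilt from a single part)"
        )
    per_frame = ds.PerFrameFunctionalGroupsSequence
    shared = ds.SharedFunctionalGroupsSequence[0]
    iop = None
    if getattr(shared, "PlaneOrientationSequence", None):
        iop = shared.PlaneOrientationSequence[0].ImageOrientationPatient
    positions, times = [], []
    for fg in per_frame:
        positions.append(np.asarray(fg.PlanePositionSequence[0].ImagePositionPatient, float))
        te = None
        if getattr(fg, "MREchoSequence", None):
            te = float(fg.MREchoSequence[0].EffectiveEchoTime)
        times.append(te)
    ranks = _position_rank(positions, iop)
    n = slice_normal(iop)
    eranks = _echo_rank(times)
    planes = []
    for pos, te, fg in zip(positions, times, per_frame):
        slope, intercept = 1.0, 0.0
        if getattr(fg, "PixelValueTransformationSequence", None):
            item = fg.PixelValueTransformationSequence[0]
            slope = float(getattr(item, "RescaleSlope", 1.0))
            intercept = float(getattr(item, "RescaleIntercept", 0.0))
        planes.append(
            _stored_plane(
                volume, ranks[round(float(pos @ n), 6)], eranks[te], slope, intercept
            )
        )
    buf = np.stack(planes).astype(np.int16)
    if buf.shape[1:] != (int(ds.Rows), int(ds.Columns)):
        raise ShapeMismatchError(
            f"stored {ds.Rows}x{ds.Columns} vs voxels {buf.shape[1:]}"
        )
    ds.PixelData = np.ascontiguousarray(buf).tobytes()
    ds.SOPInstanceUID = generate_uid()
    path = out_dir / "reconstructed-enhanced.dcm"
    _save(ds, path)
    return [path]


def _save(ds, path: Path) -> None:
    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)


__all__ = ["reconstruct_dicom"]
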