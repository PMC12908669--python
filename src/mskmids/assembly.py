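"""Assemble per-frame records into part-separated 3D/4D volumes.

Multi-echo MR data are stacked on the 4th axis in ascending echo-time order,
one volume per complex image type (magnitude/phase or real/imaginary kept as
separate files, following the BIDS ``part-`` convention). CT/CR frames carry
no part and assemble into a single volume.
"""

from __future__ import annotations

import numpy as np

from .core import ImageVolume
from .dicom_reader import (
    FrameRecord,
    SeriesGroup,
    apply_rescale,
    compute_affine,
    sort_slices,
)
from .errors import (
    AmbiguousPartError,
    DegenerateGeometryError,
    DuplicateFrameError,
    RaggedAcquisitionError,
    UnscalablePhaseError,
)

#: tolerance (ms) when grouping frames by echo time — float jitter in headers
ECHO_TIME_TOL_MS = 1e-3

#: image-type tokens naming a complex part; single letters are the compact
#: vendor form of the same words
_PART_TOKENS = {
    "MAGNITUDE": "mag",
    "M": "mag",
    "PHASE": "phase",
    "P": "phase",
    "REAL": "real",
    "R": "real",
    "IMAGINARY": "imag",
    "I": "imag",
}


def frame_part(record: FrameRecord) -> str:
    """Complex-part label for one frame from its image type ('none' if absent)."""
    image_type = record.tags.get("ImageType")
    if image_type is None:
        return "none"
    tokens = [str(t).upper() for t in image_type]
    # positions 0-1 are ORIGINAL/DERIVED and PRIMARY/SECONDARY; the part
    # token, when present, appears from position 2 on
    found = {_PART_TOKENS[t] for t in tokens[2:] if t in _PART_TOKENS}
    if len(found) > 1:
        raise AmbiguousPartError(f"multiple part tokens in image type {tokens}")
    return found.pop() if found else "none"


def split_parts(group: SeriesGroup) -> dict[str, list[FrameRecord]]:
    """Partition a series by complex part; exhaustive and disjoint."""
    out: dict[str, list[FrameRecord]] = {}
    for f in group.frames:
        out.setdefault(frame_part(f), []).append(f)
    return out


def scale_phase(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Map stored phase values to radians in [-pi, pi].

    The rescale slope/intercept is applied first; if the rescaled values
    already lie within [-pi, pi] they are returned unchanged, otherwise they
    are linearly mapped so the data maximum lands on +pi and the minimum on
    -pi (vendors store phase on arbitrary integer ranges).
    """
    rescaled = apply_rescale(stored, slope, intercept)
    lo, hi = float(rescaled.min()), float(rescaled.max())
    if max(abs(lo), abs(hi)) <= np.pi * (1 + 1e-9):
        return rescaled
    if hi == lo:
        raise UnscalablePhaseError(
            f"constant phase plane at {hi} outside [-pi, pi]; no range to map"
        )
    return (rescaled - lo) / (hi - lo) * (2 * np.pi) - np.pi


def _echo_groups(frames: list[FrameRecord]) -> list[tuple[float | None, list[FrameRecord]]]:
    """Group frames by echo time (ascending, merged within tolerance)."""
    with_te = [(f.tags.get("EchoTime"), f) for f in frames]
    if all(te is None for te, _ in with_te):
        return [(None, frames)]
    groups: list[tuple[float, list[FrameRecord]]] = []
    for te, f in sorted(with_te, key=lambda p: float(p[0])):
        te = float(te)
        if groups and te - groups[-1][0] <= ECHO_TIME_TOL_MS:
            groups[-1][1].append(f)
        else:
            groups.append((te, [f]))
    return groups


def _planar_volume(frames: list[FrameRecord], part: str) -> ImageVolume:
    # projection data (plain radiography): no patient-space orientation;
    # the affine only encodes detector pixel spacing
    (frame,) = frames
    spacing = frame.tags.get("ImagerPixelSpacing") or frame.tags.get("PixelSpacing") or (1, 1)
    sy, sx = (float(v) for v in spacing)
    affine = np.diag([sx, sy, 1.0, 1.0])
    voxels = apply_rescale(
        frame.pixels,
        frame.tags.get("RescaleSlope", 1.0),
        frame.tags.get("RescaleIntercept", 0.0),
    ).T
    dtype_hint = _dtype_hint(frame, part)
    if dtype_hint == "int16":
        voxels = voxels.astype(np.int16)
    return ImageVolume(
        voxels=voxels, affine=affine, dim_labels=("x", "y"), part=part,
        dtype_hint=dtype_hint,
    )


def _dtype_hint(frame: FrameRecord, part: str) -> str:
    identity = (
        float(frame.tags.get("RescaleSlope", 1.0)) == 1.0
        and float(frame.tags.get("RescaleIntercept", 0.0)) == 0.0
    )
    return "int16" if identity and part != "phase" and frame.pixels.dtype.kind in "iu" else "float32"


def stack_volume(frames: list[FrameRecord], part: str = "none") -> ImageVolume:
    """Build one volume from same-part frames.

    Frames are grouped by distinct echo time (ascending) and slice-sorted
    within each echo; output is 3D for a single echo and 4D ``(x, y, z,
    echo)`` otherwise. Rescale is applied; phase data are converted to
    radians. The affine comes from the first echo's slice stack, and
    ``echo_times_ms`` matches the 4th-axis order.
    """
    if not frames:
        raise RaggedAcquisitionError("no frames to stack")
    if len(frames) == 1 and frames[0].tags.get("ImageOrientationPatient") is None:
        return _planar_volume(frames, part)

    echoes = _echo_groups(frames)
    n_slices = len(echoes[0][1])
    sorted_echoes = []
    for te, efr in echoes:
        if len(efr) != n_slices:
            raise RaggedAcquisitionError(
                f"echo {te}: {len(efr)} slices, expected {n_slices}"
            )
        ordered = sort_slices(efr)
        keys = [
            tuple(np.round(np.asarray(f.tags["ImagePositionPatient"], float), 4))
            for f in ordered
        ]
        if len(set(keys)) != len(keys):
            raise DuplicateFrameError(f"duplicate (echo={te}, position) frames")
        sorted_echoes.append((te, ordered))

    def plane(f: FrameRecord) -> np.ndarray:
        slope = f.tags.get("RescaleSlope", 1.0)
        intercept = f.tags.get("RescaleIntercept", 0.0)
        if part == "phase":
            return scale_phase(f.pixels, slope, intercept).T
        return apply_rescale(f.pixels, slope, intercept).T  # (x, y) = (col, row)

    data4d = np.stack(
        [np.stack([plane(f) for f in efr], axis=2) for _, efr in sorted_echoes],
        axis=3,
    )
    affine = compute_affine(sorted_echoes[0][1])
    echo_times = [te for te, _ in sorted_echoes if te is not None]

    hint = _dtype_hint(frames[0], part)
    if len(sorted_echoes) == 1:
        voxels = data4d[..., 0]
        labels = ("x", "y", "z")
    else:
        voxels = data4d
        labels = ("x", "y", "z", "echo")
    if hint == "int16":
        voxels = voxels.astype(np.int16)
    return ImageVolume(
        voxels=voxels,
        affine=affine.matrix,
        dim_labels=labels,
        part=part,
        dtype_hint=hint,
        echo_times_ms=echo_times or None,
    )


__all__ = [
    "split_parts",
    "stack_volume",
    "scale_phase",
    "frame_part",
    "ECHO_TIME_TOL_MS",
]
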