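"""Domain types and the filename/folder grammar.

The dataset layout follows the BIDS entity convention (``sub-``, ``ses-``,
``part-`` key-value tokens, underscore separated, acquisition suffix last)
inside per-modality folders::

    sub-01/[ses-a/]mr-anat/sub-01[_ses-a][_part-mag]_megre.nii.gz

Each image carries up to three JSON sidecars sharing its basename: the
minimal interpretive header (``.json``), the sensitive patient header
(``_patient.json``) and the full original DICOM header (``_extra.json``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import FilenameError, PairingError

# ---------------------------------------------------------------------------
# Suffix registry
# ---------------------------------------------------------------------------

#: Complex-part labels an MR volume may carry.
PARTS = ("mag", "phase", "real", "imag")

#: Recognized modality folders.
MODALITY_FOLDERS = ("ct", "cr", "mr-anat", "mr-quant", "us", "seg")

#: Sidecar / image extensions, in longest-match order for parsing.
EXTENSIONS = ("_patient.json", "_extra.json", ".nii.gz", ".json")


@dataclass(frozen=True)
class SuffixInfo:
    """One row of the acquisition registry: where a suffix lives and its shape."""

    folder: str
    #: spatial axis labels; a trailing non-spatial axis is listed explicitly
    dim_labels: tuple[str, ...]
    #: included = a converter exists; reserved = parses, but no converter yet
    status: str = "included"
    #: whether the 4th axis is allowed/expected (multi-echo data)
    fourth_axis: Optional[str] = None


#: suffix -> SuffixInfo. "Included" acquisitions plus reserved placeholders.
SUFFIX_REGISTRY: dict[str, SuffixInfo] = {
    "ct": SuffixInfo("ct", ("x", "y", "z")),
    "pcct": SuffixInfo("ct", ("x", "y", "z")),
    "hrpqct": SuffixInfo("ct", ("x", "y", "z")),
    "cr": SuffixInfo("cr", ("x", "y")),
    "t1": SuffixInfo("mr-quant", ("x", "y", "z")),
    "t2": SuffixInfo("mr-quant", ("x", "y", "z")),
    "wt2": SuffixInfo("mr-quant", ("x", "y", "z")),
    "dess": SuffixInfo("mr-anat", ("x", "y", "z")),
    "dess-fid": SuffixInfo("mr-anat", ("x", "y", "z")),
    "dess_echo": SuffixInfo("mr-anat", ("x", "y", "z")),
    "megre": SuffixInfo("mr-anat", ("x", "y", "z", "echo"), fourth_axis="echo"),
    "mese": SuffixInfo("mr-anat", ("x", "y", "z", "echo"), fourth_axis="echo"),
    # reserved: recognized by the grammar and validator, no converter built
    "vel": SuffixInfo("mr-quant", ("x", "y", "z", "time", "direction"), status="reserved"),
    "diff": SuffixInfo("mr-quant", ("x", "y", "z", "direction"), status="reserved"),
    "seg": SuffixInfo("seg", ("x", "y", "z", "label"), status="reserved"),
    "us": SuffixInfo("us", ("x", "y", "z"), status="reserved"),
}

#: Suffixes for which a complex-part entity is meaningful (MR only).
MR_SUFFIXES = frozenset(
    s for s, info in SUFFIX_REGISTRY.items() if info.folder.startswith("mr-")
)

RESERVED_SUFFIXES = frozenset(
    s for s, info in SUFFIX_REGISTRY.items() if info.status == "reserved"
)


def _valid_label(label: str) -> bool:
    return label.isalnum()


# ---------------------------------------------------------------------------
# Entity key
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityKey:
    """Names one output image: participant, optional session/part, suffix, folder.

    ``recognized`` is False when the suffix was parsed from disk but is not in
    the registry (forward compatibility: unknown acquisitions are indexed,
    never rejected).
    """

    subject: str
    suffix: str
    modality_folder: str
    session: Optional[str] = None
    part: Optional[str] = None
    recognized: bool = True

    def validate(self) -> "EntityKey":
        """Check all invariants; return self for chaining."""
        if not _valid_label(self.subject):
            raise FilenameError(f"subject label {self.subject!r} must be alphanumeric")
        if self.session is not None and not _valid_label(self.session):
            raise FilenameError(f"session label {self.session!r} must be alphanumeric")
        if self.modality_folder not in MODALITY_FOLDERS:
            raise PairingError(f"unknown modality folder {self.modality_folder!r}")
        info = SUFFIX_REGISTRY.get(self.suffix)
        if info is None:
            raise PairingError(f"unknown suffix {self.suffix!r}")
        if info.folder != self.modality_folder:
            raise PairingError(
                f"suffix {self.suffix!r} belongs in folder {info.folder!r}, "
                f"not {self.modality_folder!r}"
            )
        if self.part is not None:
            if self.part not in PARTS:
                raise FilenameError(f"unknown part label {self.part!r}")
            if self.suffix not in MR_SUFFIXES:
                raise PairingError(
                    f"part entity only valid for MR suffixes, not {self.suffix!r}"
                )
        return self

    @property
    def reserved(self) -> bool:
        return self.suffix in RESERVED_SUFFIXES


def compose_filename(key: EntityKey, extension: str) -> str:
    """Relative path for ``key`` with ``extension``.

    Layout: ``sub-<s>[/ses-<x>]/<folder>/sub-<s>[_ses-<x>][_part-<p>]_<suffix><ext>``.
    Deterministic; entity order is fixed. Raises on invalid keys or
    suffix/folder mismatches before producing any path.
    """
    if extension not in EXTENSIONS:
        raise FilenameError(f"unknown extension {extension!r}")
    key.validate()
    dirs = [f"sub-{key.subject}"]
    name = [f"sub-{key.subject}"]
    if key.session is not None:
        dirs.append(f"ses-{key.session}")
        name.append(f"ses-{key.session}")
    dirs.append(key.modality_folder)
    if key.part is not None:
        name.append(f"part-{key.part}")
    return "/".join(dirs) + "/" + "_".join(name) + f"_{key.suffix}" + extension


def parse_filename(path: str) -> tuple[EntityKey, str]:
    """Inverse of :func:`compose_filename`; returns ``(key, extension)``.

    Unknown suffixes come back with ``recognized=False`` rather than raising.
    Suffixes are matched longest-first against the registry before entity
    tokenization, so the registered suffix ``dess_echo`` — which contains the
    entity separator — parses correctly.
    """
    parts = path.replace("\\", "/").split("/")
    if len(parts) < 2:
        raise FilenameError(f"path {path!r} has fewer than 2 components")
    basename = parts[-1]
    folder = parts[-2]
    extension = next((e for e in EXTENSIONS if basename.endswith(e)), None)
    if extension is None:
        raise FilenameError(f"unknown extension on {basename!r}")
    stem = basename[: -len(extension)]

    # longest-match suffix against registry (handles the underscore in dess_echo)
    suffix = None
    recognized = True
    for cand in sorted(SUFFIX_REGISTRY, key=len, reverse=True):
        if stem.endswith("_" + cand):
            suffix = cand
            stem = stem[: -len(cand) - 1]
            break
    if suffix is None:
        head, sep, tail = stem.rpartition("_")
        if not sep or not tail:
            raise FilenameError(f"no suffix found in {basename!r}")
        suffix, stem, recognized = tail, head, False

    subject = session = part = None
    for token in stem.split("_"):
        if not token:
            raise FilenameError(f"empty entity token in {basename!r}")
        ent, sep, value = token.partition("-")
        if not sep or not value:
            raise FilenameError(f"malformed entity token {token!r} in {basename!r}")
        if ent == "sub":
            subject = value
        elif ent == "ses":
            session = value
        elif ent == "part":
            part = value
        # other BIDS entities (acq-, run-, task-) accepted silently, never emitted
    if subject is None:
        raise FilenameError(f"missing sub- entity in {basename!r}")

    key = EntityKey(
        subject=subject,
        session=session,
        part=part,
        suffix=suffix,
        modality_folder=folder,
        recognized=recognized,
    )
    return key, extension


# ---------------------------------------------------------------------------
# Image volume and sidecars
# ---------------------------------------------------------------------------

#: Axis labels a volume may use; the 4th axis, when present, is non-spatial.
DIM_LABELS = ("x", "y", "z", "echo", "time", "direction", "label")


@dataclass
class ImageVolume:
    """A voxel array in patient space; the unit of conversion.

    ``voxels`` is indexed ``(x, y, z[, echo])`` where x runs along DICOM
    columns and y along rows; ``affine`` maps voxel index ``(i, j, k, 1)`` to
    RAS patient coordinates in mm. ``part`` is the complex-component label
    ('none' outside MR). For multi-echo volumes ``echo_times_ms`` matches the
    4th-axis order.
    """

    voxels: np.ndarray
    affine: np.ndarray
    dim_labels: tuple[str, ...]
    part: str = "none"
    dtype_hint: str = "float32"
    echo_times_ms: Optional[list[float]] = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim not in (2, 3, 4):
            raise ValueError(f"voxels must have 2-4 axes, got {self.voxels.ndim}")
        if len(self.dim_labels) != self.voxels.ndim:
            raise ValueError(
                f"{len(self.dim_labels)} dim labels for {self.voxels.ndim} axes"
            )
        for lab in self.dim_labels:
            if lab not in DIM_LABELS:
                raise ValueError(f"unknown axis label {lab!r}")
        if self.voxels.ndim == 4 and self.dim_labels[3] not in (
            "echo",
            "time",
            "direction",
            "label",
        ):
            raise ValueError(f"invalid 4th-axis label {self.dim_labels[3]!r}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine upper-left 3x3 block is singular")
        if self.part not in PARTS + ("none",):
            raise ValueError(f"unknown part {self.part!r}")
        if self.part == "phase":
            amax = float(np.abs(self.voxels).max()) if self.voxels.size else 0.0
            if amax > np.pi * (1 + 1e-6):
                raise ValueError("phase voxels must lie in [-pi, pi] radians")

    @property
    def n_echoes(self) -> int:
        return self.voxels.shape[3] if self.voxels.ndim == 4 else 1


@dataclass
class SidecarBundle:
    """The up-to-three JSON metadata maps attached to one volume.

    ``main`` is the minimal interpretive header (never contains patient
    identifying keys); ``patient`` holds the sensitive fields; ``extra`` the
    full serialized DICOM header for bidirectional conversion.
    """

    main: dict
    patient: Optional[dict] = None
    extra: Optional[dict] = None


@dataclass(frozen=True)
class AffineTransform:
    """4x4 homogeneous voxel-to-patient transform (last row 0,0,0,1)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last affine row must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("singular 3x3 block")
        object.__setattr__(self, "matrix", m)

    def apply(self, ijk) -> np.ndarray:
        """Map voxel indices (..., 3) to patient mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.matrix[:3, :3].T + self.matrix[:3, 3]


__all__ = [
    "PARTS",
    "MODALITY_FOLDERS",
    "EXTENSIONS",
    "SUFFIX_REGISTRY",
    "SuffixInfo",
    "MR_SUFFIXES",
    "RESERVED_SUFFIXES",
    "EntityKey",
    "compose_filename",
    "parse_filename",
    "ImageVolume",
    "SidecarBundle",
    "AffineTransform",
]
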