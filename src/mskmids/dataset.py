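"""Read and write standard-compliant dataset trees.

On disk a dataset is::

    <root>/
      participants.tsv
      sub-01/
        mr-anat/
          sub-01_part-mag_megre.nii.gz
          sub-01_part-mag_megre.json
          sub-01_part-mag_megre_patient.json
          sub-01_part-mag_megre_extra.json
        ct/ ...
      derivatives/            # processed outputs, same sub/ses structure

Images are gzipped NIfTI-1 with both sform and qform set to the RAS affine
(sform authoritative); sidecars are UTF-8 JSON with 2-space indentation so
curated datasets diff cleanly under version control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    EntityKey,
    ImageVolume,
    SidecarBundle,
    SUFFIX_REGISTRY,
    compose_filename,
    parse_filename,
)
from .errors import CollisionError, FilenameError, MidsError, NotFoundError


def _json_dump(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def write_converted(
    volume: ImageVolume,
    sidecars: SidecarBundle,
    key: EntityKey,
    root,
    write_patient: bool = True,
    write_extra: bool = True,
    overwrite: bool = False,
    derivatives: bool = False,
) -> list[Path]:
    """Write one volume and its sidecars; returns the written paths (2-4).

    The main sidecar is always written; patient/extra only when enabled and
    present. With ``derivatives=True`` the same subject/session structure is
    mirrored under ``<root>/derivatives``. Idempotent under ``overwrite``.
    """
    root = Path(root)
    if derivatives:
        root = root / "derivatives"
    if volume.echo_times_ms is not None and "EchoTime" in sidecars.main:
        et = sidecars.main["EchoTime"]
        n = len(et) if isinstance(et, list) else 1
        if n != volume.n_echoes:
            raise MidsError(
                f"EchoTime length {n} does not match echo axis {volume.n_echoes}"
            )

    image_rel = compose_filename(key, ".nii.gz")  # validates key first
    targets: list[tuple[Path, object]] = [(root / image_rel, volume)]
    targets.append((root / compose_filename(key, ".json"), sidecars.main))
    if write_patient and sidecars.patient is not None:
        targets.append((root / compose_filename(key, "_patient.json"), sidecars.patient))
    if write_extra and sidecars.extra is not None:
        targets.append((root / compose_filename(key, "_extra.json"), sidecars.extra))

    if not overwrite:
        for path, _ in targets:
            if path.exists():
                raise CollisionError(f"{path} exists and overwrite is disabled")

    written = []
    for path, payload in targets:
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(payload, ImageVolume):
            dtype = np.int16 if payload.dtype_hint == "int16" else np.float32
            img = nib.Nifti1Image(np.asarray(payload.voxels, dtype=dtype), payload.affine)
            img.set_sform(payload.affine, code=1)
            img.set_qform(payload.affine, code=1)
            nib.save(img, path)
        else:
            _json_dump(payload, path)
        written.append(path)
    return written


def write_participants(rows, root) -> Path:
    """Write ``participants.tsv`` (tab-separated, ``n/a`` for missing).

    ``rows``: DataFrame or list of dicts; ``participant_id`` is placed first
    and must be unique.
    """
    df = pd.DataFrame(rows)
    if "participant_id" not in df.columns:
        raise MidsError("participants table requires a participant_id column")
    if df["participant_id"].duplicated().any():
        dup = df["participant_id"][df["participant_id"].duplicated()].iloc[0]
        raise MidsError(f"duplicate participant_id {dup!r}")
    cols = ["participant_id"] + [c for c in df.columns if c != "participant_id"]
    df = df[cols]
    path = Path(root) / "participants.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_participants(root) -> Optional[pd.DataFrame]:
    path = Path(root) / "participants.tsv"
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str}, na_values=["n/a"])


@dataclass
class IndexEntry:
    key: EntityKey
    image: Path
    sidecars: dict[str, Path] = field(default_factory=dict)  # main|patient|extra
    derivative: bool = False


@dataclass
class DatasetIndex:
    """Parsed inventory of a dataset tree."""

    root: Path
    entries: dict[EntityKey, IndexEntry] = field(default_factory=dict)
    participants: Optional[pd.DataFrame] = None
    unknown: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return sorted({e.key.subject for e in self.entries.values()})


_SIDECAR_KIND = {".json": "main", "_patient.json": "patient", "_extra.json": "extra"}


def load_dataset(root) -> DatasetIndex:
    """Walk a tree, parse filenames, pair images with their sidecars.

    Unknown files are listed separately, never fatal; an image without a
    main sidecar is recorded as an index warning.
    """
    root = Path(root)
    index = DatasetIndex(root=root, participants=read_participants(root))
    if not root.exists():
        return index
    sidecars: dict[tuple, dict[str, Path]] = {}
    images: dict[tuple, tuple[EntityKey, Path, bool]] = {}
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        rel = path.relative_to(root)
        if rel.name == "participants.tsv" and len(rel.parts) == 1:
            continue
        parts = rel.parts
        derivative = parts[0] == "derivatives"
        if derivative:
            parts = parts[1:]
        try:
            key, ext = parse_filename("/".join(parts))
        except FilenameError:
            index.unknown.append(path)
            continue
        ident = (key.subject, key.session, key.part, key.suffix, key.modality_folder, derivative)
        if ext == ".nii.gz":
            images[ident] = (key, path, derivative)
        else:
            sidecars.setdefault(ident, {})[_SIDECAR_KIND[ext]] = path
    for ident, (key, path, derivative) in images.items():
        entry = IndexEntry(
            key=key, image=path, sidecars=sidecars.get(ident, {}), derivative=derivative
        )
        if "main" not in entry.sidecars:
            index.warnings.append(f"{path}: image has no main sidecar")
        if not derivative:
            index.entries[key] = entry
        else:
            index.entries[key] = index.entries.get(key, entry)
    # orphan sidecars (no image) are unknown-but-indexed as warnings
    for ident, m in sidecars.items():
        if ident not in images:
            for p in m.values():
                index.warnings.append(f"{p}: sidecar without an image")
    if index.participants is not None:
        known = set(index.participants["participant_id"].astype(str))
        for subj in {k.subject for k in index.entries}:
            if f"sub-{subj}" not in known and subj not in known:
                index.warnings.append(f"sub-{subj} missing from participants.tsv")
    return index


def load_volume(index: DatasetIndex, key: EntityKey) -> tuple[ImageVolume, SidecarBundle]:
    """Reconstruct a volume and its sidecars from an indexed dataset."""
    entry = index.entries.get(key)
    if entry is None:
        raise NotFoundError(f"no entry for {compose_filename(key, '.nii.gz')}")
    img = nib.load(entry.image)
    voxels = np.asarray(img.dataobj)
    main = {}
    patient = extra = None
    if "main" in entry.sidecars:
        main = json.loads(entry.sidecars["main"].read_text(encoding="utf-8"))
    if "patient" in entry.sidecars:
        patient = json.loads(entry.sidecars["patient"].read_text(encoding="utf-8"))
    if "extra" in entry.sidecars:
        extra = json.loads(entry.sidecars["extra"].read_text(encoding="utf-8"))

    labels = ("x", "y", "z", "time")[: voxels.ndim]
    echo_times = None
    et = main.get("EchoTime")
    if isinstance(et, list):
        echo_times = [float(t) for t in et]
        if voxels.ndim == 4:
            labels = ("x", "y", "z", "echo")
    info = SUFFIX_REGISTRY.get(key.suffix)
    if info is not None and voxels.ndim == 4 and info.fourth_axis:
        labels = ("x", "y", "z", info.fourth_axis)
    volume = ImageVolume(
        voxels=voxels,
        affine=img.affine,
        dim_labels=tuple(labels),
        part=key.part or "none",
        dtype_hint=str(voxels.dtype) if voxels.dtype == np.int16 else "float32",
        echo_times_ms=echo_times,
    )
    return volume, SidecarBundle(main=main, patient=patient, extra=extra)


__all__ = [
    "write_converted",
    "write_participants",
    "read_participants",
    "load_dataset",
    "load_volume",
    "DatasetIndex",
    "IndexEntry",
]
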