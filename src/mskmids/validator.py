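"""Conformance validation of an existing dataset tree.

Each check has a stable code so reports are machine-readable:

=====  ====================================================================
V1     every file parses against the filename grammar
V2     suffix belongs to the modality folder it sits in
V3     main sidecar present with every required field, of the right JSON
       type (arrays where the standard says array)
V4     image dimensionality matches the acquisition (multi-echo MR 4D,
       CT 3D, radiography 2D)
V5     EchoTime array length equals the echo-axis length
V6     no patient-identifying key in a main sidecar
V7     participants.tsv well-formed and covering all subjects (warning)
V8     reserved suffix (vel/diff/seg/us): recognized, no specification yet
       (warning)
=====  ====================================================================

An empty issue list (at error severity) means the tree is compliant. Extra
keys in a main sidecar are warnings by default to tolerate forward-
compatible additions; ``strict=True`` upgrades warnings to errors. Files
under ``derivatives/`` are only checked against the grammar (V1) — derived
content is user-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib

from .anonymize import PATIENT_FIELDS
from .core import RESERVED_SUFFIXES, SUFFIX_REGISTRY, parse_filename
from .converters import REGISTRY, spec_for_suffix
from .errors import FilenameError, MidsError

#: sidecar keys that are informative, never required — tolerated silently
_INFORMATIVE_KEYS = frozenset({"WaterFatShiftSource"})


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    code: str  # V1..V8
    path: str
    message: str

    def __str__(self):
        return f"[{self.code}:{self.severity}] {self.path}: {self.message}"


def check_required_fields(sidecar: dict, suffix: str) -> list[str]:
    """Required fields missing from a main sidecar, per the converter registry."""
    spec = spec_for_suffix(suffix)
    if spec is None:
        return []
    return [k for k in spec.required_fields if k not in sidecar]


def _check_entry(issues, rel, key, img_path, sidecar_path, strict):
    def add(severity, code, message, path=rel):
        if strict and severity == "warning":
            severity = "error"
        issues.append(Issue(severity, code, str(path), message))

    info = SUFFIX_REGISTRY.get(key.suffix)
    if not key.recognized or info is None:
        add("warning", "V1", f"unknown suffix {key.suffix!r}")
        return
    if info.folder != key.modality_folder:
        add(
            "error",
            "V2",
            f"suffix {key.suffix!r} belongs in {info.folder!r}, found in "
            f"{key.modality_folder!r}",
        )
    if key.part is not None and not info.folder.startswith("mr-"):
        add("error", "V2", f"part entity not valid for suffix {key.suffix!r}")
    if key.suffix in RESERVED_SUFFIXES:
        add("warning", "V8", f"suffix {key.suffix!r} is reserved, not yet specified")
        return

    spec = spec_for_suffix(key.suffix)
    sidecar = None
    if sidecar_path is None or not sidecar_path.exists():
        add("error", "V3", "main sidecar missing")
    else:
        try:
            sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            add("error", "V3", f"main sidecar unreadable: {exc}", path=sidecar_path)
    if sidecar is not None and spec is not None:
        for missing in check_required_fields(sidecar, key.suffix):
            add("error", "V3", f"required field {missing!r} missing from sidecar")
        for key_name in spec.array_fields:
            if key_name in sidecar and not isinstance(sidecar[key_name], list):
                add("error", "V3", f"field {key_name!r} must be a JSON array")
        for extra_key in sidecar:
            if (
                extra_key not in spec.required_fields
                and extra_key not in _INFORMATIVE_KEYS
            ):
                add("warning", "V3", f"unexpected sidecar key {extra_key!r}")
        for patient_key in PATIENT_FIELDS:
            if patient_key in sidecar:
                add("error", "V6", f"patient-identifying key {patient_key!r} in main sidecar")

    shape = None
    if img_path is not None and img_path.exists():
        try:
            shape = nib.load(img_path).shape
        except Exception as exc:
            add("error", "V4", f"image unreadable: {exc}")
    if shape is not None:
        expected = len(info.dim_labels)
        n_echo = None
        if sidecar is not None and isinstance(sidecar.get("EchoTime"), list):
            n_echo = len(sidecar["EchoTime"])
        if info.fourth_axis == "echo":
            # multi-echo acquisitions are 4D when more than one echo exists
            want = 4 if (n_echo or 2) > 1 else 3
            if len(shape) != want:
                add("error", "V4", f"expected {want}D volume, got {len(shape)}D")
            elif n_echo is not None and len(shape) == 4 and shape[3] != n_echo:
                add(
                    "error",
                    "V5",
                    f"EchoTime has {n_echo} entries but echo axis is {shape[3]}",
                )
        elif len(shape) != expected:
            add("error", "V4", f"expected {expected}D volume, got {len(shape)}D")


def validate_dataset(root, strict: bool = False) -> list[Issue]:
    """All conformance issues for the tree at ``root``."""
    root = Path(root)
    if not root.exists():
        raise MidsError(f"dataset root {root} does not exist")
    issues: list[Issue] = []

    images = {}
    mains = {}
    subjects = set()
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        rel = path.relative_to(root)
        if str(rel) == "participants.tsv":
            continue
        parts = rel.parts
        derivative = parts[0] == "derivatives"
        if derivative:
            parts = parts[1:]
            if not parts:
                continue
        try:
            key, ext = parse_filename("/".join(parts))
        except FilenameError as exc:
            sev = "warning" if strict is False else "error"
            issues.append(Issue(sev, "V1", str(rel), f"does not match grammar: {exc}"))
            continue
        if derivative:
            continue  # grammar-only for derived data
        subjects.add(key.subject)
        ident = (key.subject, key.session, key.part, key.suffix, key.modality_folder)
        if ext == ".nii.gz":
            images[ident] = (rel, key, path)
        elif ext == ".json":
            mains[ident] = path

    for ident, (rel, key, path) in images.items():
        _check_entry(issues, rel, key, path, mains.get(ident), strict)

    ptsv = root / "participants.tsv"
    if subjects:
        if not ptsv.exists():
            issues.append(
                Issue(
                    "error" if strict else "warning",
                    "V7",
                    "participants.tsv",
                    "missing participants.tsv",
                )
            )
        else:
            try:
                import pandas as pd

                table = pd.read_csv(ptsv, sep="\t", dtype=str)
                if "participant_id" not in table.columns:
                    raise ValueError("no participant_id column")
                ids = set(table["participant_id"])
                for subj in sorted(subjects):
                    if f"sub-{subj}" not in ids and subj not in ids:
                        issues.append(
                            Issue(
                                "error" if strict else "warning",
                                "V7",
                                "participants.tsv",
                                f"sub-{subj} not covered",
                            )
                        )
            except Exception as exc:
                issues.append(
                    Issue(
                        "error" if strict else "warning",
                        "V7",
                        "participants.tsv",
                        f"not well-formed: {exc}",
                    )
                )
    return issues


def errors_only(issues: list[Issue]) -> list[Issue]:
    return [i for i in issues if i.severity == "error"]


def report_jsonl(issues: list[Issue]) -> str:
    """Machine-readable report: one JSON object per line."""
    return "\n".join(
        json.dumps(
            {"severity": i.severity, "code": i.code, "path": i.path, "message": i.message}
        )
        for i in issues
    )


__all__ = [
    "Issue",
    "validate_dataset",
    "check_required_fields",
    "errors_only",
    "report_jsonl",
]
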