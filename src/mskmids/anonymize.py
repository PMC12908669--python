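"""Partition DICOM headers into the patient sidecar and the extra sidecar.

Anonymity by exclusion: the main sidecar only ever contains the fields the
standard requires, all potentially identifying attributes are collected into
a separate ``_patient.json`` that can be removed by deleting one file, and
the full-header ``_extra.json`` can be scrubbed of the same fields so that
it cannot re-leak identity.

The extra sidecar uses the DICOM JSON model (PS3.18): each attribute keyed
by its 8-digit hex tag with ``vr``/``Value`` members, binary values base64
inline — delegated to pydicom, so serialization is lossless and
round-trippable including private tags. Pixel data are excluded (they live
in the NIfTI file).
"""

from __future__ import annotations

from typing import Iterable, Optional

from pydicom.dataset import Dataset
from pydicom.datadict import tag_for_keyword

from .dicom_reader import SeriesGroup

#: Frozen, versioned list of patient-identifying attributes (seeded from the
#: DICOM basic confidentiality profile plus institution/equipment fields that
#: standard BIDS would keep but this standard relocates).
PATIENT_FIELDS: tuple[str, ...] = (
    "PatientName",
    "PatientID",
    "PatientBirthDate",
    "PatientSex",
    "PatientAge",
    "PatientWeight",
    "PatientSize",
    "PatientAddress",
    "PatientTelephoneNumbers",
    "OtherPatientIDs",
    "OtherPatientNames",
    "AccessionNumber",
    "InstitutionName",
    "InstitutionAddress",
    "ReferringPhysicianName",
    "PerformingPhysicianName",
    "PhysiciansOfRecord",
    "OperatorsName",
    "DeviceSerialNumber",
    "StationName",
    "StudyDate",
    "SeriesDate",
    "AcquisitionDate",
    "ContentDate",
    "StudyTime",
    "SeriesTime",
    "ContentTime",
    "AcquisitionDateTime",
    "StudyDescription",
    "ImageComments",
    "StudyComments",
    "AdditionalPatientHistory",
)

#: hex tag strings for the same fields, as used by DICOM JSON keys
PATIENT_TAG_KEYS: frozenset[str] = frozenset(
    f"{tag_for_keyword(kw):08X}" for kw in PATIENT_FIELDS if tag_for_keyword(kw)
)

_PIXEL_DATA_KEYS = frozenset({"7FE00008", "7FE00009", "7FE00010"})


def split_patient_fields(tags: dict) -> tuple[dict, dict]:
    """Split a keyword->value map into (patient map, residual map).

    The union reconstructs the input; the residual contains no
    patient-identifying key. Absent fields are simply omitted.
    """
    patient = {k: v for k, v in tags.items() if k in PATIENT_FIELDS}
    residual = {k: v for k, v in tags.items() if k not in PATIENT_FIELDS}
    return patient, residual


def patient_sidecar(dataset: Dataset) -> dict:
    """JSON-able patient sidecar from one source header."""
    out = {}
    for kw in PATIENT_FIELDS:
        value = getattr(dataset, kw, None)
        if value is not None and str(value) != "":
            out[kw] = str(value)
    return out


def _dataset_to_json(ds: Dataset) -> dict:
    d = ds.to_json_dict()
    for key in _PIXEL_DATA_KEYS:
        d.pop(key, None)
    return d


def serialize_extra(group: SeriesGroup) -> dict:
    """Full-header sidecar for one series.

    Classic series store one JSON header per source file under ``frames``;
    enhanced input stores the single multi-frame header (its own per-frame
    functional groups included) as a one-element ``frames`` list.
    """
    if group.source_kind == "enhanced":
        frames = [_dataset_to_json(group.dataset)]
    else:
        frames = [_dataset_to_json(f.dataset) for f in group.frames]
    return {"SourceKind": group.source_kind, "Frames": frames}


def deserialize_extra(extra: dict) -> tuple[str, list[Dataset]]:
    """Inverse of :func:`serialize_extra` (pixel data absent by design)."""
    return extra["SourceKind"], [Dataset.from_json(f) for f in extra["Frames"]]


def _scrub_json(obj):
    if isinstance(obj, dict):
        out = {}
        for key, value in obj.items():
            if key in PATIENT_TAG_KEYS:
                continue
            out[key] = _scrub_json(value)
        return out
    if isinstance(obj, list):
        return [_scrub_json(v) for v in obj]
    return obj


def anonymize_extra(extra: dict) -> dict:
    """Remove (not blank) every patient-identifying tag from an extra
    sidecar, recursing into sequences and per-frame groups."""
    return _scrub_json(extra)


__all__ = [
    "PATIENT_FIELDS",
    "PATIENT_TAG_KEYS",
    "split_patient_fields",
    "patient_sidecar",
    "serialize_extra",
    "deserialize_extra",
    "anonymize_extra",
]
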