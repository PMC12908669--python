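"""End-to-end conversion: read -> detect -> assemble -> extract -> write.

One call converts every recognized series under an input directory into a
dataset tree, producing a per-series disposition report. Unrecognized
series are skipped (strict-compliance philosophy: nothing is ever
force-converted); series whose required metadata cannot be extracted are
rejected with the reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .anonymize import anonymize_extra, patient_sidecar, serialize_extra
from .assembly import split_parts, stack_volume
from .converters import ConverterSpec, REGISTRY, detect_acquisition, extract_metadata
from .core import EntityKey, SidecarBundle
from .dataset import write_converted, write_participants
from .dicom_reader import SeriesGroup, read_dicom_tree
from .errors import MidsError


@dataclass
class SeriesReport:
    uid: str
    disposition: str  # "converted" | "skipped" | "rejected"
    suffix: Optional[str] = None
    reason: Optional[str] = None
    written: list[Path] = field(default_factory=list)


def convert_series(
    group: SeriesGroup,
    subject: str,
    out_root,
    session: Optional[str] = None,
    anonymize: bool = False,
    write_patient: bool = True,
    write_extra: bool = True,
    overwrite: bool = False,
    registry: Optional[list[ConverterSpec]] = None,
) -> SeriesReport:
    """Convert one series; returns its disposition."""
    spec = detect_acquisition(group, registry)
    if spec is None:
        return SeriesReport(uid=group.uid, disposition="skipped", reason="unrecognized")
    try:
        parts = split_parts(group)
        written: list[Path] = []
        for part, frames in sorted(parts.items()):
            volume = stack_volume(frames, part)
            main = extract_metadata(group, spec, volume)
            if group.source_kind == "classic" and len(parts) > 1:
                # per-part frame list so each part round-trips independently
                sub = SeriesGroup(uid=group.uid, frames=frames, source_kind="classic")
                extra = serialize_extra(sub)
            else:
                extra = serialize_extra(group)
            patient = patient_sidecar(
                group.dataset if group.source_kind == "enhanced" else frames[0].dataset
            )
            if anonymize:
                extra = anonymize_extra(extra)
                patient = None
            key = EntityKey(
                subject=subject,
                session=session,
                part=None if part == "none" else part,
                suffix=spec.suffix,
                modality_folder=spec.modality_folder,
            )
            bundle = SidecarBundle(main=main, patient=patient, extra=extra)
            written.extend(
                write_converted(
                    volume,
                    bundle,
                    key,
                    out_root,
                    write_patient=write_patient and not anonymize,
                    write_extra=write_extra,
                    overwrite=overwrite,
                )
            )
        return SeriesReport(
            uid=group.uid, disposition="converted", suffix=spec.suffix, written=written
        )
    except MidsError as exc:
        return SeriesReport(
            uid=group.uid, disposition="rejected", suffix=spec.suffix, reason=str(exc)
        )


def convert_directory(
    in_dir,
    out_root,
    subject: str,
    session: Optional[str] = None,
    anonymize: bool = False,
    write_patient: bool = True,
    write_extra: bool = True,
    overwrite: bool = False,
    participants_row: Optional[dict] = None,
    registry: Optional[list[ConverterSpec]] = None,
) -> list[SeriesReport]:
    """Convert every DICOM series under ``in_dir`` into ``out_root``.

    The participants table gains one row for the subject (free-form
    health-data columns may be passed via ``participants_row``).
    """
    groups = read_dicom_tree(in_dir)
    reports = [
        convert_series(
            g,
            subject,
            out_root,
            session=session,
            anonymize=anonymize,
            write_patient=write_patient,
            write_extra=write_extra,
            overwrite=overwrite,
            registry=registry,
        )
        for g in groups
    ]
    if any(r.disposition == "converted" for r in reports):
        row = {"participant_id": f"sub-{subject}"}
        if participants_row:
            row.update(participants_row)
        _merge_participants(row, out_root)
    return reports


def _merge_participants(row: dict, root) -> None:
    from .dataset import read_participants

    existing = read_participants(root)
    rows = []
    if existing is not None:
        rows = existing.to_dict("records")
        rows = [r for r in rows if r.get("participant_id") != row["participant_id"]]
    rows.append(row)
    rows.sort(key=lambda r: str(r.get("participant_id")))
    write_participants(rows, root)


__all__ = ["convert_directory", "convert_series", "SeriesReport"]
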