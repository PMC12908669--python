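"""Acquisition recognition and required-metadata extraction.

The converter registry is a declarative list of :class:`ConverterSpec`
plugins, one per supported acquisition. Detection walks the registry
most-specific-first and returns the first match; a series matching nothing
is *skipped*, never force-converted — only acquisitions explicitly covered
by the standard are emitted, which both guarantees strictly compliant
sidecars and prevents identifying free-text fields from leaking through.

New acquisitions are supported by registering a new spec; existing specs
never need modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .core import ImageVolume, SUFFIX_REGISTRY
from .dicom_reader import SeriesGroup
from .errors import AmbiguousDetectionError, IncompleteMetadataError

#: gyromagnetic ratio of 1H, MHz/T
GAMMA_MHZ_PER_T = 42.577
#: water-fat chemical shift, ppm
WATER_FAT_PPM = 3.4

#: series-description tokens identifying derived quantitative maps; no DICOM
#: tag encodes "water T2", so these are configuration, extensible at runtime
MAP_TOKENS: dict[str, str] = {
    "WT2 MAP": "wt2",
    "T2 MAP": "t2",
    "T1 MAP": "t1",
}

#: sequence-name tokens for double-echo steady-state acquisitions
DESS_TOKENS = ("DESS", "MENSA", "FADE")


def _upper(value) -> str:
    return str(value or "").upper()


def _sequence_tokens(tags: dict) -> str:
    """Concatenated sequence descriptors, checked in a fixed priority order:
    ScanningSequence first, then EchoPulseSequence, then sequence names."""
    parts = []
    ss = tags.get("ScanningSequence")
    if ss is not None:
        parts.append(" ".join(ss) if isinstance(ss, (list, tuple)) else str(ss))
    parts.append(_upper(tags.get("EchoPulseSequence")))
    parts.append(_upper(tags.get("SequenceName")))
    parts.append(_upper(tags.get("PulseSequenceName")))
    return " ".join(p for p in parts if p).upper()


def _is_gradient_echo(tags: dict) -> bool:
    seq = _sequence_tokens(tags)
    return "GR" in seq.split() or "GRADIENT" in seq


def _is_spin_echo(tags: dict) -> bool:
    seq = _sequence_tokens(tags)
    return "SE" in seq.split() or "SPIN" in seq


def _has_inversion(tags: dict) -> bool:
    seq = _sequence_tokens(tags)
    return "IR" in seq.split() or "INVERSION" in seq


def _is_dess(tags: dict) -> bool:
    seq = _sequence_tokens(tags) + " " + _upper(tags.get("SeriesDescription"))
    return any(tok in seq for tok in DESS_TOKENS)


def _map_suffix(tags: dict) -> Optional[str]:
    desc = _upper(tags.get("SeriesDescription"))
    for token, suffix in MAP_TOKENS.items():
        if token in desc:
            return suffix
    return None


@dataclass(frozen=True)
class ConverterSpec:
    """One supported acquisition: how to recognize it and what to extract.

    ``(modality_folder, suffix, required_fields, dimensionality)`` mirror the
    standard's registry row for the acquisition; ``detect`` is a predicate
    over series-level tags; ``extract`` builds the main sidecar and must
    produce every required field or raise.
    """

    name: str
    suffix: str
    modality_folder: str
    detect: Callable[[SeriesGroup], bool]
    required_fields: tuple[str, ...]
    dimensionality: tuple[str, ...]
    extract: Callable[[SeriesGroup, ImageVolume], dict]
    #: required fields whose JSON value must be an array
    array_fields: tuple[str, ...] = ()
    #: detection priority tier; lower = more specific. Two matches within the
    #: same tier are ambiguous.
    specificity: int = 0


def _require(tags: dict, key: str, suffix: str):
    value = tags.get(key)
    if value is None:
        raise IncompleteMetadataError(key, suffix)
    return value


def _num(value) -> float:
    return float(value)


# ---------------------------------------------------------------------------
# Per-acquisition extraction
# ---------------------------------------------------------------------------


def _extract_megre(group: SeriesGroup, volume: ImageVolume) -> dict:
    tags = group.tags
    if not volume.echo_times_ms:
        raise IncompleteMetadataError("EchoTime", "megre")
    main = {"EchoTime": [float(t) for t in volume.echo_times_ms]}
    b0 = _num(_require(tags, "MagneticFieldStrength", "megre"))
    pbw = _num(_require(tags, "PixelBandwidth", "megre"))
    wfs = tags.get("WaterFatShift")
    if wfs is not None:
        main["WaterFatShift"] = float(wfs)
        main["WaterFatShiftSource"] = "vendor"
    else:
        # water-fat frequency shift (Hz) at this field over the per-pixel
        # bandwidth: gamma [MHz/T] * shift [ppm] cancel to Hz/T
        main["WaterFatShift"] = b0 * GAMMA_MHZ_PER_T * WATER_FAT_PPM / pbw
        main["WaterFatShiftSource"] = "computed"
    main["MagneticFieldStrength"] = b0
    main["PixelBandwidth"] = pbw
    return main


def _extract_mese(group: SeriesGroup, volume: ImageVolume) -> dict:
    tags = group.tags
    if not volume.echo_times_ms:
        raise IncompleteMetadataError("EchoTime", "mese")
    refocus = tags.get("RefocusingFlipAngle")
    if refocus is None:
        # no standard DICOM attribute carries the refocusing angle; on a
        # spin-echo acquisition vendors report it as the flip angle
        refocus = tags.get("FlipAngle")
    if refocus is None:
        raise IncompleteMetadataError("RefocusingFlipAngle", "mese")
    return {
        "EchoTime": [float(t) for t in volume.echo_times_ms],
        "RefocusingFlipAngle": _num(refocus),
    }


def _extract_dess(group: SeriesGroup, volume: ImageVolume) -> dict:
    return {"PulseSequenceType": "DESS"}


def _extract_ct(suffix: str):
    def extract(group: SeriesGroup, volume: ImageVolume) -> dict:
        tags = group.tags
        main = {
            "XRayEnergy": _num(_require(tags, "KVP", suffix)),
            "XRayExposure": _num(_require(tags, "Exposure", suffix)),
            "ConvolutionKernel": str(_require(tags, "ConvolutionKernel", suffix)),
            "RescaleIntercept": _num(tags.get("RescaleIntercept", 0.0)),
            "RescaleSlope": _num(tags.get("RescaleSlope", 1.0)),
        }
        if suffix == "hrpqct":
            for key in (
                "ScancoMuScaling",
                "ScancoDensitySlope",
                "ScancoDensityIntercept",
                "ScancoMuWater",
            ):
                main[key] = _num(_require(tags, key, suffix))
        return main

    return extract


def _extract_cr(group: SeriesGroup, volume: ImageVolume) -> dict:
    tags = group.tags
    return {
        "ExposureTime": _num(_require(tags, "ExposureTime", "cr")),
        "XRayTubeCurrent": _num(_require(tags, "XRayTubeCurrent", "cr")),
    }


def _extract_map(group: SeriesGroup, volume: ImageVolume) -> dict:
    return {}


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_CT_FIELDS = (
    "XRayEnergy",
    "XRayExposure",
    "ConvolutionKernel",
    "RescaleIntercept",
    "RescaleSlope",
)
_SCANCO_EXTRA = (
    "ScancoMuScaling",
    "ScancoDensitySlope",
    "ScancoDensityIntercept",
    "ScancoMuWater",
)


def _mr(group: SeriesGroup) -> bool:
    return _upper(group.tags.get("Modality")) == "MR"


def _ct(group: SeriesGroup) -> bool:
    return _upper(group.tags.get("Modality")) == "CT"


def default_registry() -> list[ConverterSpec]:
    """The built-in plugin registry, most-specific specs first."""
    return [
        ConverterSpec(
            name="hrpqct",
            suffix="hrpqct",
            modality_folder="ct",
            specificity=0,
            detect=lambda g: _ct(g) and "SCANCO" in _upper(g.tags.get("Manufacturer")),
            required_fields=_CT_FIELDS + _SCANCO_EXTRA,
            dimensionality=("x", "y", "z"),
            extract=_extract_ct("hrpqct"),
        ),
        ConverterSpec(
            name="pcct",
            suffix="pcct",
            modality_folder="ct",
            specificity=0,
            detect=lambda g: _ct(g)
            and "PHOTON" in _upper(g.tags.get("DetectorType")),
            required_fields=_CT_FIELDS,
            dimensionality=("x", "y", "z"),
            extract=_extract_ct("pcct"),
        ),
        ConverterSpec(
            name="ct",
            suffix="ct",
            modality_folder="ct",
            specificity=1,
            detect=_ct,
            required_fields=_CT_FIELDS,
            dimensionality=("x", "y", "z"),
            extract=_extract_ct("ct"),
        ),
        ConverterSpec(
            name="cr",
            suffix="cr",
            modality_folder="cr",
            specificity=0,
            detect=lambda g: _upper(g.tags.get("Modality")) in ("CR", "DX"),
            required_fields=("ExposureTime", "XRayTubeCurrent"),
            dimensionality=("x", "y"),
            extract=_extract_cr,
        ),
        ConverterSpec(
            name="wt2-map",
            suffix="wt2",
            modality_folder="mr-quant",
            specificity=0,
            detect=lambda g: _mr(g) and _map_suffix(g.tags) == "wt2",
            required_fields=(),
            dimensionality=("x", "y", "z"),
            extract=_extract_map,
        ),
        ConverterSpec(
            name="t2-map",
            suffix="t2",
            modality_folder="mr-quant",
            specificity=0,
            detect=lambda g: _mr(g) and _map_suffix(g.tags) == "t2",
            required_fields=(),
            dimensionality=("x", "y", "z"),
            extract=_extract_map,
        ),
        ConverterSpec(
            name="t1-map",
            suffix="t1",
            modality_folder="mr-quant",
            specificity=0,
            detect=lambda g: _mr(g) and _map_suffix(g.tags) == "t1",
            required_fields=(),
            dimensionality=("x", "y", "z"),
            extract=_extract_map,
        ),
        ConverterSpec(
            name="dess",
            suffix="dess",
            modality_folder="mr-anat",
            specificity=0,
            detect=lambda g: _mr(g) and _is_dess(g.tags),
            required_fields=("PulseSequenceType",),
            dimensionality=("x", "y", "z"),
            extract=_extract_dess,
        ),
        ConverterSpec(
            name="megre",
            suffix="megre",
            modality_folder="mr-anat",
            specificity=1,
            detect=lambda g: _mr(g)
            and _is_gradient_echo(g.tags)
            and not _has_inversion(g.tags)
            and not _is_dess(g.tags)
            and len(g.distinct_echo_times()) >= 2,
            required_fields=(
                "EchoTime",
                "WaterFatShift",
                "MagneticFieldStrength",
                "PixelBandwidth",
            ),
            array_fields=("EchoTime",),
            dimensionality=("x", "y", "z", "echo"),
            extract=_extract_megre,
        ),
        ConverterSpec(
            name="mese",
            suffix="mese",
            modality_folder="mr-anat",
            specificity=1,
            detect=lambda g: _mr(g)
            and _is_spin_echo(g.tags)
            and not _is_gradient_echo(g.tags)
            and len(g.distinct_echo_times()) >= 2,
            required_fields=("EchoTime", "RefocusingFlipAngle"),
            array_fields=("EchoTime",),
            dimensionality=("x", "y", "z", "echo"),
            extract=_extract_mese,
        ),
    ]


#: module-level registry used by the pipeline, validator and docs; treat as
#: read-only, extend via register()
REGISTRY: list[ConverterSpec] = default_registry()


def register(spec: ConverterSpec, registry: Optional[list[ConverterSpec]] = None) -> None:
    """Add a plugin spec (prepended within its specificity tier)."""
    reg = REGISTRY if registry is None else registry
    for i, existing in enumerate(reg):
        if existing.specificity >= spec.specificity:
            reg.insert(i, spec)
            return
    reg.append(spec)


def spec_for_suffix(suffix: str, registry: Optional[list[ConverterSpec]] = None) -> Optional[ConverterSpec]:
    for spec in REGISTRY if registry is None else registry:
        if spec.suffix == suffix:
            return spec
    return None


def detect_acquisition(
    group: SeriesGroup, registry: Optional[list[ConverterSpec]] = None
) -> Optional[ConverterSpec]:
    """First matching spec, or None (series skipped, never force-converted)."""
    reg = REGISTRY if registry is None else registry
    matches = [s for s in reg if s.detect(group)]
    if not matches:
        return None
    best = min(s.specificity for s in matches)
    top = [s for s in matches if s.specificity == best]
    if len(top) > 1:
        raise AmbiguousDetectionError(
            "series matches multiple converters at equal specificity: "
            + ", ".join(s.name for s in top)
        )
    return top[0]


def extract_metadata(group: SeriesGroup, spec: ConverterSpec, volume: ImageVolume) -> dict:
    """Main-sidecar map for one converted volume; every required field present."""
    main = spec.extract(group, volume)
    for key in spec.required_fields:
        if key not in main:
            raise IncompleteMetadataError(key, spec.suffix)
    assert SUFFIX_REGISTRY[spec.suffix].folder == spec.modality_folder
    return main


__all__ = [
    "ConverterSpec",
    "REGISTRY",
    "default_registry",
    "register",
    "detect_acquisition",
    "extract_metadata",
    "spec_for_suffix",
    "GAMMA_MHZ_PER_T",
    "WATER_FAT_PPM",
    "MAP_TOKENS",
    "DESS_TOKENS",
]
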