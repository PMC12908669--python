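"""Acquisition detection and required-metadata extraction."""

import numpy as np
import pytest

from mskmids.assembly import split_parts, stack_volume
from mskmids.converters import (
    ConverterSpec,
    GAMMA_MHZ_PER_T,
    WATER_FAT_PPM,
    default_registry,
    detect_acquisition,
    extract_metadata,
    register,
    spec_for_suffix,
)
from mskmids.core import SUFFIX_REGISTRY
from mskmids.dicom_reader import FrameRecord, SeriesGroup, read_dicom_tree
from mskmids.errors import AmbiguousDetectionError, IncompleteMetadataError
from mskmids.synthetic import make_megre_classic


def _mr_group(**tags):
    base = {"Modality": "MR", "Manufacturer": "x", "ImageOrientationPatient": None}
    base.update(tags)
    base = {k: v for k, v in base.items() if v is not None}
    frames = [
        FrameRecord(tags={**base, "EchoTime": te, "InstanceNumber": i}, pixels=np.zeros((2, 2)))
        for i, te in enumerate(tags.pop("_echo_times", (10.0,)))
    ]
    return SeriesGroup(uid="u", frames=frames, source_kind="classic")


@pytest.mark.parametrize(
    "variant,expected",
    [("megre", "megre"), ("mese", "mese"), ("ct", "ct"), ("pcct", "pcct"),
     ("hrpqct", "hrpqct"), ("cr", "cr")],
)
def test_detection_matrix(all_fixture_dirs, variant, expected):
    """Every fixture variant is detected by exactly one converter."""
    groups = read_dicom_tree(all_fixture_dirs[variant])
    assert len(groups) == 1
    spec = detect_acquisition(groups[0])
    assert spec is not None and spec.suffix == expected
    # and by *exactly one*: no other registered spec matches at its tier
    matches = [s for s in default_registry() if s.detect(groups[0])]
    best = min(s.specificity for s in matches)
    assert len([s for s in matches if s.specificity == best]) == 1


def test_single_echo_mr_skipped():
    group = _mr_group(ScanningSequence="GR", _echo_times=(10.0,))
    assert detect_acquisition(group) is None


def test_unrecognized_modality_skipped_never_raises():
    group = _mr_group(Modality="XA", _echo_times=(1.0,))
    assert detect_acquisition(group) is None


def test_megre_predicate_requires_no_inversion():
    group = _mr_group(ScanningSequence=["GR", "IR"], _echo_times=(2.0, 4.0))
    assert detect_acquisition(group) is None


def test_mese_detected_via_echo_pulse_sequence_fallback():
    """Enhanced files advertise EchoPulseSequence instead of ScanningSequence."""
    group = _mr_group(EchoPulseSequence="SPIN", _echo_times=(10.0, 20.0))
    spec = detect_acquisition(group)
    assert spec is not None and spec.suffix == "mese"


def test_dess_detected_by_sequence_token():
    for token in ("DESS", "MENSA", "FADE"):
        group = _mr_group(SequenceName=token, _echo_times=(5.0,))
        spec = detect_acquisition(group)
        assert spec is not None and spec.suffix == "dess"


def test_quant_map_detected_by_series_description():
    group = _mr_group(SeriesDescription="knee wT2 map", _echo_times=(10.0,))
    spec = detect_acquisition(group)
    assert spec is not None and spec.suffix == "wt2"


def test_ambiguous_detection_raises():
    reg = default_registry()
    dup = ConverterSpec(
        name="ct-clone", suffix="ct", modality_folder="ct", specificity=1,
        detect=lambda g: str(g.tags.get("Modality")).upper() == "CT",
        required_fields=(), dimensionality=("x", "y", "z"),
        extract=lambda g, v: {},
    )
    reg.append(dup)
    frames = [FrameRecord(tags={"Modality": "CT", "Manufacturer": "x"}, pixels=np.zeros((2, 2)))]
    group = SeriesGroup(uid="u", frames=frames, source_kind="classic")
    with pytest.raises(AmbiguousDetectionError, match="ct"):
        detect_acquisition(group, reg)


def test_registry_is_extensible_without_touching_existing(all_fixture_dirs):
    """Plugin contract: adding a dummy spec changes no existing detection."""
    reg = default_registry()
    before = {
        v: detect_acquisition(read_dicom_tree(d)[0], reg).suffix
        for v, d in all_fixture_dirs.items()
    }
    dummy = ConverterSpec(
        name="dummy", suffix="seg", modality_folder="seg", specificity=0,
        detect=lambda g: str(g.tags.get("Modality")) == "NEVER",
        required_fields=(), dimensionality=("x", "y", "z"),
        extract=lambda g, v: {},
    )
    register(dummy, reg)
    after = {
        v: detect_acquisition(read_dicom_tree(d)[0], reg).suffix
        for v, d in all_fixture_dirs.items()
    }
    assert before == after


def test_registry_reproduces_standard_rows():
    """(folder, suffix, fields, dimensionality) of each converter match the
    acquisition registry rows; one spec per included convertible suffix."""
    reg = default_registry()
    suffixes = [s.suffix for s in reg]
    assert len(suffixes) == len(set(suffixes))
    for spec in reg:
        info = SUFFIX_REGISTRY[spec.suffix]
        assert info.status == "included"
        assert info.folder == spec.modality_folder
        assert spec.dimensionality == info.dim_labels
    by_suffix = {s.suffix: s for s in reg}
    assert set(by_suffix["ct"].required_fields) == {
        "XRayEnergy", "XRayExposure", "ConvolutionKernel",
        "RescaleIntercept", "RescaleSlope",
    }
    assert set(by_suffix["hrpqct"].required_fields) >= {
        "ScancoMuScaling", "ScancoDensitySlope", "ScancoDensityIntercept", "ScancoMuWater",
    }
    assert set(by_suffix["cr"].required_fields) == {"ExposureTime", "XRayTubeCurrent"}
    assert set(by_suffix["mese"].required_fields) == {"EchoTime", "RefocusingFlipAngle"}
    assert {"EchoTime", "WaterFatShift", "MagneticFieldStrength"} <= set(
        by_suffix["megre"].required_fields
    )
    assert by_suffix["dess"].required_fields == ("PulseSequenceType",)


def test_extract_mese_refocusing_and_echo_array(mese_dir):
    group = read_dicom_tree(mese_dir)[0]
    spec = detect_acquisition(group)
    vol = stack_volume(split_parts(group)["mag"], "mag")
    main = extract_metadata(group, spec, vol)
    assert main["RefocusingFlipAngle"] == 180.0
    assert main["EchoTime"] == [10.0, 20.0, 30.0, 40.0, 50.0]


def test_extract_ct_literal_values(ct_dirs):
    group = read_dicom_tree(ct_dirs["ct"])[0]
    spec = detect_acquisition(group)
    vol = stack_volume(group.frames, "none")
    main = extract_metadata(group, spec, vol)
    assert main["XRayEnergy"] == 120.0
    assert main["XRayExposure"] == 100.0
    assert main["ConvolutionKernel"] == "B30"
    assert main["RescaleSlope"] == 1.0 and main["RescaleIntercept"] == -1024.0


def test_extract_megre_water_fat_shift_closed_form(megre_mag_dir):
    """No vendor water-fat shift: computed as B0 * 42.577 MHz/T * 3.4 ppm
    / pixel bandwidth — checked against an independent hand computation."""
    group = read_dicom_tree(megre_mag_dir)[0]
    spec = detect_acquisition(group)
    vol = stack_volume(group.frames, "mag")
    main = extract_metadata(group, spec, vol)
    expected = 3.0 * 42.577 * 3.4 / 434.0
    assert np.isclose(main["WaterFatShift"], expected, rtol=1e-12)
    assert main["WaterFatShiftSource"] == "computed"
    assert main["MagneticFieldStrength"] == 3.0
    assert main["PixelBandwidth"] == 434.0
    assert GAMMA_MHZ_PER_T == 42.577 and WATER_FAT_PPM == 3.4


def test_extract_missing_required_field_rejects(ct_dirs):
    group = read_dicom_tree(ct_dirs["ct"])[0]
    spec = detect_acquisition(group)
    vol = stack_volume(group.frames, "none")
    for f in group.frames:
        f.tags.pop("ConvolutionKernel", None)
    with pytest.raises(IncompleteMetadataError, match="ConvolutionKernel"):
        extract_metadata(group, spec, vol)


def test_spec_for_suffix_lookup():
    assert spec_for_suffix("megre").name == "megre"
    assert spec_for_suffix("vel") is None
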