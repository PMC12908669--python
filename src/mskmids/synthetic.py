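"""Deterministic vendor-style DICOM generators for every supported acquisition.

These emulate the kinds of input the converter targets — classic single-frame
gradient-echo series (GE-style multi-echo Dixon data), a single enhanced
multi-frame spin-echo file (Philips-style), conventional / photon-counting /
Scanco-style CT, and plain radiography — without copying any real vendor's
private-tag layout. Manufacturer strings carry a ``-style-fixture`` marker so
nothing generated here can be mistaken for real scanner output, while
detection predicates match structural tokens and therefore accept both.

Phantoms are analytic so downstream quantitative checks are possible:

* MEGRE: disk of S0 = 1000 over background 0, mono-exponential T2* = 20 ms
  decay across echoes, Gaussian noise sigma = 2% of S0 (seeded).
* MESE: same disk with T2 = 50 ms.
* CT: water cylinder (~0 HU) with a bone-like insert (~+700 HU).

Every file embeds sentinel identity strings (patient name ``SENTINEL^PHI``,
institution ``SENTINEL-INSTITUTE`` ...) to power anonymization leak tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, MRImageStorage
from pydicom.uid import ComputedRadiographyImageStorage, EnhancedMRImageStorage

from .dicom_reader import (
    SCANCO_FIELDS,
    SCANCO_PRIVATE_GROUP,
)

#: default MEGRE phantom parameters
MEGRE_T2STAR_MS = 20.0
MESE_T2_MS = 50.0
PHANTOM_S0 = 1000.0
NOISE_FRACTION = 0.02

#: sentinel identity values; must never appear in anonymized output
SENTINEL_PHI = {
    "PatientName": "SENTINEL^PHI",
    "PatientID": "SENTINEL-ID-0001",
    "PatientBirthDate": "19700101",
    "PatientSex": "O",
    "InstitutionName": "SENTINEL-INSTITUTE",
    "ReferringPhysicianName": "SENTINEL^DOCTOR",
    "OperatorsName": "SENTINEL^OPERATOR",
    "StationName": "SENTINEL-STATION",
    "DeviceSerialNumber": "SENTINEL-SERIAL-42",
    "AccessionNumber": "SENTINEL-ACC-7",
    "StudyDate": "20240102",
    "StudyTime": "101500",
}

AXIAL = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

_PART_TOKEN = {"mag": "MAGNITUDE", "phase": "PHASE", "real": "REAL", "imag": "IMAGINARY"}

_ROOT_UID = "1.2.826.0.1.3680043.10.1405."


def _uid(seed: int, *counters: int) -> str:
    return _ROOT_UID + ".".join(str(c) for c in (seed % 10**8,) + counters)


def _disk_mask(matrix: tuple[int, int], radius_frac: float = 0.35) -> np.ndarray:
    rows, cols = matrix
    j, i = np.mgrid[0:rows, 0:cols]
    r2 = (j - rows / 2) ** 2 + (i - cols / 2) ** 2
    return r2 <= (min(rows, cols) * radius_frac) ** 2


def _base_dataset(sop_class, seed: int, series: int, instance: int) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = _uid(seed, series, 9000 + instance)
    ds.StudyInstanceUID = _uid(seed, 1)
    ds.SeriesInstanceUID = _uid(seed, series)
    ds.SeriesNumber = series
    ds.InstanceNumber = instance
    for kw, value in SENTINEL_PHI.items():
        setattr(ds, kw, value)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    return ds


def _save(ds: Dataset, path: Path) -> None:
    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    ds.file_meta = meta
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(path, enforce_file_format=True)


def _set_pixels(ds: Dataset, pixels: np.ndarray, signed: bool) -> None:
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelRepresentation = 1 if signed else 0
    ds.PixelData = np.ascontiguousarray(pixels).tobytes()


def _mag_plane(rng, matrix, mask, te_ms, t2_ms) -> np.ndarray:
    signal = PHANTOM_S0 * np.exp(-te_ms / t2_ms) * mask
    noisy = signal + rng.normal(0.0, NOISE_FRACTION * PHANTOM_S0, size=matrix)
    return np.clip(np.rint(noisy), 0, 32767).astype(np.int16)


#: phase rescale slope: maps the stored int range [-4096, 4095] just inside
#: [-pi, pi] so the rescaled values need no further mapping (and the
#: transform inverts exactly on round-trip)
PHASE_SLOPE = 0.000766


def _phase_plane(rng, matrix, mask) -> tuple[np.ndarray, float]:
    """Smooth wrapped-phase ramp, stored as ints with a fixed rescale slope."""
    rows, cols = matrix
    j, i = np.mgrid[0:rows, 0:cols]
    phase = (i / max(cols - 1, 1) * 1.6 - 0.8) * np.pi * mask
    phase += rng.normal(0.0, 0.01, size=matrix) * mask
    stored = np.clip(np.rint(phase / PHASE_SLOPE), -4096, 4095).astype(np.int16)
    return stored, PHASE_SLOPE


def make_megre_classic(
    out_dir,
    n_echoes: int = 3,
    echo_times=(2.4, 4.8, 7.2),
    matrix: tuple[int, int] = (32, 32),
    n_slices: int = 4,
    spacing=(1.0, 1.0, 1.0),
    orientation=AXIAL,
    parts=("mag",),
    field_T: float = 3.0,
    pixel_bandwidth: float = 434.0,
    position=(0.0, 0.0, 0.0),
    seed: int = 0,
) -> Path:
    """Classic (one file per frame) gradient-echo multi-echo series, GE-style.

    One file per (echo, slice, part); ``spacing`` is (row, column, slice) mm.
    Deterministic given ``seed``.
    """
    out_dir = Path(out_dir)
    echo_times = tuple(float(t) for t in echo_times)[:n_echoes]
    assert len(echo_times) == n_echoes, "need one echo time per echo"
    rng = np.random.default_rng(seed)
    mask = _disk_mask(matrix)
    iop = np.asarray(orientation, float)
    normal = np.cross(iop[:3], iop[3:])
    instance = 0
    for part in parts:
        for e, te in enumerate(echo_times):
            for k in range(n_slices):
                instance += 1
                ds = _base_dataset(MRImageStorage, seed, series=11, instance=instance)
                ds.Modality = "MR"
                ds.Manufacturer = "GE-style-fixture"
                ds.ScanningSequence = "GR"
                ds.SequenceVariant = "SS"
                ds.ImageType = ["ORIGINAL", "PRIMARY", _PART_TOKEN[part]]
                ds.EchoTime = te
                ds.RepetitionTime = 30.0
                ds.FlipAngle = 12.0
                ds.MagneticFieldStrength = field_T
                ds.PixelBandwidth = pixel_bandwidth
                ds.PixelSpacing = [spacing[0], spacing[1]]
                ds.SliceThickness = spacing[2]
                ds.ImageOrientationPatient = list(iop)
                ds.ImagePositionPatient = list(
                    np.asarray(position, float) + normal * spacing[2] * k
                )
                if part == "phase":
                    stored, slope = _phase_plane(rng, matrix, mask)
                    ds.RescaleSlope = slope
                    ds.RescaleIntercept = 0.0
                    _set_pixels(ds, stored, signed=True)
                else:
                    _set_pixels(ds, _mag_plane(rng, matrix, mask, te, MEGRE_T2STAR_MS), signed=True)
                _save(ds, out_dir / f"megre-{part}-e{e}-s{k}.dcm")
    return out_dir


def make_mese_enhanced(
    out_dir,
    n_echoes: int = 5,
    echo_times=(10.0, 20.0, 30.0, 40.0, 50.0),
    refocusing_flip_deg: float = 180.0,
    matrix: tuple[int, int] = (32, 32),
    n_slices: int = 3,
    spacing=(1.0, 1.0, 2.0),
    position=(0.0, 0.0, 0.0),
    seed: int = 0,
) -> Path:
    """Single enhanced multi-frame spin-echo file, Philips-style.

    ``n_echoes * n_slices`` frames with per-frame functional groups (echo
    time, plane position) and shared groups carrying the refocusing flip
    angle and geometry. The file advertises ``EchoPulseSequence = SPIN``
    instead of a classic ScanningSequence, as enhanced MR files do.
    """
    out_dir = Path(out_dir)
    echo_times = tuple(float(t) for t in echo_times)[:n_echoes]
    assert len(echo_times) == n_echoes, "need one echo time per echo"
    rng = np.random.default_rng(seed + 1)
    mask = _disk_mask(matrix)

    ds = _base_dataset(EnhancedMRImageStorage, seed, series=21, instance=1)
    ds.Modality = "MR"
    ds.Manufacturer = "Philips-style-fixture"
    ds.EchoPulseSequence = "SPIN"
    ds.MagneticFieldStrength = 3.0
    ds.NumberOfFrames = n_echoes * n_slices

    shared = Dataset()
    timing = Dataset()
    timing.RepetitionTime = 3000.0
    timing.FlipAngle = refocusing_flip_deg
    shared.MRTimingAndRelatedParametersSequence = [timing]
    measures = Dataset()
    measures.PixelSpacing = [spacing[0], spacing[1]]
    measures.SliceThickness = spacing[2]
    shared.PixelMeasuresSequence = [measures]
    orient = Dataset()
    orient.ImageOrientationPatient = list(AXIAL)
    shared.PlaneOrientationSequence = [orient]
    ds.SharedFunctionalGroupsSequence = [shared]

    per_frame = []
    planes = []
    # frame order: echo-major (all slices of echo 1, then echo 2, ...)
    for e, te in enumerate(echo_times):
        for k in range(n_slices):
            fg = Dataset()
            pos = Dataset()
            pos.ImagePositionPatient = list(
                np.asarray(position, float) + np.array([0.0, 0.0, spacing[2] * k])
            )
            fg.PlanePositionSequence = [pos]
            echo = Dataset()
            echo.EffectiveEchoTime = te
            fg.MREchoSequence = [echo]
            ftype = Dataset()
            ftype.FrameType = ["ORIGINAL", "PRIMARY", "MAGNITUDE"]
            fg.MRImageFrameTypeSequence = [ftype]
            per_frame.append(fg)
            planes.append(_mag_plane(rng, matrix, mask, te, MESE_T2_MS))
    ds.PerFrameFunctionalGroupsSequence = per_frame
    _set_pixels(ds, planes[0], signed=True)  # sets Rows/Columns
    ds.PixelData = np.ascontiguousarray(np.stack(planes)).tobytes()
    _save(ds, out_dir / "mese-enhanced.dcm")
    return out_dir


def make_ct_series(
    out_dir,
    variant: str = "ct",
    kvp: float = 120.0,
    exposure_mAs: float = 100.0,
    kernel: str = "B30",
    slope: float = 1.0,
    intercept: float = -1024.0,
    scanco_fields: dict | None = None,
    matrix: tuple[int, int] = (32, 32),
    n_slices: int = 10,
    spacing=(0.8, 0.8, 1.0),
    seed: int = 0,
) -> Path:
    """Classic CT series: water cylinder (~0 HU) with bone insert (~+700 HU).

    ``variant`` selects conventional (``ct``), photon-counting (``pcct``,
    detector-type token set) or Scanco-style HR-pQCT (``hrpqct``,
    manufacturer token + four density-calibration private fields).
    """
    if variant not in ("ct", "pcct", "hrpqct"):
        raise ValueError(f"unknown CT variant {variant!r}")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed + 2)
    rows, cols = matrix
    water = _disk_mask(matrix, 0.4)
    bone = _disk_mask(matrix, 0.12)
    hu = np.full(matrix, -1000.0)
    hu[water] = 0.0
    hu[bone] = 700.0
    if scanco_fields is None and variant == "hrpqct":
        scanco_fields = {
            "ScancoMuScaling": 8192.0,
            "ScancoDensitySlope": 1657.0,
            "ScancoDensityIntercept": -393.0,
            "ScancoMuWater": 0.2409,
        }
    series_number = {"ct": 31, "pcct": 32, "hrpqct": 33}[variant]
    for k in range(n_slices):
        ds = _base_dataset(CTImageStorage, seed, series=series_number, instance=k + 1)
        ds.Modality = "CT"
        ds.Manufacturer = (
            "SCANCO-style-fixture" if variant == "hrpqct" else "CT-style-fixture"
        )
        if variant == "pcct":
            ds.DetectorType = "PHOTON_COUNTING"
        ds.KVP = kvp
        ds.Exposure = int(round(exposure_mAs))  # (0018,1152) is an integer string
        ds.ConvolutionKernel = kernel
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelSpacing = [spacing[0], spacing[1]]
        ds.SliceThickness = spacing[2]
        ds.ImageOrientationPatient = list(AXIAL)
        ds.ImagePositionPatient = [0.0, 0.0, spacing[2] * k]
        if variant == "hrpqct":
            block = ds.private_block(SCANCO_PRIVATE_GROUP, "SCANCO", create=True)
            for offset, name in SCANCO_FIELDS.items():
                block.add_new(offset, "DS", str(scanco_fields[name]))
        noisy = hu + rng.normal(0.0, 5.0, size=matrix)
        stored = np.rint((noisy - intercept) / slope)
        _set_pixels(ds, np.clip(stored, -32768, 32767).astype(np.int16), signed=True)
        _save(ds, out_dir / f"{variant}-s{k:03d}.dcm")
    return out_dir


def make_cr_image(
    out_dir,
    exposure_time_ms: float = 10.0,
    tube_current_mA: float = 100.0,
    matrix: tuple[int, int] = (64, 64),
    spacing=(0.14, 0.14),
    seed: int = 0,
) -> Path:
    """Single 2D plain-radiography file (projection image, no patient frame)."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed + 3)
    rows, cols = matrix
    j, i = np.mgrid[0:rows, 0:cols]
    bone = (np.abs(i - cols / 2) < cols * 0.12).astype(float)
    image = 400.0 + 1200.0 * bone + rng.normal(0.0, 30.0, size=matrix)
    ds = _base_dataset(ComputedRadiographyImageStorage, seed, series=41, instance=1)
    ds.Modality = "CR"
    ds.Manufacturer = "CR-style-fixture"
    # both are DICOM integer strings
    ds.ExposureTime = int(round(exposure_time_ms))
    ds.XRayTubeCurrent = int(round(tube_current_mA))
    ds.ImagerPixelSpacing = [spacing[0], spacing[1]]
    _set_pixels(ds, np.clip(np.rint(image), 0, 32767).astype(np.int16), signed=True)
    _save(ds, out_dir / "cr.dcm")
    return out_dir


FIXTURE_MAKERS = {
    "megre": make_megre_classic,
    "mese": make_mese_enhanced,
    "ct": lambda out, seed=0: make_ct_series(out, variant="ct", seed=seed),
    "pcct": lambda out, seed=0: make_ct_series(out, variant="pcct", seed=seed),
    "hrpqct": lambda out, seed=0: make_ct_series(out, variant="hrpqct", seed=seed),
    "cr": make_cr_image,
}


def make_fixture(variant: str, out_dir, seed: int = 0) -> Path:
    """Dispatch one fixture variant with defaults."""
    try:
        maker = FIXTURE_MAKERS[variant]
    except KeyError:
        raise ValueError(
            f"unknown fixture variant {variant!r}; choose from {sorted(FIXTURE_MAKERS)}"
        ) from None
    return maker(out_dir, seed=seed)


__all__ = [
    "make_megre_classic",
    "make_mese_enhanced",
    "make_ct_series",
    "make_cr_image",
    "make_fixture",
    "FIXTURE_MAKERS",
    "SENTINEL_PHI",
    "MEGRE_T2STAR_MS",
    "MESE_T2_MS",
    "PHANTOM_S0",
    "NOISE_FRACTION",
]
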