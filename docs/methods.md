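# Methods

## Scope and model

`mskmids` implements a BIDS/MIDS-style data standard for musculoskeletal
imaging: DICOM acquisitions are converted into per-subject modality folders
(`ct`, `cr`, `mr-anat`, `mr-quant`, with `us` and `seg` reserved) holding
gzipped NIfTI volumes plus up to three JSON sidecars, a `participants.tsv`
table at the root, and an optional `derivatives/` subtree mirroring the
subject/session structure for processed outputs. The package covers the
full life cycle: conversion, loading, validation, anonymization, and
reconstruction of the original DICOM from the stored full header.

Supported acquisitions and their contracts:

| suffix | folder | volume | required sidecar fields |
|---|---|---|---|
| ct, pcct | ct | 3D | XRayEnergy [kVp], XRayExposure [mAs], ConvolutionKernel, RescaleIntercept, RescaleSlope |
| hrpqct | ct | 3D | the ct fields + ScancoMuScaling, ScancoDensitySlope, ScancoDensityIntercept, ScancoMuWater |
| cr | cr | 2D | ExposureTime [ms], XRayTubeCurrent [mA] |
| megre | mr-anat | 4D (x,y,z,echo) | EchoTime (array, ms), WaterFatShift [px], MagneticFieldStrength [T], PixelBandwidth [Hz/px] |
| mese | mr-anat | 4D (x,y,z,echo) | EchoTime (array, ms), RefocusingFlipAngle [deg] |
| dess, dess-fid, dess_echo | mr-anat | 3D | PulseSequenceType = "DESS" |
| t1, t2, wt2 | mr-quant | 3D | — (derived maps) |
| vel, diff, seg, us | — | — | reserved: parsed and flagged, no converter |

The radiography row has no canonical suffix in the source registry; `cr`
is used because the filename grammar requires one. The printed field name
"X-RayTubeCurrent" is emitted as `XRayTubeCurrent` to keep sidecar keys in
CamelCase alphanumeric form. `dess_echo` is registered verbatim even
though it contains the entity separator; filenames are parsed by
longest-match against the suffix registry before entity tokenization, so
the inconsistency with `dess-fid` is preserved rather than silently
normalized.

## Filename grammar

Entities follow BIDS: `sub-<label>[/ses-<label>]/<folder>/`
`sub-<label>[_ses-<label>][_part-<part>]_<suffix><ext>`, labels strictly
alphanumeric. The parser accepts unknown suffixes (flagged, not rejected)
and foreign BIDS entities (`acq-`, `run-`) for forward compatibility but
never emits them. Sessions are supported but never invented: the converter
writes the session level only when the caller supplies a session label.
Sidecar names are `<base>.json`, `<base>_patient.json`,
`<base>_extra.json` — suffix-based naming keeps the three headers adjacent
and unambiguous.

## DICOM reading and geometry

Classic single-frame files are grouped by series UID; enhanced multi-frame
files are exploded into per-frame records, with per-frame functional-group
values (effective echo time, plane position, frame type, rescale)
overriding shared ones. Both encodings normalize to the same record list,
so assembly and detection are encoding-agnostic.

The voxel index convention is `(i, j, k)` = (column, row, slice). The
affine is built in DICOM LPS coordinates — in-plane axes from the
orientation cosines scaled by pixel spacing, through-plane axis from the
inter-slice displacement (or normal x slice thickness for a single slice),
origin at the first slice's position — then converted to RAS by negating
the first two rows. Voxel data are never flipped; the transform is
lossless, which is what makes the DICOM round-trip exact. Slices are
ordered by projecting the image position onto the slice normal, with
instance number breaking ties.

Numerical tolerances (pinned by tests): orientation consistency 1e-3 per
cosine; slice-gap uniformity ratio 1.01 (irregular gaps are rejected, not
resampled); echo-time grouping 1e-3 ms. Projection images (radiography)
have no patient frame; their affine encodes detector pixel spacing only.

## Assembly and complex parts

Frames are partitioned by the complex-part token of the image type
(`MAGNITUDE`/`PHASE`/`REAL`/`IMAGINARY`, or the single-letter vendor
forms); CT/CR frames carry part `none`. Echoes stack on the 4th axis in
ascending echo-time order, matching the `EchoTime` array. Phase data are
converted to radians: the rescale transform is applied first and, only if
the result exceeds [-pi, pi], values are mapped linearly so the data
maximum lands on +pi and minimum on -pi. Vendors encode phase ranges
inconsistently and no header field settles it; the heuristic is explicit
and a converter plugin can override it. Stored data with identity rescale
remain int16 on disk; anything rescaled becomes float32.

## Detection and extraction

Detection walks the registry most-specific-first (Scanco-manufacturer and
photon-counting-detector predicates before generic CT; sequence-token DESS
and map-token detection before the generic multi-echo predicates) and
takes the first match; two matches within a tier raise an ambiguity error.
Sequence identification checks `ScanningSequence` first, then
`EchoPulseSequence`, then sequence-name fields, because vendors store the
same information in different attributes. A gradient-echo series needs >= 2
distinct echo times and no inversion-recovery token to be multi-echo
gradient echo; a spin-echo series >= 2 echo times. Water-T2 maps carry no
dedicated DICOM tag, so they are detected from a configurable
series-description token.

Two extraction conventions deserve note. No standard DICOM attribute holds
the refocusing flip angle, so a dedicated tag is honored when present and
otherwise the flip angle of a spin-echo acquisition is taken as the
refocusing angle (for enhanced files, from the shared MR timing group).
`WaterFatShift` in pixels is read from an explicit vendor tag when
available, else computed as B0 x 42.577 MHz/T x 3.4 ppm / PixelBandwidth;
the sidecar records a `WaterFatShiftSource` provenance key
(`vendor`/`computed`).

Any required field that cannot be obtained rejects the series: the output
is guaranteed to contain all and only the required fields, which is also
what makes anonymity-by-exclusion sound.

## Anonymization

`PATIENT_FIELDS` is a frozen list of identifying attributes (demographics,
institution and physician names, device/station identifiers, study dates
and times, comment fields), seeded from the DICOM basic confidentiality
profile. These never enter the main sidecar; they populate the removable
`_patient.json`. In anonymize mode the patient sidecar is not written
*and* the same tags are removed (not blanked) from the extra sidecar,
since the full header would otherwise re-leak identity. The extra sidecar
is DICOM-JSON (PS3.18) via pydicom, lossless for private tags and binary
values, pixel data excluded.

## Round-trip

Reconstruction restores every stored tag verbatim, regenerates pixel data
by inverting the rescale transform with rounding to the nearest stored
integer, and mints fresh SOP instance UIDs (so re-imported files cannot
collide with originals in a PACS) while keeping study/series UIDs.
Round-trip is bit-exact for unmodified integer volumes; float-valued
derived volumes would be quantized and are documented as approximate. A
single part of a multi-part *enhanced* file cannot be rebuilt alone (the
stored multi-frame header covers all parts); classic series store per-part
frame lists and round-trip independently.

## Synthetic data generator

The generator emulates the kinds of test data the converter targets:
classic single-frame GE-style MEGRE series (default 3 echoes at
2.4/4.8/7.2 ms x 4 slices, magnitude and optionally phase/real/imaginary
parts, 3 T, 434 Hz/px), a single enhanced multi-frame Philips-style MESE
file (5 echoes at 10–50 ms x 3 slices, refocusing flip 180 deg),
conventional / photon-counting / Scanco-style CT (120 kVp, 100 mAs, kernel
"B30", rescale 1/-1024), and one 2-D radiograph (10 ms, 100 mA). Phantoms
are analytic: a disk of S0 = 1000 decaying mono-exponentially with
T2\* = 20 ms (MEGRE) or T2 = 50 ms (MESE) over zero background with seeded
Gaussian noise of sigma = 2% of S0 — small enough that a log-linear fit
over the disk mean recovers the relaxation time to well within 10%, large
enough that images are not noise-free; CT uses a water cylinder (~0 HU)
with a bone-like insert (+700 HU). Matrix sizes default to 32 x 32 so the
whole suite runs in seconds.

Fixtures are vendor-*style*, not forgeries: manufacturer strings read
`GE-style-fixture`, `SCANCO-style-fixture`, etc., and detection matches
structural tokens, so both fixtures and real data pass the same
predicates. Scanco calibration values live in a private block with creator
`"SCANCO"`; phase uses a rescale slope of 7.66e-4 mapping the stored
integer range just inside [-pi, pi] so phase conversion is the identity
and round-trips exactly. Every file embeds sentinel identity strings
(`SENTINEL^PHI`, `SENTINEL-INSTITUTE`, ...) to power byte-level leak
tests.

What the fixtures do **not** emulate: compressed transfer syntaxes, real
vendor private-tag layouts beyond the fields read here, gantry-tilted or
irregularly spaced geometries, k-space artifacts, multi-study archives.
Passing tests therefore demonstrate the correctness of the conversion
logic and format contracts, not robustness to every real-world DICOM
pathology.

## Validation

Checks V1–V8 (grammar, folder pairing, required fields and JSON types,
dimensionality, echo-axis consistency, identity keys in the main sidecar,
participants coverage, reserved suffixes) each carry a stable code; the
tree is compliant iff no error-severity issue exists. Unexpected extra
keys in a main sidecar are warnings — forward-compatible additions should
not break validation — and `strict=True` upgrades warnings to errors.
Because the validator and converter share one registry, converter output
validating cleanly is structural, not coincidental. Files under
`derivatives/` are checked for grammar only; derived content is
user-defined. A missing extra sidecar is compliant (the header is
optional); it only forecloses DICOM reconstruction.

## Design choices made where the design was open

- NIfTI-1, gzipped, sform and qform both set with sform authoritative;
  int16 preserved when no rescale was applied, float32 otherwise.
- JSON sidecars are UTF-8, 2-space indented, keys in registry order, for
  stable diffs under version control.
- DESS double echoes are emitted as separate 3-D volumes per suffix
  (`dess-fid`, `dess_echo`) rather than one 4-D file, matching the 3-D
  contract of those rows.
- Echo axis order is ascending echo time; nothing in the source headers
  mandates an order, and ascending matches the `EchoTime` array naturally.
- The subject label is caller-supplied, never derived from the patient
  name, so anonymized filenames cannot leak identity.

## Known limitations

- Compressed DICOM transfer syntaxes, DICOM networking, and DICOMDIR are
  out of scope; little-endian uncompressed Part-10 files only.
- Velocity, diffusion, segmentation and ultrasound data are recognized as
  reserved suffixes but have no converters.
- Irregular slice spacing is rejected rather than resampled.
- Photon-counting detection relies on the detector-type attribute; no
  single tag is authoritative across vendors.
- Float-valued (derived) volumes round-trip to DICOM only approximately.

## Problem sizes

Tests and the acceptance script run on 32 x 32 matrices with 3–10 slices
and 1–5 echoes per series — the package's chosen fixture scale, at which
the full suite plus the acceptance run completes in under a minute while
still exercising 4-D assembly, all five orientations of the geometry
oracle, and every converter.
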