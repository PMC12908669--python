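# mskmids

Curation tools for musculoskeletal (MSK) imaging research data.

Quantitative MSK imaging spans MRI, CT and plain radiography, acquired on
scanners from many vendors that each encode metadata differently within
DICOM. Pooling such data across centers — for multi-echo T2/T2\* relaxometry
of muscle and cartilage, Dixon fat–water imaging, or HR-pQCT bone
microarchitecture — requires a single source-agnostic layout that
downstream pipelines can rely on. `mskmids` converts DICOM acquisitions
into a BIDS/MIDS-style dataset tree and back, for researchers who curate,
share, and process MSK imaging studies.

## The data model

Each converted acquisition becomes one gzipped NIfTI volume named by
BIDS-style entities inside a per-modality folder,

```
sub-01/[ses-a/]mr-anat/sub-01[_ses-a][_part-mag]_megre.nii.gz
```

with up to **three JSON sidecars** sharing its basename:

1. `*.json` — the minimal interpretive header: all and only the fields the
   acquisition requires (e.g. `EchoTime` array in ms and
   `RefocusingFlipAngle` in degrees for multi-echo spin echo;
   `XRayEnergy`/`XRayExposure`/`ConvolutionKernel`/rescale for CT, plus the
   four Scanco density-calibration fields for HR-pQCT);
2. `*_patient.json` — every potentially identifying attribute (patient
   demographics, institution, dates, device serials). Anonymization is
   deleting one file, or converting with `--anonymize`;
3. `*_extra.json` — the complete original DICOM header (DICOM-JSON,
   PS3.18), enabling lossless reconstruction of the source series.

Multi-echo MR is stored as a single 4-D volume `(x, y, z, echo)` with echoes
in ascending echo-time order, one file per complex part
(`part-mag`/`part-phase`/`part-real`/`part-imag`, phase in radians in
[-pi, pi]). CT is 3-D, radiography 2-D. The NIfTI sform/qform hold the RAS
voxel-to-patient affine derived from the DICOM (LPS) geometry.

Conversion is *strict by construction*: a plugin registry of converters
recognizes supported acquisitions from structural header tokens (modality,
scanning sequence, echo count, manufacturer/detector tokens) and everything
unrecognized is skipped, never force-converted — so emitted sidecars are
guaranteed compliant and free-text identifying fields cannot slip through.
A validator (codes V1–V8: grammar, folder pairing, required fields,
dimensionality, echo-count consistency, identity leakage, participants
table, reserved suffixes) checks existing trees.

## Worked example

Generate a deterministic two-series study (classic GE-style multi-echo
gradient echo + one enhanced Philips-style multi-echo spin-echo file),
convert, inspect, and validate it:

```console
$ mskmids make-fixtures --variant megre --out dicom/megre --seed 1
wrote 12 file(s) to dicom/megre
$ mskmids make-fixtures --variant mese --out dicom/mese --seed 1
wrote 1 file(s) to dicom/mese
$ mskmids convert dicom study --subject 01
series 1.2.826.0.1.3680043.10.1405.1.11: converted as megre (4 files)
series 1.2.826.0.1.3680043.10.1405.1.21: converted as mese (4 files)
$ mskmids inspect study
sub-01 mr-anat/megre part-mag: shape=(32, 32, 4, 3) echoes=[2.4, 4.8, 7.2]
sub-01 mr-anat/mese part-mag: shape=(32, 32, 3, 5) echoes=[10.0, 20.0, 30.0, 40.0, 50.0]
$ mskmids validate study
0 error(s), 0 warning(s)
```

The 12 classic files (3 echoes x 4 slices) became one 4-D volume whose 4th
axis is echo time; the enhanced file's 15 frames became a 5-echo volume.
The main sidecar of the gradient-echo series reads:

```json
{
  "EchoTime": [2.4, 4.8, 7.2],
  "WaterFatShift": 1.000657603686636,
  "WaterFatShiftSource": "computed",
  "MagneticFieldStrength": 3.0,
  "PixelBandwidth": 434.0
}
```

`WaterFatShift` (in pixels) was not provided by the source header, so it
was computed from field strength and pixel bandwidth
(3 T x 42.577 MHz/T x 3.4 ppm / 434 Hz/px ~= 1.0007 px) and flagged as
such. From Python the same tree loads back as NumPy arrays:

```python
from mskmids import EntityKey, load_dataset, load_volume

index = load_dataset("study")
key = EntityKey(subject="01", part="mag", suffix="megre", modality_folder="mr-anat")
volume, sidecars = load_volume(index, key)
volume.voxels.shape   # (32, 32, 4, 3)
sidecars.main["EchoTime"]  # [2.4, 4.8, 7.2]
```

and `mskmids roundtrip study out --subject 01 --suffix megre --part mag`
rebuilds the 12 original DICOM files, pixel-for-pixel, from the volume and
its `_extra.json`.

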