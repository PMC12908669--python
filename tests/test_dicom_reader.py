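"""DICOM loading, enhanced-file explosion, and patient-space geometry."""

import numpy as np
import pydicom
import pytest

from mskmids.dicom_reader import (
    FrameRecord,
    apply_rescale,
    compute_affine,
    explode_enhanced,
    read_dicom_tree,
    sort_slices,
)
from mskmids.errors import (
    DegenerateGeometryError,
    EmptyInputError,
    GeometryError,
    InvalidRescaleError,
    NonUniformSpacingError,
)
from mskmids.synthetic import make_megre_classic, make_mese_enhanced


def _rotation(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.deg2rad(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


#: >= 5 orientations including obliques, as (row cosines, column cosines)
ORIENTATIONS = [
    ((1, 0, 0), (0, 1, 0)),  # axial
    ((0, 1, 0), (0, 0, -1)),  # sagittal
    ((1, 0, 0), (0, 0, -1)),  # coronal
    (tuple(_rotation((0, 0, 1), 30) @ (1, 0, 0)), tuple(_rotation((0, 0, 1), 30) @ (0, 1, 0))),
    (
        tuple(_rotation((1, 1, 0), 20) @ _rotation((0, 0, 1), 45) @ (1, 0, 0)),
        tuple(_rotation((1, 1, 0), 20) @ _rotation((0, 0, 1), 45) @ (0, 1, 0)),
    ),
]


def _frames(orientation, n_slices=4, spacing=(1.2, 0.7, 2.0), origin=(5.0, -3.0, 10.0)):
    """Synthetic frame records with known geometry (no files involved)."""
    row, col = (np.asarray(v, float) for v in orientation)
    normal = np.cross(row, col)
    frames = []
    for k in range(n_slices):
        pos = np.asarray(origin) + normal * spacing[2] * k
        frames.append(
            FrameRecord(
                tags={
                    "ImageOrientationPatient": list(row) + list(col),
                    "ImagePositionPatient": list(pos),
                    "PixelSpacing": [spacing[0], spacing[1]],
                    "SliceThickness": spacing[2],
                    "InstanceNumber": k + 1,
                },
                pixels=np.zeros((8, 8), dtype=np.int16),
            )
        )
    return frames


@pytest.mark.parametrize("orientation", ORIENTATIONS, ids=["axial", "sagittal", "coronal", "oblique-z30", "oblique-double"])
def test_affine_reproduces_frame_positions(orientation):
    """Oracle: affine.(i,j,k) equals the DICOM mapping P = IPP_k + i*dc*r + j*dr*c
    (converted LPS->RAS) for every corner voxel of every frame, within 1e-6 mm."""
    spacing = (1.2, 0.7, 2.0)
    frames = _frames(orientation, spacing=spacing)
    affine = compute_affine(frames)
    row, col = (np.asarray(v, float) for v in orientation)
    flip = np.array([-1.0, -1.0, 1.0])
    for k, f in enumerate(frames):
        ipp = np.asarray(f.tags["ImagePositionPatient"], float)
        for i, j in [(0, 0), (7, 0), (0, 7), (7, 7), (3, 5)]:
            expected_lps = ipp + row * spacing[1] * i + col * spacing[0] * j
            got = affine.apply([i, j, k])
            assert np.allclose(got, expected_lps * flip, atol=1e-6)


def test_affine_axial_identity_case():
    frames = _frames(((1, 0, 0), (0, 1, 0)), spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0))
    affine = compute_affine(frames)
    assert np.allclose(affine.matrix[:3, :3], np.diag([-1.0, -1.0, 1.0]))
    assert np.allclose(affine.matrix[:3, 3], 0)


def test_affine_reversed_slice_order_negates_through_plane_axis():
    frames = _frames(ORIENTATIONS[0])
    fwd = compute_affine(frames)
    rev = compute_affine(frames[::-1])
    assert np.allclose(rev.matrix[:3, 2], -fwd.matrix[:3, 2])
    # same voxel-to-patient mapping after reindexing k -> n-1-k
    n = len(frames) - 1
    assert np.allclose(fwd.apply([2, 3, 1]), rev.apply([2, 3, n - 1]))


def test_affine_input_order_invariance():
    """Sorting is internal: shuffled frame enumeration gives the same affine."""
    frames = _frames(ORIENTATIONS[4])
    rng = np.random.default_rng(3)
    shuffled = [frames[i] for i in rng.permutation(len(frames))]
    a = compute_affine(sort_slices(frames)).matrix
    b = compute_affine(sort_slices(shuffled)).matrix
    assert np.array_equal(a, b)


def test_affine_rejects_irregular_spacing():
    frames = _frames(ORIENTATIONS[0])
    pos = np.asarray(frames[2].tags["ImagePositionPatient"])
    frames[2].tags["ImagePositionPatient"] = list(pos + [0, 0, 0.5])
    with pytest.raises(NonUniformSpacingError):
        compute_affine(frames)


def test_affine_single_slice_requires_thickness():
    frame = _frames(ORIENTATIONS[0], n_slices=1)[0]
    del frame.tags["SliceThickness"]
    with pytest.raises(DegenerateGeometryError):
        compute_affine([frame])


def test_affine_rejects_inconsistent_orientation():
    frames = _frames(ORIENTATIONS[0])
    frames[1].tags["ImageOrientationPatient"] = list(
        np.asarray(frames[1].tags["ImageOrientationPatient"]) + 0.01
    )
    with pytest.raises(GeometryError):
        compute_affine(frames)


def test_apply_rescale_hounsfield_and_oracle():
    assert apply_rescale(np.array([1024]), 1, -1024)[0] == 0
    assert apply_rescale(np.array([0]), 3.5, -7.0)[0] == -7.0
    rng = np.random.default_rng(0)
    stored = rng.integers(-32768, 32767, size=(16, 16), dtype=np.int16)
    out = apply_rescale(stored, 0.5, -10.0)
    expected = np.array([[0.5 * v - 10.0 for v in r] for r in stored])
    assert np.allclose(out, expected)
    with pytest.raises(InvalidRescaleError):
        apply_rescale(stored, 0.0, 0.0)


def test_read_tree_classic_counts(megre_mag_dir):
    groups = read_dicom_tree(megre_mag_dir)
    assert len(groups) == 1
    assert groups[0].source_kind == "classic"
    assert len(groups[0].frames) == 12  # 3 echoes x 4 slices
    assert groups[0].distinct_echo_times() == [2.4, 4.8, 7.2]


def test_read_tree_empty_directory(tmp_path):
    with pytest.raises(EmptyInputError):
        read_dicom_tree(tmp_path)


def test_read_tree_skips_non_dicom(megre_mag_dir, tmp_path):
    import shutil

    shutil.copytree(megre_mag_dir, tmp_path / "data")
    (tmp_path / "data" / "README.txt").write_text("not a dicom")
    groups = read_dicom_tree(tmp_path / "data")
    assert len(groups) == 1 and len(groups[0].frames) == 12


def test_read_tree_mixed_classic_and_enhanced(megre_mag_dir, mese_dir, tmp_path):
    import shutil

    shutil.copytree(megre_mag_dir, tmp_path / "d" / "megre")
    shutil.copytree(mese_dir, tmp_path / "d" / "mese")
    groups = read_dicom_tree(tmp_path / "d")
    assert len(groups) == 2
    assert {g.source_kind for g in groups} == {"classic", "enhanced"}


def test_explode_enhanced_counts_and_echoes(mese_dir):
    (path,) = list(mese_dir.glob("*.dcm"))
    group = explode_enhanced(pydicom.dcmread(path))
    assert len(group.frames) == 15  # 5 echoes x 3 slices
    assert group.distinct_echo_times() == [10.0, 20.0, 30.0, 40.0, 50.0]
    # per-frame overrides: echo times appear on records in frame order
    per_frame_tes = [f.tags["EchoTime"] for f in group.frames]
    assert per_frame_tes[:3] == [10.0, 10.0, 10.0]
    assert per_frame_tes[-1] == 50.0
    # shared values propagated to every frame
    assert all(f.tags["FlipAngle"] == 180.0 for f in group.frames)


def test_classic_and_enhanced_encodings_equivalent(mese_dir, tmp_path):
    """The same acquisition encoded classic (one file per frame) and enhanced
    (one multi-frame file) yields identical frame lists up to source_kind."""
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage

    (path,) = list(mese_dir.glob("*.dcm"))
    enhanced = explode_enhanced(pydicom.dcmread(path))
    # re-encode every exploded frame as a classic single-frame file
    for i, f in enumerate(enhanced.frames):
        ds = Dataset()
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = f"1.2.3.{i}"
        ds.SeriesInstanceUID = "1.2.3"
        ds.Modality = "MR"
        ds.Manufacturer = f.tags["Manufacturer"]
        ds.EchoTime = f.tags["EchoTime"]
        ds.ImagePositionPatient = list(f.tags["ImagePositionPatient"])
        ds.ImageOrientationPatient = list(f.tags["ImageOrientationPatient"])
        ds.PixelSpacing = list(f.tags["PixelSpacing"])
        ds.SliceThickness = f.tags["SliceThickness"]
        ds.InstanceNumber = i + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.Rows, ds.Columns = f.pixels.shape
        ds.PixelData = np.ascontiguousarray(f.pixels).tobytes()
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.file_meta = meta
        ds.save_as(tmp_path / f"f{i:03d}.dcm", enforce_file_format=True)
    classic = read_dicom_tree(tmp_path)[0]
    assert classic.source_kind == "classic" and enhanced.source_kind == "enhanced"
    assert len(classic.frames) == len(enhanced.frames)
    for a, b in zip(classic.frames, enhanced.frames):
        assert float(a.tags["EchoTime"]) == float(b.tags["EchoTime"])
        assert np.allclose(
            np.asarray(a.tags["ImagePositionPatient"], float),
            np.asarray(b.tags["ImagePositionPatient"], float),
        )
        assert np.array_equal(a.pixels, b.pixels)
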