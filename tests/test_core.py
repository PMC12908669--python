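"""Filename grammar and domain-type invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mskmids.core import (
    EntityKey,
    ImageVolume,
    MR_SUFFIXES,
    PARTS,
    RESERVED_SUFFIXES,
    SUFFIX_REGISTRY,
    compose_filename,
    parse_filename,
)
from mskmids.errors import FilenameError, PairingError


def all_valid_keys():
    """Exhaustive product: every suffix x {with,without session} x parts."""
    keys = []
    for suffix, info in SUFFIX_REGISTRY.items():
        parts = (None,) + PARTS if suffix in MR_SUFFIXES else (None,)
        for session, part in itertools.product((None, "a"), parts):
            keys.append(
                EntityKey(
                    subject="01",
                    session=session,
                    part=part,
                    suffix=suffix,
                    modality_folder=info.folder,
                )
            )
    return keys


def test_compose_megre_mag_path():
    key = EntityKey(subject="01", part="mag", suffix="megre", modality_folder="mr-anat")
    assert compose_filename(key, ".nii.gz") == "sub-01/mr-anat/sub-01_part-mag_megre.nii.gz"


def test_compose_ct_sidecar_path():
    key = EntityKey(subject="01", suffix="ct", modality_folder="ct")
    assert compose_filename(key, ".json") == "sub-01/ct/sub-01_ct.json"


def test_compose_session_level():
    key = EntityKey(subject="01", session="a", suffix="ct", modality_folder="ct")
    assert compose_filename(key, ".nii.gz") == "sub-01/ses-a/ct/sub-01_ses-a_ct.nii.gz"


@pytest.mark.parametrize("key", all_valid_keys(), ids=str)
@pytest.mark.parametrize("ext", [".nii.gz", ".json", "_patient.json", "_extra.json"])
def test_compose_parse_involution(key, ext):
    """parse(compose(k)) == k over the full entity product, all extensions."""
    parsed, parsed_ext = parse_filename(compose_filename(key, ext))
    assert parsed == key
    assert parsed_ext == ext


@settings(derandomize=True, max_examples=200)
@given(
    subject=st.text(alphabet="abc012", min_size=1, max_size=4),
    session=st.one_of(st.none(), st.text(alphabet="xy9", min_size=1, max_size=3)),
    part=st.sampled_from((None,) + PARTS),
    suffix=st.sampled_from(sorted(SUFFIX_REGISTRY)),
)
def test_compose_parse_involution_random_labels(subject, session, part, suffix):
    if part is not None and suffix not in MR_SUFFIXES:
        part = None
    key = EntityKey(
        subject=subject,
        session=session,
        part=part,
        suffix=suffix,
        modality_folder=SUFFIX_REGISTRY[suffix].folder,
    )
    parsed, _ = parse_filename(compose_filename(key, ".nii.gz"))
    assert parsed == key


def test_parse_part_phase_mese():
    key, ext = parse_filename("sub-01/mr-anat/sub-01_part-phase_mese.nii.gz")
    assert (key.subject, key.session, key.part, key.suffix, key.modality_folder) == (
        "01",
        None,
        "phase",
        "mese",
        "mr-anat",
    )


def test_parse_session_entity():
    key, _ = parse_filename("sub-01/ses-a/ct/sub-01_ses-a_ct.nii.gz")
    assert key.session == "a"


def test_parse_recompose_identity():
    path = "sub-01/mr-anat/sub-01_megre.nii.gz"
    key, ext = parse_filename(path)
    assert compose_filename(key, ext) == path


def test_dess_underscore_suffix_longest_match():
    """dess_echo contains the entity separator; longest-match wins."""
    key = EntityKey(subject="01", suffix="dess_echo", modality_folder="mr-anat")
    path = compose_filename(key, ".nii.gz")
    parsed, _ = parse_filename(path)
    assert parsed.suffix == "dess_echo"
    assert parsed.recognized


def test_unknown_suffix_flagged_not_rejected():
    key, _ = parse_filename("sub-01/mr-anat/sub-01_mystery.nii.gz")
    assert key.suffix == "mystery"
    assert not key.recognized


def test_reserved_suffixes_parse_with_marker():
    for suffix in ("vel", "diff", "seg"):
        folder = SUFFIX_REGISTRY[suffix].folder
        key, _ = parse_filename(f"sub-01/{folder}/sub-01_{suffix}.nii.gz")
        assert key.recognized and key.reserved


def test_invalid_pairing_names_both_values():
    key = EntityKey(subject="01", suffix="megre", modality_folder="ct")
    with pytest.raises(PairingError, match="megre.*ct|ct.*megre"):
        compose_filename(key, ".nii.gz")


def test_part_invalid_outside_mr():
    key = EntityKey(subject="01", part="mag", suffix="ct", modality_folder="ct")
    with pytest.raises(PairingError):
        compose_filename(key, ".nii.gz")


@pytest.mark.parametrize(
    "path",
    [
        "sub-01/mr-anat/sub-01_part-_mese.nii.gz",  # empty entity value
        "sub-01/mr-anat/sub-01_mese.weird",  # unknown extension
        "justafile.nii.gz",  # too few components
        "sub-01/mr-anat/mese.nii.gz",  # no sub- entity
    ],
)
def test_malformed_paths_rejected(path):
    with pytest.raises(FilenameError):
        parse_filename(path)


def test_labels_reject_separator_characters():
    for bad in ("a_b", "a-b", "a b", "a/b"):
        key = EntityKey(subject=bad, suffix="ct", modality_folder="ct")
        with pytest.raises(FilenameError):
            key.validate()


def test_suffix_registry_matches_standard_rows():
    """Folder pairing and dimensionality of every included acquisition."""
    included = {s: i for s, i in SUFFIX_REGISTRY.items() if i.status == "included"}
    assert set(included) == {
        "ct", "pcct", "hrpqct", "cr", "t1", "t2", "wt2",
        "dess", "dess-fid", "dess_echo", "megre", "mese",
    }
    for suffix in ("ct", "pcct", "hrpqct"):
        assert included[suffix].folder == "ct"
        assert included[suffix].dim_labels == ("x", "y", "z")
    assert included["cr"].folder == "cr" and included["cr"].dim_labels == ("x", "y")
    for suffix in ("t1", "t2", "wt2"):
        assert included[suffix].folder == "mr-quant"
    for suffix in ("dess", "dess-fid", "dess_echo", "megre", "mese"):
        assert included[suffix].folder == "mr-anat"
    for suffix in ("megre", "mese"):
        assert included[suffix].dim_labels == ("x", "y", "z", "echo")
    assert RESERVED_SUFFIXES == {"vel", "diff", "seg", "us"}


def test_image_volume_invariants():
    with pytest.raises(ValueError):
        ImageVolume(np.zeros((2, 2, 2)), np.eye(4), ("x", "y"))  # label count
    singular = np.eye(4)
    singular[0, 0] = 0
    with pytest.raises(ValueError):
        ImageVolume(np.zeros((2, 2, 2)), singular, ("x", "y", "z"))
    with pytest.raises(ValueError):
        ImageVolume(np.full((2, 2, 2), 4.0), np.eye(4), ("x", "y", "z"), part="phase")
    vol = ImageVolume(np.zeros((2, 2, 2, 3)), np.eye(4), ("x", "y", "z", "echo"))
    assert vol.n_echoes == 3
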