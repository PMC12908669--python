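"""Shared fixtures: synthetic DICOM inputs and a converted dataset tree.

Everything is generated at test time; session scope keeps the suite fast
since fixture directories are read-only for the tests that use them.
"""

import pytest

from mskmids.pipeline import convert_directory
from mskmids.synthetic import (
    make_cr_image,
    make_ct_series,
    make_megre_classic,
    make_mese_enhanced,
)


@pytest.fixture(scope="session")
def megre_dir(tmp_path_factory):
    """Classic GE-style MEGRE: 3 echoes x 4 slices, magnitude + phase."""
    root = tmp_path_factory.mktemp("megre")
    make_megre_classic(root, parts=("mag", "phase"), seed=7)
    return root


@pytest.fixture(scope="session")
def megre_mag_dir(tmp_path_factory):
    """Magnitude-only classic MEGRE (12 files)."""
    root = tmp_path_factory.mktemp("megre_mag")
    make_megre_classic(root, parts=("mag",), seed=7)
    return root


@pytest.fixture(scope="session")
def mese_dir(tmp_path_factory):
    """Enhanced Philips-style MESE: one file, 5 echoes x 3 slices."""
    root = tmp_path_factory.mktemp("mese")
    make_mese_enhanced(root, seed=7)
    return root


@pytest.fixture(scope="session")
def ct_dirs(tmp_path_factory):
    """One directory per CT variant."""
    root = tmp_path_factory.mktemp("ct")
    out = {}
    for variant in ("ct", "pcct", "hrpqct"):
        out[variant] = make_ct_series(root / variant, variant=variant, seed=7)
    return out


@pytest.fixture(scope="session")
def cr_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("cr")
    make_cr_image(root, seed=7)
    return root


@pytest.fixture(scope="session")
def all_fixture_dirs(megre_dir, mese_dir, ct_dirs, cr_dir):
    """variant name -> input directory, covering every converter."""
    dirs = {"megre": megre_dir, "mese": mese_dir, "cr": cr_dir}
    dirs.update(ct_dirs)
    return dirs


@pytest.fixture(scope="session")
def converted_tree(tmp_path_factory, all_fixture_dirs):
    """One dataset tree holding every fixture modality, subject per variant."""
    out = tmp_path_factory.mktemp("dataset")
    subjects = {"megre": "01", "mese": "01", "ct": "02", "pcct": "03", "hrpqct": "04", "cr": "05"}
    reports = {}
    for variant, in_dir in all_fixture_dirs.items():
        reports[variant] = convert_directory(in_dir, out, subject=subjects[variant])
    return out, reports, subjects
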