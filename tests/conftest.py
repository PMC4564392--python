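"""Shared fixtures: small phantoms and rendered subjects."""

from __future__ import annotations

import numpy as np
import pytest

from lesionmorph import phantom
from lesionmorph.tpm import TPMSet
from lesionmorph.volumes import Volume


@pytest.fixture(scope="session")
def shell_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        grid_shape=(40, 40, 40), voxel_size_mm=1.0, wm_radius_mm=12.0,
        gm_thickness_mm=3.0, geometry="sphere_shell",
    )


@pytest.fixture(scope="session")
def slab_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        grid_shape=(24, 24, 24), voxel_size_mm=1.0, wm_radius_mm=8.0,
        gm_thickness_mm=4.0, geometry="flat_slab",
    )


@pytest.fixture(scope="session")
def shell_labels(shell_spec) -> Volume:
    return phantom.make_labelmap(shell_spec)


@pytest.fixture(scope="session")
def lesioned_subject(shell_labels):
    """Labels with implanted lesions plus rendered T1/FLAIR channels."""
    lesions = phantom.LesionSpec(n_wmh=4, n_li=1)
    labels, wmh, li = phantom.implant_lesions(shell_labels, lesions, seed=1)
    model = phantom.IntensityModel()
    t1, flair = phantom.render_intensities(labels, wmh, li, model, seed=2)
    mask = labels.with_data(np.ones(labels.shape, dtype=np.uint8))
    return dict(labels=labels, wmh=wmh, li=li, t1=t1, flair=flair,
                model=model, mask=mask)


@pytest.fixture(scope="session")
def truth_tpms(shell_labels) -> TPMSet:
    return phantom.truth_tpms(shell_labels)
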