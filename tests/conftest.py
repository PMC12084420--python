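"""Shared fixtures: the canonical spectral axis, generator spectra and a
session-scoped default synthetic scene (rendered once, reused by the
recovery and detection tests)."""

from __future__ import annotations

import numpy as np
import pytest

import srslipid as sl


@pytest.fixture(scope="session")
def axis() -> sl.SpectralAxis:
    return sl.build_spectral_axis(sl.DEFAULT_REGIONS)


@pytest.fixture(scope="session")
def spectra(axis):
    return sl.make_component_spectra(axis)


@pytest.fixture(scope="session")
def refs(spectra):
    return sl.reference_set_from_spectra(spectra)


@pytest.fixture(scope="session")
def default_scene(spectra):
    """The default 256 x 256 x 153 scene (quantized, noise-free), seed 1."""
    return sl.render_scene(sl.SceneLayout(), spectra, seed=1)


@pytest.fixture(scope="session")
def default_weights(default_scene, refs):
    cube, _ = default_scene
    return sl.decompose_cube(cube, refs)


@pytest.fixture()
def toy_cell_masks():
    """A square cell containing a square nucleus, nucleus clear of the edge."""
    cell = np.zeros((40, 40), dtype=bool)
    cell[5:35, 5:35] = True
    nucleus = np.zeros((40, 40), dtype=bool)
    nucleus[15:25, 15:25] = True
    return nucleus, cell
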