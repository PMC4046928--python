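"""Shared fixtures.

Small-scale fixtures (thin gel, tight margins) keep unit tests fast; the
full-scale study conditions (1 kPa, 70 µm gel, 4.84 µm mesh) are reserved
for the acceptance tests and shared session-wide so the expensive forward
solves run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from femtfm import (
    forward_surface_displacements,
    make_two_cell_fixture,
    recover_mixed,
)

SMALL = dict(thickness=20.0, spacing=4.0, margin=25.0)


@pytest.fixture(scope="session")
def small_fixture():
    """Two-cell force field on a thin gel: cheap enough for unit tests."""
    return make_two_cell_fixture(**SMALL)


@pytest.fixture(scope="session")
def small_disp(small_fixture):
    return forward_surface_displacements(small_fixture)


@pytest.fixture(scope="session")
def small_roundtrip(small_fixture, small_disp):
    tf, rep = recover_mixed(
        small_disp.in_plane(),
        small_fixture.mask(),
        small_fixture.substrate,
        min_margin=SMALL["margin"],
    )
    return tf, rep


@pytest.fixture(scope="session")
def study_fixture():
    """The canonical validation geometry: two 20 µm cells, 10 µm apart,
    1 kPa gel, 70 µm thick, 4.84 µm surface mesh."""
    return make_two_cell_fixture()


@pytest.fixture(scope="session")
def study_disp(study_fixture):
    return forward_surface_displacements(study_fixture)


@pytest.fixture(scope="session")
def study_roundtrip(study_fixture, study_disp):
    tf, rep = recover_mixed(
        study_disp.in_plane(), study_fixture.mask(), study_fixture.substrate
    )
    return tf, rep


def max_force_error(tf, truth, floor_frac=0.0):
    """Max node-by-node in-plane nodal force error over labeled nodes.

    ``floor_frac`` restricts the max to nodes whose true force magnitude
    is at least that fraction of the peak.
    """
    mag = np.hypot(truth.fx, truth.fy)
    sel = (truth.labels > 0) & (mag >= floor_frac * mag.max())
    return float(np.hypot(tf.fx - truth.fx, tf.fy - truth.fy)[sel].max())
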