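"""Shared fixtures: phantom geometry and one expensive registration run.

The 64-voxel phantom pair and its registration are session-scoped because
several tests (cost behaviour, QA improvement, displacement recovery)
examine different aspects of the same run.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import lungmech as lm
from lungmech.phantom import (
    ScaledDeformation,
    _cohort_deformation,
    moving_frame_labels,
)


@pytest.fixture(scope="session")
def phantom64():
    """Lobes, vessels and lung mask at 64^3, 1 mm isotropic."""
    lobes, vessels, lung = lm.make_lung_phantom((64, 64, 64), seed=3)
    return lobes, vessels, lung


@pytest.fixture(scope="session")
def phantom_pair(phantom64):
    """A ground-truth deformation with max |u| = 5 voxels and its CT pair."""
    lobes, vessels, lung = phantom64
    grid = lung.grid
    base = _cohort_deformation(grid, np.random.default_rng(0))
    in_lung = lung.data.astype(bool)
    pts = grid.coords()[in_lung]

    def max_u(s):
        return float(
            np.linalg.norm(ScaledDeformation(base, s).displacement_at(pts), axis=-1).max()
        )

    s = brentq(lambda s: max_u(s) - 5.0, 0.0, 3.0)
    deformation = ScaledDeformation(base, s)
    ct_exp, ct_insp = lm.synthesize_image_pair(lung, vessels, deformation)
    return {
        "lobes": lobes,
        "vessels": vessels,
        "lung": lung,
        "deformation": deformation,
        "true_dvf": deformation.to_field(grid),
        "ct_exp": ct_exp,
        "ct_insp": ct_insp,
        "moving_lobes": moving_frame_labels(lobes, deformation),
        "moving_vessels": moving_frame_labels(vessels, deformation),
    }


@pytest.fixture(scope="session")
def registration_result(phantom_pair):
    """The SSTVD registration of the session phantom pair."""
    transform, dvf, trace = lm.register_ct_pair(
        phantom_pair["ct_exp"], phantom_pair["ct_insp"], phantom_pair["lung"]
    )
    return {"transform": transform, "dvf": dvf, "trace": trace}
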