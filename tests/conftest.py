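"""Shared fixtures: small meshes and expensive session-scoped runs."""

import numpy as np
import pytest

from hexaheart.cells.backends import MahajanBackend
from hexaheart.fem import SolverConfig
from hexaheart.mesh import (assign_nine_regions, build_biventricular_phantom,
                            build_slab_mesh)
from hexaheart.tensors import isotropic_conductivity

#: longitudinal diffusivity (µm²/ms) calibrated for 0.7 m/s plane-wave CV
D_L = 1.84376225e5

#: solver settings used for quantitative conduction measurements
CV_CONFIG = SolverConfig(dt_pde=0.05, dt_ode=0.01, splitting="strang",
                         theta=0.5)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced two-cavity phantom with nine-region labels (400 µm)."""
    mask, mesh = build_biventricular_phantom(
        outer_radii=(4000.0, 4000.0, 5600.0), wall_thickness=1400.0,
        septum_thickness=1400.0, base_height=2000.0, edge=400.0)
    assign_nine_regions(mesh)
    return mask, mesh


@pytest.fixture(scope="session")
def tiny_slab():
    """3x2x2-element slab for assembly-level checks."""
    return build_slab_mesh((300.0, 200.0, 200.0), 100.0)


@pytest.fixture(scope="session")
def tiny_system(tiny_slab):
    from hexaheart.fem import assemble

    sigma = isotropic_conductivity(tiny_slab.n_elements, 1.0e5)
    return assemble(tiny_slab, sigma)


@pytest.fixture(scope="session")
def backend():
    return MahajanBackend()


@pytest.fixture(scope="session")
def reentry_stats():
    """One shared S1-S2 sheet run (the expensive reentry fixture)."""
    from hexaheart.protocols import s1s2_sheet

    return s1s2_sheet()


@pytest.fixture(scope="session")
def coarse_cv():
    """Longitudinal CV on the production-resolution (200 µm) slab."""
    from hexaheart.fem import slab_cv

    return slab_cv(D_L, (9600.0, 600.0, 600.0), 200.0, CV_CONFIG)


@pytest.fixture(scope="session")
def reference_cv():
    """Longitudinal CV on the 50 µm reference slab (expensive)."""
    from hexaheart.fem import slab_cv

    return slab_cv(D_L, (9600.0, 600.0, 600.0), 50.0, CV_CONFIG)
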