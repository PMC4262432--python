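"""Cell-model backends with a uniform array interface for tissue solvers.

A backend bundles a compiled ``step(V, Q, dt, mult, iion)`` kernel (advance
internal states at frozen voltage, report ionic current), the state-space
size, a rest state and the multiplier layout. The tissue stepper is thereby
independent of which membrane model runs at the nodes.
"""

from __future__ import annotations

import numpy as np

from . import mahajan, twovar
from .kernel import params_vector, step_states as _mahajan_step


class MahajanBackend:
    """Rabbit ventricular membrane dynamics at every node."""

    n_states = mahajan.N_STATES

    def __init__(self, params: mahajan.CellParameters | None = None):
        self.params = params or mahajan.CellParameters()
        self._pv = params_vector(self.params)

    @property
    def rest_v(self) -> float:
        return mahajan.REST_V

    def rest_q(self) -> np.ndarray:
        return mahajan.REST_Q.copy()

    def step(self, V, Q, dt, mult, iion):
        _mahajan_step(V, Q, dt, mult, self._pv, iion)


class TwoVarBackend:
    """Cubic-excitation reference model (dimensionless voltage).

    Coefficients (K, A, EPS, G) default to the module constants; pass
    overrides for e.g. faster recovery (shorter wavelength) fixtures.
    """

    n_states = twovar.N_STATES

    def __init__(self, k=twovar.K, a=twovar.A, eps=twovar.EPS, g=twovar.G):
        self._pv = np.array([k, a, eps, g], dtype=float)

    @property
    def rest_v(self) -> float:
        return twovar.REST_V

    def rest_q(self) -> np.ndarray:
        return twovar.REST_Q.copy()

    def step(self, V, Q, dt, mult, iion):
        twovar.step_states(V, Q, dt, mult, self._pv, iion)


class PassiveBackend:
    """Zero ionic current: pure diffusion (conservation/null-space tests)."""

    n_states = 1

    rest_v = 0.0

    def rest_q(self) -> np.ndarray:
        return np.zeros(1)

    def step(self, V, Q, dt, mult, iion):
        iion[:] = 0.0
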