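"""Shared fixtures and the independent lattice-hopping MFPT oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nbratchet import Geometry, make_environment


@pytest.fixture(scope="session")
def env():
    """Default thermal environment: 300 K, water viscosity, R = 5 nm."""
    return make_environment()


@pytest.fixture(scope="session")
def geom():
    """Default geometry: p = 0.34 nm, r_d = 0.5 nm, L_escape = 5 nm."""
    return Geometry()


def lattice_mfpt_s(potential_kt, start_nm, end_nm, diffusion_m2_per_s, n_sites=20001):
    """Exact MFPT of a nearest-neighbour hopping chain, as an oracle.

    The continuum problem is discretized on ``n_sites`` lattice points with
    detailed-balance hop rates w(i->i+1) = (D/h^2) exp(-(V_{i+1}-V_i)/2),
    reflecting at the start, absorbing at the end.  The MFPT of the chain
    solves a first-order recurrence exactly (no quadrature involved), and
    converges to the continuum MFPT as h^2.
    """
    span = abs(end_nm - start_nm)
    sgn = math.copysign(1.0, end_nm - start_nm)
    s = np.linspace(0.0, span, n_sites)
    v = np.asarray(potential_kt(start_nm + sgn * s), dtype=float)
    h = s[1] - s[0]
    dv = np.diff(v)
    # d_i = T_i - T_{i+1}; reflecting start gives d_0 = 1/w_0^+, interior
    # balance gives w_i^+ d_i = 1 + w_i^- d_{i-1}
    d = np.empty(n_sites - 1)
    d[0] = math.exp(dv[0] / 2.0)
    for i in range(1, n_sites - 1):
        d[i] = (1.0 + math.exp(dv[i - 1] / 2.0) * d[i - 1]) * math.exp(dv[i] / 2.0)
    d_nm2 = diffusion_m2_per_s * 1e18
    return float(np.sum(d)) * h * h / d_nm2


@pytest.fixture(scope="session")
def lattice_oracle():
    return lattice_mfpt_s
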