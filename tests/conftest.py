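import math

import numpy as np
import pytest
from scipy.integrate import quad

from taurace import FIXTURES, Erlang, Exponential, Hyperexponential


def mm_quad(dist, integrand, moment_hint=None):
    """Adaptive-quadrature oracle for MM waiting-time integrals.

    Integrates on [0, T] with T chosen so the neglected tail is far below
    1e-10: both exponentials decay at least like e^{βτ}, so
    T = (60 + log(1+α))/|β| bounds the remainder by ~α e^{βT}/|β|.
    Interior break points at the mean keep the subdivision efficient for
    stiff sets (|γ| ≫ |β|).
    """
    p = dist.params
    T = (60.0 + max(0.0, math.log1p(p.alpha))) / abs(p.beta)
    m = dist.mean()
    # stiff sets (|γ| ≫ |β|) hide a narrow fast component of width ~1/|γ|
    # near the origin: integrate it on its own scale, then the slow tail
    cut = min(40.0 / abs(p.gamma_), T / 2)
    pts = sorted({min(max(m, 2 * cut), T / 2), min(max(10 * m, 4 * cut), T / 2)})
    head = quad(integrand, 0.0, cut, limit=200)[0]
    tail = quad(integrand, cut, T, points=pts, limit=200)[0]
    return head + tail


def quad_norm(dist):
    return mm_quad(dist, dist.pdf)


def quad_mean(dist):
    return mm_quad(dist, lambda t: t * dist.pdf(t))


def quad_second_moment(dist):
    return mm_quad(dist, lambda t: t * t * dist.pdf(t))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def a1_dist():
    """Single-molecule MM density at k1=1e7 M⁻¹s⁻¹, k2=250 s⁻¹, k−1=0, S=5 μM."""
    return FIXTURES["A1"].dist()


@pytest.fixture(params=["A1", "A2", "A3"])
def a_set_dist(request):
    return FIXTURES[request.param].dist()


@pytest.fixture
def family_zoo():
    """One representative of each supported waiting-time family."""
    return {
        "exponential": Exponential(0.0078),
        "erlang": Erlang(k=2, lam=0.0078),
        "hyperexponential": Hyperexponential(weights=(0.4, 0.6), rates=(0.01, 0.05)),
        "mm_single_molecule": FIXTURES["A1"].dist(),
    }
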