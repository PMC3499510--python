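"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the closed-form antiderivative code under
test: integrals are computed by adaptive quadrature (scipy.integrate.quad)
piece by piece, and fits are solved from quadrature-built design matrices.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.integrate import quad

from ppctrack import RleSignal

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_signal(
    rng: np.random.Generator,
    n_runs: int,
    max_len: int = 10,
    value_sampler=None,
    chrom: str = "chr",
    origin: int = 0,
) -> RleSignal:
    lengths = rng.integers(1, max_len + 1, size=n_runs)
    if value_sampler is None:
        values = rng.normal(0.0, 2.0, size=n_runs)
    else:
        values = value_sampler(rng, n_runs)
    return RleSignal(chrom, origin, lengths, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def staircase(signal: RleSignal, x: float) -> float:
    """Value of the RLE staircase at coordinate x."""
    bounds = signal.run_bounds
    i = int(np.searchsorted(bounds, x, side="right")) - 1
    return float(signal.values[min(max(i, 0), signal.n_runs - 1)])


def quad_data_moments(signal: RleSignal, a: float, b: float, max_j: int):
    """d_j = integral over [a,b) of x^j f(x) dx by adaptive quadrature,
    split at run boundaries (x relative to a)."""
    bounds = signal.run_bounds.astype(float)
    cuts = [a] + [float(t) for t in bounds if a < t < b] + [b]
    d = np.zeros(max_j + 1)
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        v = staircase(signal, (lo + hi) / 2)
        for j in range(max_j + 1):
            val, _ = quad(lambda x: (x - a) ** j * v, lo, hi, epsabs=1e-13, epsrel=1e-13)
            d[j] += val
    return d


def quad_design(a: float, b: float, order: int) -> np.ndarray:
    """G[j,k] = integral (x-a)^j (x-a)^k dx by quadrature."""
    n = order + 1
    G = np.empty((n, n))
    for j in range(n):
        for k in range(n):
            G[j, k], _ = quad(
                lambda x: (x - a) ** (j + k), a, b, epsabs=1e-13, epsrel=1e-13
            )
    return G


def oracle_fit(signal: RleSignal, a: float, b: float, order: int) -> np.ndarray:
    """Numeric minimization of the integral squared error: normal equations
    built entirely by quadrature, coefficients about origin a."""
    G = quad_design(a, b, order)
    d = quad_data_moments(signal, a, b, order)
    return np.linalg.solve(G, d)


def oracle_fit_constrained(
    signal: RleSignal, a: float, b: float, order: int, boundary
) -> np.ndarray:
    """Quadrature-built KKT solve of the constrained minimization."""
    n = order + 1
    m = len(boundary)
    G = quad_design(a, b, order)
    d = quad_data_moments(signal, a, b, order)
    A = np.array([[(xk - a) ** j for j in range(n)] for xk, _ in boundary])
    v = np.array([vk for _, vk in boundary])
    if m == n:
        return np.linalg.solve(A, v)
    kkt = np.zeros((n + m, n + m))
    kkt[:n, :n] = G
    kkt[:n, n:] = A.T
    kkt[n:, :n] = A
    return np.linalg.solve(kkt, np.concatenate([d, v]))[:n]


def riemann_error(model_eval, signal: RleSignal, a: float, b: float, n_points: int):
    """Midpoint Riemann sum of (model - staircase)^2 over [a, b)."""
    x = np.linspace(a, b, n_points, endpoint=False) + (b - a) / n_points / 2
    f = np.array([staircase(signal, xi) for xi in x])
    m = np.array([model_eval(xi) for xi in x])
    return float(np.sum((m - f) ** 2) * (b - a) / n_points)
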