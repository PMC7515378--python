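"""Deterministic and stochastic signal generators.

Fixtures for exercising the entropies: periodic sequences, uniform
noise, the logistic map, a simplified Lorenz flow with a single
bifurcation parameter, and the Caputo fractional-difference Hénon map.
All deterministic generators are reproducible from their parameters
alone; only the uniform-random generator consumes a seed.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "periodic_signal",
    "uniform_random_signal",
    "logistic_series",
    "logistic_lyapunov",
    "simplified_lorenz_series",
    "caputo_kernel",
    "fractional_henon_series",
    "classic_henon_series",
]

#: Default cap on fractional Hénon length: the map carries full
#: power-law memory, so generating n samples costs O(n^2) work.
FRACTIONAL_HENON_MAX_N = 5_000


def periodic_signal(period_values, n: int) -> np.ndarray:
    """Cyclic repetition of ``period_values`` truncated to length ``n``."""
    values = np.asarray(period_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("period_values must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    reps = -(-n // values.size)
    return np.tile(values, reps)[:n]


def uniform_random_signal(n: int, seed=None, low: float = 0.0, high: float = 1.0) -> np.ndarray:
    """Uniform i.i.d. noise on [low, high); the maximally irregular fixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n)


def _logistic_orbit(mu: float, n_total: int, x0: float) -> np.ndarray:
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0={x0} must lie in (0, 1)")
    if not 0.0 < mu <= 4.0:
        raise ValueError(f"mu={mu} must lie in (0, 4]")
    if mu == 4.0 and x0 == 0.5:
        warnings.warn(
            "x0=0.5 at mu=4 maps to the degenerate orbit 1, 0, 0, ...; "
            "choose a different initial condition",
            stacklevel=3,
        )
    orbit = np.empty(n_total)
    x = x0
    for i in range(n_total):
        x = mu * x * (1.0 - x)
        orbit[i] = x
    return orbit


def logistic_series(mu: float, n: int, x0: float = 0.3, transient: int = 1000) -> np.ndarray:
    """Orbit of the logistic map x -> mu*x*(1-x) after a transient.

    Parameters
    ----------
    mu : control parameter in (0, 4]; the map is fully chaotic at 4.
    n : samples returned.
    x0 : initial condition in (0, 1). The default avoids the
        measure-zero preimages of the unstable fixed points.
    transient : iterations discarded before recording.
    """
    return _logistic_orbit(mu, transient + n, x0)[transient:]


def logistic_lyapunov(mu: float, n: int = 100_000, x0: float = 0.3, transient: int = 1000) -> float:
    """Lyapunov exponent of the logistic map by direct orbit averaging.

    Mean of ln|mu*(1-2x)| along the orbit after the transient. At mu=4
    the known value is ln 2. Raises if the orbit hits x=0.5 exactly
    (zero derivative, log undefined); superstable parameters can
    otherwise produce very large negative values, which are returned
    as computed.
    """
    orbit = _logistic_orbit(mu, transient + n, x0)[transient:]
    deriv = np.abs(mu * (1.0 - 2.0 * orbit))
    if np.any(deriv == 0.0):
        raise ValueError("derivative zero encountered: orbit hit x=0.5 exactly")
    return float(np.log(deriv).mean())


def _lorenz_rhs(state, c: float):
    x1, x2, x3 = state
    return (
        10.0 * (x2 - x1),
        (24.0 - 4.0 * c) * x1 - x1 * x3 + c * x2,
        x1 * x2 - 8.0 * x3 / 3.0,
    )


def simplified_lorenz_series(
    c: float,
    n: int,
    h: float = 0.01,
    transient: int = 10_000,
    initial=(0.3, 0.2, 0.1),
) -> np.ndarray:
    """x1 component of the simplified Lorenz flow, fixed-step RK4.

    The flow is the three-variable system
    dx1 = 10(x2 - x1), dx2 = (24 - 4c)x1 - x1*x3 + c*x2,
    dx3 = x1*x2 - 8*x3/3, with single bifurcation parameter c (chaotic
    around c=2). One sample is recorded per integration step of size
    ``h`` after ``transient`` discarded steps.
    """
    if h <= 0:
        raise ValueError("step size h must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    state = tuple(float(v) for v in initial)
    out = np.empty(n)
    for step in range(transient + n):
        k1 = _lorenz_rhs(state, c)
        k2 = _lorenz_rhs(tuple(s + 0.5 * h * k for s, k in zip(state, k1)), c)
        k3 = _lorenz_rhs(tuple(s + 0.5 * h * k for s, k in zip(state, k2)), c)
        k4 = _lorenz_rhs(tuple(s + h * k for s, k in zip(state, k3)), c)
        state = tuple(
            s + h * (a + 2 * b + 2 * cc + dd) / 6.0
            for s, a, b, cc, dd in zip(state, k1, k2, k3, k4)
        )
        if max(abs(v) for v in state) > 1e6:
            raise ValueError(f"integration blow-up at step {step}")
        if step >= transient:
            out[step - transient] = state[0]
    return out


def caputo_kernel(nu: float, n: int) -> np.ndarray:
    """Memory kernel phi(k) = Gamma(k+nu) / (Gamma(nu) * Gamma(k+1)).

    Evaluated by the multiplicative recurrence phi(0)=1,
    phi(k) = phi(k-1) * (k-1+nu)/k, which is overflow-free for long
    memories. phi(k)=1 for every k when nu=1 and decays like a power
    law for nu<1.
    """
    if not 0.0 < nu <= 1.0:
        raise ValueError(f"fractional order nu={nu} must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    phi = np.empty(n)
    phi[0] = 1.0
    for k in range(1, n):
        phi[k] = phi[k - 1] * (k - 1.0 + nu) / k
    return phi


def fractional_henon_series(
    a: float,
    b: float,
    nu: float,
    n: int,
    x0: float = 0.1,
    y0: float = 0.1,
    transient: int = 0,
    allow_long: bool = False,
) -> np.ndarray:
    """x series of the Caputo fractional-difference Hénon map.

    The state is the full-memory convolution
    ``x_i = x0 + sum_j phi(i-j) * (1 - a*x_{j-1}^2 + y_{j-1} - x_{j-1})``
    (and likewise for y with increment ``b*x_{j-1} - y_{j-1}``), where
    phi is :func:`caputo_kernel`. At nu=1 the kernel is identically 1
    and the recursion telescopes to the classic Hénon map.

    ``transient`` initial samples are dropped from the returned series
    (the memory still starts at the initial condition). Lengths beyond
    5000 total samples require ``allow_long=True`` because of the
    quadratic memory cost. Raises on divergence, reporting the index
    reached.
    """
    total = n + transient
    if n < 1:
        raise ValueError("n must be >= 1")
    if total > FRACTIONAL_HENON_MAX_N and not allow_long:
        raise ValueError(
            f"requested {total} samples exceeds the default cap "
            f"{FRACTIONAL_HENON_MAX_N} (O(n^2) memory convolution); "
            "pass allow_long=True to override"
        )
    phi = caputo_kernel(nu, total)
    x = np.empty(total + 1)
    y = np.empty(total + 1)
    fx = np.empty(total)
    fy = np.empty(total)
    x[0], y[0] = float(x0), float(y0)
    for i in range(1, total + 1):
        fx[i - 1] = 1.0 - a * x[i - 1] ** 2 + y[i - 1] - x[i - 1]
        fy[i - 1] = b * x[i - 1] - y[i - 1]
        kernel = phi[:i][::-1]
        x[i] = x[0] + kernel @ fx[:i]
        y[i] = y[0] + kernel @ fy[:i]
        if not (np.isfinite(x[i]) and np.isfinite(y[i])) or abs(x[i]) > 1e6:
            raise ValueError(f"trajectory unbounded at index {i}")
    return x[1 + transient :]


def classic_henon_series(
    a: float, b: float, n: int, x0: float = 0.1, y0: float = 0.1, transient: int = 0
) -> np.ndarray:
    """Classic Hénon map x -> 1 - a*x^2 + y, y -> b*x (reference orbit)."""
    x, y = float(x0), float(y0)
    out = np.empty(n)
    for i in range(transient + n):
        x, y = 1.0 - a * x * x + y, b * x
        if abs(x) > 1e6:
            raise ValueError(f"trajectory unbounded at index {i + 1}")
        if i >= transient:
            out[i - transient] = x
    return out
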