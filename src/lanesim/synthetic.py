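"""Synthetic inputs with known ground truth for estimator validation.

Every estimator in the package is required to pass parameter recovery on
data generated here before being applied to simulation output.
"""

from __future__ import annotations

import numpy as np

from .observables import CorrelationGrid, ObservableSeries

__all__ = [
    "ou_series",
    "rotational_diffusion_angles",
    "powerlaw_grid",
    "gaussian_series",
]


def gaussian_series(n, sigma, dt=1.0, mean=0.0, seed=0) -> ObservableSeries:
    """White Gaussian series of known variance sigma**2."""
    rng = np.random.default_rng(seed)
    t = dt * np.arange(n)
    return ObservableSeries(t, mean + sigma * rng.standard_normal(n), "white")


def ou_series(n, tau, sigma=1.0, dt=1.0, seed=0) -> ObservableSeries:
    """Ornstein-Uhlenbeck-type series with correlation time ``tau``.

    Exact discrete recursion, so the stationary autocorrelation is
    exp(-t/tau) and the stationary variance sigma**2.
    """
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau)
    noise_sd = sigma * np.sqrt(1.0 - a * a)
    v = np.empty(n)
    v[0] = sigma * rng.standard_normal()
    eps = rng.standard_normal(n - 1)
    for k in range(1, n):
        v[k] = a * v[k - 1] + noise_sd * eps[k - 1]
    return ObservableSeries(dt * np.arange(n), v, f"ou(tau={tau})")


def rotational_diffusion_angles(n_particles, n_steps, D_r, dt, seed=0):
    """Free angular random walks: <cos(theta(t)-theta(0))> = exp(-D_r t).

    Returns (times, theta_samples) shaped like simulation output.
    """
    rng = np.random.default_rng(seed)
    steps = np.sqrt(2.0 * D_r * dt) * rng.standard_normal((n_steps, n_particles))
    theta = np.vstack(
        [rng.uniform(-np.pi, np.pi, n_particles), steps]
    ).cumsum(axis=0)
    times = dt * np.arange(n_steps + 1)
    return times, theta


def powerlaw_grid(
    xmax=60.0,
    ymax=25.0,
    bin_size=0.5,
    amplitude=1.0,
    x_exponent=1.5,
    y_exponent=0.5,
    eta_scale=1.0,
    noise=0.0,
    x_core=2.0,
    seed=0,
) -> CorrelationGrid:
    """Correlation grid built exactly as A x^(-a) f(y / x^b) plus noise.

    The master profile f is a unit Gaussian in the rescaled coordinate;
    by construction the grid collapses perfectly under the matching
    rescaling exponents (spread zero at zero noise).
    """
    rng = np.random.default_rng(seed)
    nx = int(round(2 * xmax / bin_size))
    ny = int(round(2 * ymax / bin_size))
    x = -xmax + bin_size * (np.arange(nx) + 0.5)
    y = -ymax + bin_size * (np.arange(ny) + 0.5)
    ax = np.maximum(np.abs(x), x_core)
    vals = (
        amplitude
        * ax[:, None] ** (-x_exponent)
        * np.exp(-0.5 * (y[None, :] / (eta_scale * ax[:, None] ** y_exponent)) ** 2)
    )
    if noise:
        vals = vals + noise * rng.standard_normal(vals.shape)
    return CorrelationGrid(x, y, vals, pair="synthetic", bin_size=bin_size)
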