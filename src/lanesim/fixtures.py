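"""Named deterministic configurations for tests and demonstrations."""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigError
from .params import ModelParams, assign_radii, assign_species
from .state import ParticleState, init_random

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "two_lane_perfect",
    "mingled_random",
    "colliding_pair",
    "single_right",
)


def make_fixture(name: str, params: ModelParams = None, N: int = 64,
                 seed: int = 7):
    """Build a named small configuration; returns (state, params).

    - ``two_lane_perfect``: right movers fill the lower half-box, left
      movers the upper half, every orientation exactly on its preferred
      direction (order parameter exactly zero, bimodal density
      difference).
    - ``mingled_random``: uniform random mixed state.
    - ``colliding_pair``: one right and one left mover at contact in the
      two-body scattering geometry (impact parameter from params.seed-free
      default 0.25).
    - ``single_right``: a single right mover at the box centre, theta = 0
      (plus its left-moving far-away partner to keep populations equal).
    """
    if name == "two_lane_perfect":
        if params is None:
            params = ModelParams(B=2.0, Lx=40.0, Ly=20.0)
        rng = np.random.default_rng(seed)
        species = assign_species(N)
        x = rng.uniform(0, params.Lx, N)
        y = np.where(
            species == 1,
            rng.uniform(0, 0.5 * params.Ly, N),
            rng.uniform(0.5 * params.Ly, params.Ly, N),
        )
        theta = np.where(species == 1, 0.0, math.pi)
        return ParticleState(x, y, theta, species, assign_radii(N)), params
    if name == "mingled_random":
        if params is None:
            params = ModelParams(B=5.0, Lx=40.0, Ly=20.0)
        return init_random(N, params, seed=seed), params
    if name == "colliding_pair":
        if params is None:
            params = ModelParams(B=5.0, Lx=400.0, Ly=200.0)
        y_in = 0.25
        rng_pair = 2.0
        half_dx = 0.5 * math.sqrt(rng_pair**2 - (2 * y_in) ** 2)
        cx, cy = params.Lx / 2.0, params.Ly / 2.0
        x = np.array([cx - half_dx, cx + half_dx])
        y = np.array([cy + y_in, cy - y_in])
        theta = np.array([0.0, math.pi - math.pi / 10.0])
        species = np.array([1, -1], dtype=np.int8)
        radii = np.array([1.0, 1.0])
        return ParticleState(x, y, theta, species, radii), params
    if name == "single_right":
        # one active right mover; its far-corner left partner keeps the
        # populations formally equal and never interacts
        if params is None:
            params = ModelParams(B=2.0, Lx=40.0, Ly=20.0)
        x = np.array([params.Lx / 2.0, params.Lx / 4.0])
        y = np.array([params.Ly / 2.0, params.Ly / 4.0])
        theta = np.array([0.0, math.pi])
        species = np.array([1, -1], dtype=np.int8)
        radii = np.array([1.0, 1.0])
        return ParticleState(x, y, theta, species, radii), params
    raise ConfigError(
        f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
    )
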