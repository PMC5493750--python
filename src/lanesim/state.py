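"""Particle configurations and their construction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .params import ModelParams, assign_radii, assign_species


def wrap_angle(theta):
    """Map angles to (-pi, pi], ties at the branch cut going to +pi."""
    wrapped = np.mod(np.asarray(theta) + np.pi, 2.0 * np.pi) - np.pi
    # np.mod puts exact -pi at -pi; move it to +pi per our convention
    return np.where(wrapped == -np.pi, np.pi, wrapped)


@dataclass
class ParticleState:
    """Positions, orientations and labels of N particles in a periodic box.

    ``species`` is +1 for right movers (preferred direction Theta = 0) and
    -1 for left movers (Theta = pi).  Orientations are stored unwrapped;
    use :meth:`theta_wrapped` for output.
    """

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    species: np.ndarray
    radii: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        n = len(self.x)
        for name in ("y", "theta", "species", "radii"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"field {name!r} length mismatch")
        if np.count_nonzero(self.species == 1) != np.count_nonzero(
            self.species == -1
        ):
            raise ConfigError("the two populations must have equal size")

    @property
    def N(self) -> int:
        return len(self.x)

    @property
    def preferred_angle(self) -> np.ndarray:
        """Theta_i: 0 for right movers, pi for left movers."""
        return np.where(self.species == 1, 0.0, np.pi)

    def theta_wrapped(self) -> np.ndarray:
        return wrap_angle(self.theta)

    def copy(self) -> "ParticleState":
        return ParticleState(
            self.x.copy(),
            self.y.copy(),
            self.theta.copy(),
            self.species.copy(),
            self.radii.copy(),
            self.t,
        )


def init_random(N: int, params: ModelParams, seed=None) -> ParticleState:
    """Uniform random positions and orientations, alternating radii.

    All draws come from one generator seeded by ``seed`` (default: the
    seed stored in ``params``) in the fixed order x, y, theta, so runs are
    bit-reproducible.
    """
    if N % 2:
        raise ConfigError("N must be even: the two populations have equal size")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    x = rng.uniform(0.0, params.Lx, N)
    y = rng.uniform(0.0, params.Ly, N)
    theta = rng.uniform(-np.pi, np.pi, N)
    return ParticleState(
        x=x,
        y=y,
        theta=theta,
        species=assign_species(N),
        radii=assign_radii(N),
    )


@dataclass
class DensityField:
    """Coarse-grained per-species densities on a rectangular grid.

    ``rho_right`` and ``rho_left`` are particle-number densities
    (particles per unit area); ``delta`` is their difference, the field
    whose histogram distinguishes lanes (bimodal) from the mingled liquid
    (Gaussian).
    """

    rho_right: np.ndarray
    rho_left: np.ndarray
    bin_x: float
    bin_y: float
    box: tuple = field(default=None)

    @property
    def delta(self) -> np.ndarray:
        return self.rho_right - self.rho_left

    @property
    def bin_area(self) -> float:
        return self.bin_x * self.bin_y
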