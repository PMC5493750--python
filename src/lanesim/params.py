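"""Microscopic model parameters.

The model has two species of self-propelled particles driven toward
opposite directions (Theta = 0 for right movers, pi for left movers) by a
harmonic angular drive of amplitude ``H``, and interacting through purely
repulsive pairwise torques of amplitude ``B`` with a linearly decaying
kernel of range ``a_i + a_j``.  With the self-propulsion speed ``v0`` and
the drive amplitude fixed to one, the only control parameters left are the
repulsion strength ``B`` and the particle density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

#: the two interaction radii of the bidisperse mixture; polydispersity
#: avoids crystallization artefacts.
RADII = (1.0, 1.4)

#: mean pairwise interaction range, E[a_i + a_j] for the bidisperse mixture.
MEAN_PAIR_RANGE = RADII[0] + RADII[1]


@dataclass(frozen=True)
class ModelParams:
    """All microscopic constants of the torque-coupled binary mixture.

    Parameters
    ----------
    B
        Repulsion torque amplitude (dimensionless, > 0 for a meaningful
        model; B = 0 is the trivially laning limit and is accepted).
    H
        Drive-alignment amplitude, default 1 (the regime analysed
        throughout).
    v0
        Self-propulsion speed, default 1.  All particles move at exactly
        this speed at all times; the dynamics acts on angles only.
    dt
        Forward-Euler time step, default 1e-2.
    Lx, Ly
        Periodic box lengths.  The default geometry is a 2:1 rectangle
        elongated along the drive (``Lx = 2 Ly``); other aspect ratios
        must be explicitly allowed.
    seed
        Seed of the single RNG driving every stochastic operation.
    """

    B: float
    Lx: float
    Ly: float
    H: float = 1.0
    v0: float = 1.0
    dt: float = 1e-2
    seed: int = 0
    allow_aspect_override: bool = field(default=False, repr=False)

    def __post_init__(self):
        if self.B < 0:
            raise ConfigError(f"B must be >= 0, got {self.B}")
        if self.H <= 0:
            raise ConfigError(f"H must be > 0, got {self.H}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ConfigError("box lengths must be positive")
        if not self.allow_aspect_override and not math.isclose(
            self.Lx, 2.0 * self.Ly, rel_tol=1e-9
        ):
            raise ConfigError(
                f"default geometry requires Lx = 2*Ly (got Lx={self.Lx}, "
                f"Ly={self.Ly}); pass allow_aspect_override=True to override"
            )

    # ---------------------------------------------------------------- helpers
    @classmethod
    def for_area_fraction(
        cls, B: float, N: int, area_fraction: float, **kwargs
    ) -> "ModelParams":
        """Box (2:1 aspect) holding ``N`` particles at a given area fraction.

        The area fraction is defined from the interaction disks,
        phi = pi * sum_i a_i**2 / (Lx * Ly).
        """
        disk_area = math.pi * (RADII[0] ** 2 + RADII[1] ** 2) / 2.0 * N
        box_area = disk_area / area_fraction
        Ly = math.sqrt(box_area / 2.0)
        return cls(B=B, Lx=2.0 * Ly, Ly=Ly, **kwargs)

    @classmethod
    def for_number_density(
        cls, B: float, N: int, rho: float, **kwargs
    ) -> "ModelParams":
        """Box (2:1 aspect) holding ``N`` particles at number density rho."""
        Ly = math.sqrt(N / rho / 2.0)
        return cls(B=B, Lx=2.0 * Ly, Ly=Ly, **kwargs)

    @property
    def box_area(self) -> float:
        return self.Lx * self.Ly

    def number_density(self, N: int) -> float:
        return N / self.box_area

    def area_fraction(self, N: int) -> float:
        """phi = pi * sum a_i^2 / (Lx Ly) for the alternating radii scheme."""
        return math.pi * (RADII[0] ** 2 + RADII[1] ** 2) / 2.0 * N / self.box_area

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def assign_radii(N: int) -> np.ndarray:
    """Alternating interaction radii: a = 1.4 for every second particle."""
    radii = np.empty(N)
    radii[0::2] = RADII[0]
    radii[1::2] = RADII[1]
    return radii


def assign_species(N: int) -> np.ndarray:
    """Species labels (+1 right mover, -1 left mover), N/2 per species.

    The pattern +,-,-,+ of period four keeps the populations equal for any
    even N while giving each species both interaction radii.
    """
    if N % 2:
        raise ConfigError("N must be even: the two populations have equal size")
    idx = np.arange(N) % 4
    return np.where((idx == 0) | (idx == 3), 1, -1).astype(np.int8)
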