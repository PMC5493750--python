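"""Microscopic dynamics: torques, neighbour search, Euler integration.

Equations of motion (overdamped, torque-only)::

    dr_i/dt     = v0 * p(theta_i),            p(t) = (cos t, sin t)
    dtheta_i/dt = -H sin(theta_i - Theta_i) + sum_j T_ij
    T_ij        = -B(r_ij) sin(theta_i - phi_ij)

with ``Theta_i`` the preferred direction of particle i's species (0 or
pi), ``phi_ij`` the angle of the centre-to-centre vector r_i - r_j, and
the kernel ``B(r) = B (1 - r / (a_i + a_j))`` for r below the interaction
range and zero beyond.  The pair torque derives from the angular energy
``U_ij = -B(r_ij) cos(theta_i - phi_ij)``: interacting particles turn
their backs to each other.

The two scalar functions :func:`pair_torque` and :func:`drive_torque`
below are the single authoritative definition of the model (the torque
seam); the compiled kernels replicate them for speed and are tested
against them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .errors import DegeneratePairError
from .params import ModelParams
from .state import ParticleState

logger = logging.getLogger(__name__)

__all__ = [
    "pair_torque",
    "drive_torque",
    "neighbor_pairs",
    "euler_step",
    "simulate",
    "SimulationResult",
]


# --------------------------------------------------------------- torque seam
def pair_torque(theta_i, r_i, r_j, a_i, a_j, params: ModelParams) -> float:
    """Torque exerted on particle i by particle j.

    Zero beyond the interaction range ``a_i + a_j``; inside the range the
    torque rotates i toward pointing away from j, with magnitude bounded
    by the kernel ``B(r_ij)``.
    """
    dx = _min_image_scalar(r_i[0] - r_j[0], params.Lx)
    dy = _min_image_scalar(r_i[1] - r_j[1], params.Ly)
    rng = a_i + a_j
    r2 = dx * dx + dy * dy
    if r2 < 1e-24:
        raise DegeneratePairError()
    if r2 >= rng * rng:
        return 0.0
    r = math.sqrt(r2)
    kern = params.B * (1.0 - r / rng)
    phi = math.atan2(dy, dx)
    return -kern * math.sin(theta_i - phi)


def drive_torque(theta, species, params: ModelParams) -> float:
    """Harmonic angular drive toward the species' preferred direction.

    ``species`` is +1 (right, Theta = 0) or -1 (left, Theta = pi).  The
    torque vanishes iff theta equals Theta (mod 2 pi) and restores toward
    it otherwise.
    """
    theta0 = 0.0 if species == 1 else math.pi
    return -params.H * math.sin(theta - theta0)


def _min_image_scalar(d, L):
    d = d - L * round(d / L)
    return d


# ----------------------------------------------------------- neighbour search
def neighbor_pairs(state: ParticleState, params: ModelParams, method="sap"):
    """Interacting pairs (minimum-image distance below a_i + a_j).

    ``method`` is ``"sap"`` (sweep-and-prune broad phase, the production
    path) or ``"brute"`` (all-pairs oracle).  Narrow boxes fall back to
    the brute-force scan, since the pruning window would wrap onto
    itself.  Returns a sorted array of unordered index pairs, shape
    (n_pairs, 2) with i < j.
    """
    if method == "sap" and params.Lx >= 4.0 * _kernels.A_MAX + 1e-9:
        ii, jj = _kernels.pairs_sap(
            state.x, state.y, state.radii, params.Lx, params.Ly
        )
    else:
        ii, jj = _kernels.pairs_brute(
            state.x, state.y, state.radii, params.Lx, params.Ly
        )
    pairs = np.stack([np.minimum(ii, jj), np.maximum(ii, jj)], axis=1)
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return pairs


# ------------------------------------------------------------------ stepping
def _use_sap(params: ModelParams) -> bool:
    return params.Lx >= 4.0 * _kernels.A_MAX + 1e-9


def euler_step(state: ParticleState, params: ModelParams) -> ParticleState:
    """One forward-Euler step; returns a new state, input left untouched."""
    new = state.copy()
    order = np.argsort(new.x).astype(np.int64)
    dummy = np.empty(0)
    status = _kernels.advance(
        new.x, new.y, new.theta, dummy, dummy,  # unwrapped tracking off
        new.radii, new.preferred_angle, order,
        params.B, params.H, params.v0, params.dt, params.Lx, params.Ly,
        1, False, _use_sap(params),
    )
    if status == _kernels.STATUS_DEGENERATE:
        raise DegeneratePairError(_find_degenerate(state, params))
    new.t = state.t + params.dt
    return new


def _find_degenerate(state, params):
    pos = np.stack([state.x, state.y], axis=1)
    for i in range(state.N):
        d = pos - pos[i]
        d[:, 0] -= params.Lx * np.round(d[:, 0] / params.Lx)
        d[:, 1] -= params.Ly * np.round(d[:, 1] / params.Ly)
        r2 = np.sum(d * d, axis=1)
        r2[i] = np.inf
        j = int(np.argmin(r2))
        if r2[j] < 1e-24:
            return (min(i, j), max(i, j))
    return None


@dataclass
class SimulationResult:
    """Output of :func:`simulate`.

    ``times``/``W`` sample the orientational order parameter at the
    requested cadence; optional per-sample orientation and unwrapped
    displacement arrays support diffusivity measurements, and snapshots
    support structural analysis.
    """

    state: ParticleState
    times: np.ndarray
    W: np.ndarray
    theta_samples: Optional[np.ndarray] = None
    ux_samples: Optional[np.ndarray] = None
    uy_samples: Optional[np.ndarray] = None
    snapshots: Optional[list] = None
    snapshot_times: Optional[list] = None


def simulate(
    state: ParticleState,
    params: ModelParams,
    steps: int,
    sample_every: int = 100,
    record_theta: bool = False,
    record_unwrapped: bool = False,
    snapshot_every: Optional[int] = None,
    log_every: Optional[int] = None,
) -> SimulationResult:
    """Integrate the equations of motion for ``steps`` Euler steps.

    The input state is not modified.  ``sample_every`` sets the cadence
    (in steps) of the order-parameter series and of the optional theta /
    unwrapped-displacement records; ``snapshot_every`` stores full
    configuration copies.
    """
    from .observables import order_parameter

    s = state.copy()
    n = s.N
    theta0 = s.preferred_angle
    order = np.argsort(s.x).astype(np.int64)
    ux = np.zeros(n)
    uy = np.zeros(n)
    use_sap = _use_sap(params)

    nsamp = steps // sample_every
    times = np.empty(nsamp + 1)
    W = np.empty(nsamp + 1)
    times[0] = s.t
    W[0] = order_parameter(s)
    theta_samples = np.empty((nsamp + 1, n)) if record_theta else None
    ux_samples = np.empty((nsamp + 1, n)) if record_unwrapped else None
    uy_samples = np.empty((nsamp + 1, n)) if record_unwrapped else None
    if record_theta:
        theta_samples[0] = s.theta
    if record_unwrapped:
        ux_samples[0] = ux
        uy_samples[0] = uy
    snapshots = [] if snapshot_every else None
    snapshot_times = [] if snapshot_every else None

    stride = sample_every
    if snapshot_every:
        stride = math.gcd(int(sample_every), int(snapshot_every))
    done = 0
    isamp = 0
    while done < steps:
        chunk = min(stride, steps - done)
        status = _kernels.advance(
            s.x, s.y, s.theta, ux, uy, s.radii, theta0, order,
            params.B, params.H, params.v0, params.dt, params.Lx, params.Ly,
            chunk, record_unwrapped, use_sap,
        )
        if status == _kernels.STATUS_DEGENERATE:
            raise DegeneratePairError(_find_degenerate(s, params))
        done += chunk
        s.t += chunk * params.dt
        if done % sample_every == 0:
            isamp += 1
            times[isamp] = s.t
            W[isamp] = order_parameter(s)
            if record_theta:
                theta_samples[isamp] = s.theta
            if record_unwrapped:
                ux_samples[isamp] = ux
                uy_samples[isamp] = uy
        if snapshot_every and done % snapshot_every == 0:
            snapshots.append(s.copy())
            snapshot_times.append(s.t)
        if log_every and done % log_every == 0:
            logger.info(
                "step %d/%d t=%.2f W=%.4f", done, steps, s.t, W[isamp]
            )
    return SimulationResult(
        state=s,
        times=times[: isamp + 1],
        W=W[: isamp + 1],
        theta_samples=theta_samples[: isamp + 1] if record_theta else None,
        ux_samples=ux_samples[: isamp + 1] if record_unwrapped else None,
        uy_samples=uy_samples[: isamp + 1] if record_unwrapped else None,
        snapshots=snapshots,
        snapshot_times=snapshot_times,
    )
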