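import math

import numpy as np
import pytest

from lanesim import ModelParams, ParticleState, init_random


@pytest.fixture
def small_params():
    return ModelParams(B=3.0, Lx=40.0, Ly=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_state(N, params, seed):
    return init_random(N, params, seed=seed)


def scalar_reference_step(state: ParticleState, params: ModelParams):
    """Independent plain-python transcription of the equations of motion.

    One forward-Euler step computed with explicit loops and its own
    minimum-image arithmetic; used as an oracle for the compiled path.
    """
    n = state.N
    x, y, th = state.x.copy(), state.y.copy(), state.theta.copy()
    torque = np.zeros(n)
    for i in range(n):
        theta0 = 0.0 if state.species[i] == 1 else math.pi
        torque[i] += -params.H * math.sin(th[i] - theta0)
        for j in range(n):
            if j == i:
                continue
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            dx -= params.Lx * round(dx / params.Lx)
            dy -= params.Ly * round(dy / params.Ly)
            r = math.hypot(dx, dy)
            rng_ij = state.radii[i] + state.radii[j]
            if r >= rng_ij or r == 0.0:
                continue
            kern = params.B * (1.0 - r / rng_ij)
            phi = math.atan2(dy, dx)
            torque[i] += -kern * math.sin(th[i] - phi)
    nx = np.empty(n)
    ny = np.empty(n)
    nth = np.empty(n)
    for i in range(n):
        nx[i] = (x[i] + params.v0 * math.cos(th[i]) * params.dt) % params.Lx
        ny[i] = (y[i] + params.v0 * math.sin(th[i]) * params.dt) % params.Ly
        nth[i] = th[i] + params.dt * torque[i]
    out = state.copy()
    out.x, out.y, out.theta = nx, ny, nth
    out.t = state.t + params.dt
    return out
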