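"""Extended-XYZ trajectory I/O.

One frame per stored step; per-row fields species, x, y, theta, radius,
with the frame comment recording time, B, H, v0 and the box.  Angles are
stored in radians (wrapped to (-pi, pi]).  Values round-trip at full
double precision.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .errors import ConfigError
from .params import ModelParams
from .state import ParticleState

__all__ = ["write_frames", "read_frames"]

_SPECIES_NAME = {1: "R", -1: "L"}
_SPECIES_CODE = {"R": 1, "L": -1}


def write_frames(path, states, params: Optional[ModelParams] = None) -> None:
    """Write a list of states as an extended-XYZ trajectory."""
    if isinstance(states, ParticleState):
        states = [states]
    with open(path, "w") as fh:
        for s in states:
            fh.write(f"{s.N}\n")
            comment = (
                'Properties=species:S:1:pos:R:2:theta:R:1:radius:R:1 '
                f"Time={float(s.t)!r}"
            )
            if params is not None:
                comment += (
                    f' Lattice="{params.Lx!r} 0.0 0.0 {params.Ly!r}"'
                    f" B={params.B!r} H={params.H!r} v0={params.v0!r}"
                )
            fh.write(comment + "\n")
            theta = s.theta_wrapped()
            for i in range(s.N):
                fh.write(
                    f"{_SPECIES_NAME[int(s.species[i])]} {float(s.x[i])!r} "
                    f"{float(s.y[i])!r} {float(theta[i])!r} "
                    f"{float(s.radii[i])!r}\n"
                )


def read_frames(path) -> List[ParticleState]:
    """Read an extended-XYZ trajectory written by :func:`write_frames`.

    Frames with unequal species populations are rejected with an error
    naming the frame (the model requires two equal groups).
    """
    states = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ConfigError(
                f"frame {frame}: bad particle count line {lines[pos]!r}"
            ) from exc
        comment = lines[pos + 1]
        t = 0.0
        for tok in comment.split():
            if tok.startswith("Time="):
                t = float(tok[5:])
        rows = lines[pos + 2: pos + 2 + n]
        if len(rows) < n:
            raise ConfigError(f"frame {frame}: truncated ({len(rows)}/{n} rows)")
        species = np.empty(n, dtype=np.int8)
        x = np.empty(n)
        y = np.empty(n)
        theta = np.empty(n)
        radii = np.empty(n)
        for i, row in enumerate(rows):
            parts = row.split()
            if len(parts) != 5:
                raise ConfigError(f"frame {frame}, row {i}: expected 5 fields")
            if parts[0] not in _SPECIES_CODE:
                raise ConfigError(
                    f"frame {frame}, row {i}: unknown species {parts[0]!r}"
                )
            species[i] = _SPECIES_CODE[parts[0]]
            x[i], y[i], theta[i], radii[i] = map(float, parts[1:])
        if np.count_nonzero(species == 1) != np.count_nonzero(species == -1):
            raise ConfigError(
                f"frame {frame}: unequal species counts "
                f"({np.count_nonzero(species == 1)} right, "
                f"{np.count_nonzero(species == -1)} left)"
            )
        states.append(ParticleState(x, y, theta, species, radii, t))
        pos += 2 + n
        frame += 1
    return states
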