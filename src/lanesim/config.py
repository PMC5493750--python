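"""Configuration files, run manifests and reproducible seeding."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .params import ModelParams

logger = logging.getLogger(__name__)

__all__ = ["RunOptions", "read_config", "RunManifest"]

_CONFIG_KEYS = {"B", "H", "v0", "dt", "Lx", "Ly", "N", "seed", "steps",
                "save_every"}
_DEFAULTS = {"H": 1.0, "v0": 1.0, "dt": 1e-2, "seed": 0, "save_every": 0}


@dataclass
class RunOptions:
    """Non-physics run options read alongside the model parameters."""

    N: int
    steps: int
    save_every: int = 0


def read_config(path, allow_aspect_override: bool = False):
    """Read a YAML config into (ModelParams, RunOptions).

    Keys: B, H, v0, dt, Lx, Ly, N, seed, steps, save_every; unknown keys
    are rejected, physics defaults (H = 1, v0 = 1, dt = 1e-2) fill gaps.
    Ly may be omitted (Ly = Lx / 2).  B = 0 is accepted with a warning:
    it is the degenerate limit that trivially forms full-box lanes.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("B", "N", "steps"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key!r}")
    if "Lx" not in raw and "Ly" not in raw:
        raise ConfigError("missing required config key: 'Lx' (or 'Ly')")
    merged = {**_DEFAULTS, **raw}
    if "Ly" not in merged:
        merged["Ly"] = merged["Lx"] / 2.0
    if "Lx" not in merged:
        merged["Lx"] = merged["Ly"] * 2.0
    if merged["B"] == 0:
        logger.warning("B = 0: degenerate laned limit (no repulsion)")
    try:
        params = ModelParams(
            B=float(merged["B"]),
            H=float(merged["H"]),
            v0=float(merged["v0"]),
            dt=float(merged["dt"]),
            Lx=float(merged["Lx"]),
            Ly=float(merged["Ly"]),
            seed=int(merged["seed"]),
            allow_aspect_override=allow_aspect_override,
        )
    except ConfigError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    n = int(merged["N"])
    if n <= 0 or n % 2:
        raise ConfigError(f"key 'N': must be a positive even integer, got {n}")
    opts = RunOptions(
        N=n, steps=int(merged["steps"]), save_every=int(merged["save_every"])
    )
    return params, opts


@dataclass
class RunManifest:
    """Snapshot of everything needed to regenerate a run's outputs."""

    command: str
    config: dict
    seed: int
    outputs: list = field(default_factory=list)
    version: str = ""
    started: str = ""
    wall_seconds: float = 0.0

    @classmethod
    def start(cls, command: str, config: dict, seed: int) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config,
            seed=seed,
            version=__version__,
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def finish(self, out_dir, outputs, t0: float) -> Path:
        self.outputs = [str(o) for o in outputs]
        self.wall_seconds = time.monotonic() - t0
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
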