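"""Run configuration: tolerances, constants and grids, overridable from YAML."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from pathlib import Path

from . import __version__
from .constants import HARTREE_TO_KCAL, IND_MAX_THRESHOLD, WTMAD2_REFERENCE_KCAL

__all__ = ["RunConfig", "load_config", "write_manifest"]

log = logging.getLogger("cdscs")


@dataclasses.dataclass
class RunConfig:
    """Defaults for every tunable the pipeline exposes."""

    scf_energy_tol: float = 1e-9
    scf_density_tol: float = 1e-7
    hartree_to_kcal: float = HARTREE_TO_KCAL
    wtmad2_constant: float = WTMAD2_REFERENCE_KCAL
    multiref_threshold: float = IND_MAX_THRESHOLD
    grid_n_radial: int = 35
    grid_n_theta: int = 10
    grid_n_phi: int = 20
    intracule_r_max: float = 15.0
    intracule_bin_width: float = 0.05
    pair_count_tol: float = 1e-2
    frozen_core: bool = False

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    import yaml

    cfg = RunConfig.from_mapping(yaml.safe_load(Path(path).read_text()) or {})
    log.info("loaded config from %s: %s", path, dataclasses.asdict(cfg))
    return cfg


def write_manifest(path: str | Path, command: str, inputs: dict,
                   seed: int | None = None) -> None:
    """Machine-readable record of a run (inputs, seed, versions)."""
    manifest = {
        "command": command,
        "inputs": inputs,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("manifest written to %s", path)
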