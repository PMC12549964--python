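"""Run configuration: defaults, YAML round-trip, and deterministic seed splitting."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["RunConfig", "spawn_seeds"]


@dataclass
class RunConfig:
    """Parameters for one end-to-end simulate-and-retrieve run.

    The defaults reproduce the reference study conditions at full scale:
    100 explosion realizations per structure, 100 patterns per realization
    (so ``n_simulations * patterns_per_simulation`` total patterns), mean
    ionization 1.2 charges/atom, detector efficiencies {0.3, 0.6, 1.0},
    blur sigma 0.5 px and a 100-bin envelope.  Tests and examples override
    the counts downwards.
    """

    label: str = "run"
    pdb_path: str | None = None  # mutually exclusive with n_atoms synthesis
    n_atoms: int = 1000
    n_simulations: int = 100
    patterns_per_simulation: int = 100
    mean_ionization: float = 1.2
    fluence: float = 5.0e6  # photons/nm^2
    efficiencies: tuple[float, ...] = (0.3, 0.6, 1.0)
    blur_sigma: float = 0.5
    envelope_bins: int = 100
    jitter_sigma: float = 0.3  # A, per-realization structural heterogeneity
    radius_scale: float = 1.0
    dt: float = 0.5  # fs
    max_time: float = 250.0  # fs
    softening: float = 0.1  # A
    master_seed: int = 0
    out_dir: str = "runs/out"

    def __post_init__(self):
        self.efficiencies = tuple(float(e) for e in self.efficiencies)
        if any(not 0.0 <= e <= 1.0 for e in self.efficiencies):
            raise ValueError("efficiencies must lie in [0, 1]")
        if self.n_simulations < 1 or self.patterns_per_simulation < 1:
            raise ValueError("n_simulations and patterns_per_simulation must be >= 1")

    @property
    def total_patterns(self) -> int:
        return self.n_simulations * self.patterns_per_simulation

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "efficiencies" in data:
            data["efficiencies"] = tuple(data["efficiencies"])
        return cls(**data)


def spawn_seeds(master_seed: int, *path: int) -> np.random.SeedSequence:
    """Counter-based seed splitting: one independent stream per (stage, index...) path.

    Uses numpy's ``SeedSequence`` spawn keys directly, so the stream for a
    given path is reproducible regardless of execution order — safe under
    parallel or partial runs.
    """
    return np.random.SeedSequence(master_seed, spawn_key=path)
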