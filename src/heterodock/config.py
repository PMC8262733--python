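"""Pipeline configuration: every threshold used by the pipeline, as one
dataclass with YAML round-trip and CLI-flag override support.

Defaults carry the published operating point of the method: subunit and
interface TM-score thresholds 0.4, model-redundancy TM-score 0.8, 50-model
cap, 70% identity cap for the monomer/homo-oligomer library, 4.0 Å
resolution cutoff for the heterodimer library, top-200 sequence ranks, and
the <1000-residue subunit limit.  Physical-filter thresholds and the
template-score weights are this package's declared choices.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # template-search thresholds
    tm_subunit: float = 0.4        # subunit TM-score must exceed this
    tm_interface: float = 0.4      # interface TM-score below this is discarded
    top_k: int = 200               # sequence-path rank depth per subunit
    max_hits: int = 2000           # resource guard on stored hits

    # library construction
    identity_cap: float = 0.7      # DB-Mo/Ho mutual identity cap (also DB-Het pairs)
    resolution_max: float = 4.0    # DB-Het resolution cutoff, Å
    contact_cutoff: float = 8.0    # interface residue CA/CB cutoff, Å
    domain_min_len: int = 30
    domain_density: float = 0.04

    # model filtering
    max_clash_fraction: float = 0.1
    min_contacts: int = 5
    min_interface_area: float = 300.0   # Å²
    clash_distance: float = 3.0         # Å

    # scoring / ranking
    w_subunit: float = 1.0
    w_interface: float = 2.0
    tm_redundancy: float = 0.8
    max_models: int = 50

    # input handling
    min_chain_len: int = 10
    max_subunit_len: int = 1000

    # run control
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("tm_subunit", "tm_interface", "identity_cap", "tm_redundancy",
                     "max_clash_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("resolution_max", "contact_cutoff", "min_interface_area",
                     "clash_distance", "w_subunit", "w_interface"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("top_k", "max_hits", "max_models", "min_chain_len",
                     "max_subunit_len", "domain_min_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def with_overrides(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        for k, v in overrides.items():
            if v is None:
                continue
            if k not in data:
                raise ValueError(f"unknown config key {k!r}")
            data[k] = v
        return PipelineConfig(**data)
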