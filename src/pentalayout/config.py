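"""Run configuration: one YAML/JSON document with validation and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Tuple

import yaml

from .clustering import ClusterSweepConfig
from .stoichiometry import GateWindows

__all__ = ["RunConfig", "validate_config", "load_config"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Either ``inputs`` (paths plus dialects) or ``synthetic`` (truth
    parameters for the generators) must be present.
    """

    seed: int = 1
    out_dir: str = "results"
    inputs: Dict[str, str] = field(default_factory=dict)
    synthetic: Dict[str, object] = field(
        default_factory=lambda: {
            "n_subjects": 6,
            "subject_sd": 0.3,
            "regional_sd": 1.0,
            "probes_per_gene": 4,
            "probe_noise_sd": 0.2,
            "nuclei_per_type": 100,
        }
    )
    noise_log2: float = 4.0
    enrich_fold: float = 5.0
    alpha: float = 0.05
    min_support: int = 2
    gate: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (40, 5), "beta": (40, 5), "chi": (20, 5)}
    )
    sweep: Dict[str, object] = field(default_factory=dict)
    reference: str = "Fro"
    transforms: Tuple[str, ...] = ("log2", "proportional")
    stages: Tuple[str, ...] = ("preprocess", "cluster", "stoich", "layout")

    def gate_windows(self) -> GateWindows:
        return GateWindows(
            alpha=tuple(self.gate["alpha"]),
            beta=tuple(self.gate["beta"]),
            chi=tuple(self.gate["chi"]),
        )

    def sweep_config(self) -> ClusterSweepConfig:
        kwargs = dict(self.sweep)
        for key in ("sigma_grid", "k_grid", "transforms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return ClusterSweepConfig(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("out_dir", None)  # where a run lands is not part of what it is
        text = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def validate_config(config: RunConfig) -> List[str]:
    """Return a list of violations; an empty list means the config is ok."""
    problems: List[str] = []
    if not config.inputs and not config.synthetic:
        problems.append("neither input paths nor synthetic truth provided")
    if config.seed < 0:
        problems.append("seed must be nonnegative")
    if not 0 < config.alpha < 1:
        problems.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.min_support < 1:
        problems.append(f"min_support must be >= 1, got {config.min_support}")
    if config.noise_log2 <= 0:
        problems.append(f"noise_log2 must be positive, got {config.noise_log2}")
    if config.enrich_fold <= 1:
        problems.append(f"enrich_fold must exceed 1, got {config.enrich_fold}")
    try:
        config.gate_windows()
    except (ValueError, KeyError) as exc:
        problems.append(f"invalid gate windows: {exc}")
    try:
        sweep = config.sweep_config()
        if not sweep.sigma_grid:
            problems.append("empty sigma grid")
    except (ValueError, TypeError) as exc:
        problems.append(f"invalid sweep config: {exc}")
    unknown = set(config.stages) - {"preprocess", "cluster", "stoich", "layout"}
    if unknown:
        problems.append(f"unknown stages: {sorted(unknown)}")
    bad_transforms = set(config.transforms) - {"log2", "proportional"}
    if bad_transforms:
        problems.append(f"unknown transforms: {sorted(bad_transforms)}")
    return problems


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**payload)
    for key in ("transforms", "stages"):
        setattr(cfg, key, tuple(getattr(cfg, key)))
    return cfg
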