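"""Run configuration: a YAML file fully determining a reproducible run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

_KNOWN_BLOCKS = {
    "architecture", "incidence", "mortality", "population", "cohort", "analysis", "output",
}


@dataclass
class RunConfig:
    """Everything a run needs besides the seed.

    Blocks mirror the pipeline stages: ``architecture`` (target_h2 and
    optionally maf_values / or_values / n_snps), ``incidence`` (a bundled
    disease preset name, or family + parameters), ``mortality`` (a CSV path
    or ``synthetic``), ``population`` (n, seed), ``cohort`` (span,
    min_prevalence, age_step) and ``analysis`` (designs, target_power,
    bias_mode).
    """

    architecture: dict = field(default_factory=lambda: {"target_h2": 0.41})
    incidence: dict = field(default_factory=lambda: {"preset": "stroke"})
    mortality: dict = field(default_factory=lambda: {"source": "synthetic"})
    population: dict = field(default_factory=lambda: {"n": 100_000, "seed": 1})
    cohort: dict = field(
        default_factory=lambda: {"span": 10, "min_prevalence": 0.0025, "age_step": 1}
    )
    analysis: dict = field(
        default_factory=lambda: {
            "designs": ["age_matched", "young_cases_old_controls"],
            "target_power": 0.8,
            "bias_mode": "best_power",
            "bias_age_step": 5,
        }
    )
    output: dict = field(default_factory=lambda: {"directory": "lodsim_out"})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def echo(self, directory) -> None:
        """Write the effective configuration into the output directory."""
        Path(directory).mkdir(parents=True, exist_ok=True)
        with open(Path(directory) / "config.yaml", "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(
            f"{path}: unknown configuration blocks {sorted(unknown)}; "
            f"known blocks are {sorted(_KNOWN_BLOCKS)}"
        )
    cfg = RunConfig()
    for block, value in raw.items():
        if not isinstance(value, dict):
            raise ValueError(f"{path}: block {block!r} must be a mapping")
        merged = dict(getattr(cfg, block))
        merged.update(value)
        setattr(cfg, block, merged)
    return cfg
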