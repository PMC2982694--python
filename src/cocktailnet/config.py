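"""Run configuration: one validated object carries every numeric convention.

All tunable conventions (solver backend, PPI evidence threshold, cell line,
lambda, R-grid step, ratio-combination mode, weight function, seed) flow
through :class:`RunConfig` so the pipeline stages themselves stay pure.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import yaml

from .combine import MODES
from .expression import WEIGHT_FUNCTIONS

logger = logging.getLogger(__name__)

SOLVERS = ("highs",)
LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class RunConfig:
    solver: str = "highs"
    min_methods: int = 2
    cell_line: str = "MCF7"
    lam: float = 0.5
    r_step: int = 1
    combine_mode: str = "saturating"
    weight_fn: str = "abs_log2"
    seed: int = 0
    log_level: str = "INFO"

    # YAML key -> field name (lambda is a Python keyword)
    _ALIASES = {"lambda": "lam"}

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValueError(f"solver: unknown backend {self.solver!r}")
        if self.min_methods < 0:
            raise ValueError("min_methods: must be >= 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda: must be in [0, 1], got {self.lam}")
        if self.r_step < 1:
            raise ValueError("r_step: must be >= 1")
        if self.combine_mode not in MODES:
            raise ValueError(f"combine_mode: must be one of {MODES}")
        if self.weight_fn not in WEIGHT_FUNCTIONS:
            raise ValueError(f"weight_fn: unknown function {self.weight_fn!r}")
        if self.log_level not in LOG_LEVELS:
            raise ValueError(f"log_level: must be one of {LOG_LEVELS}")
        self.seed = int(self.seed)

    def weight_function(self):
        return WEIGHT_FUNCTIONS[self.weight_fn]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda"] = d.pop("lam")
        return d


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Load a YAML config file (or defaults); unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    fields = {f.name for f in dataclasses.fields(RunConfig)} - {"_ALIASES"}
    kwargs = {}
    for key, value in data.items():
        name = RunConfig._ALIASES.get(key, key)
        if name not in fields:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[name] = value
    cfg = RunConfig(**kwargs)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg
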