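"""Analysis configuration.

Defaults mirror the study conventions the pipeline implements: feature-level
significance at FDR 0.05, feature-trait correlation filters at P < 0.01
(primary) and P < 0.05 (secondary), and module retention at >= 3 members with
average within-module |r| > 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import yaml

log = logging.getLogger("gxd")

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    fdr_q: float = 0.05
    corr_p_primary: float = 0.01
    corr_p_secondary: float = 0.05
    module_min_size: int = 3
    module_min_avg_corr: float = 0.5
    correlation_method: str = "pearson"  # pearson | spearman
    sharpness_grid: list[float] = field(default_factory=lambda: [float(s) for s in range(1, 31)])
    rng_seed: int = 0
    replicate_collapse: str = "line_diet"  # line_diet | line_diet_replicate

    def __post_init__(self) -> None:
        for key in ("fdr_q", "corr_p_primary", "corr_p_secondary"):
            v = getattr(self, key)
            if not (0.0 < float(v) < 1.0):
                raise ValueError(f"{key}={v!r} out of range: must lie in (0, 1)")
            setattr(self, key, float(v))
        if not (0.0 <= float(self.module_min_avg_corr) <= 1.0):
            raise ValueError(
                f"module_min_avg_corr={self.module_min_avg_corr!r} out of range: must lie in [0, 1]"
            )
        if int(self.module_min_size) < 1:
            raise ValueError(f"module_min_size={self.module_min_size!r}: must be >= 1")
        self.module_min_size = int(self.module_min_size)
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(
                f"correlation_method={self.correlation_method!r}: must be pearson or spearman"
            )
        grid = [float(s) for s in self.sharpness_grid]
        if not grid:
            raise ValueError("sharpness_grid must be nonempty")
        if any(s <= 0 for s in grid):
            raise ValueError("sharpness_grid values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sharpness_grid must be strictly increasing")
        self.sharpness_grid = grid
        if self.replicate_collapse not in ("line_diet", "line_diet_replicate"):
            raise ValueError(
                f"replicate_collapse={self.replicate_collapse!r}: "
                "must be line_diet or line_diet_replicate"
            )
        self.rng_seed = int(self.rng_seed)


def load_config(path: str | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Absent keys take their defaults; keyword overrides win over the file.
    The effective configuration is echoed to the ``gxd`` logger.
    """
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path!r} must contain a key/value mapping")
        known = {f.name for f in fields(AnalysisConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    cfg = AnalysisConfig(**values)
    log.info("effective config: %s", cfg)
    return cfg
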