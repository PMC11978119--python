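"""Analysis configuration (YAML-serialisable)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .costs import (DEFAULT_DISCOUNT_RATE, DEFAULT_EXCHANGE_RATE,
                    DEFAULT_TERMINAL_WINDOW)
from .extrapolate import ExtrapolationConfig
from .lifetable import DEFAULT_AGE_CAP


@dataclass
class AnalysisConfig:
    """End-to-end pipeline settings.

    extrapolation: rolling-window / spline / estimability tunables.
    n_replicates: Monte Carlo referents per patient.
    age_cap: simulation stops at this attained age (qx beyond the table = 1).
    terminal_window_K: months before death pooled into the terminal cost
    profile. discount_rate is annual; exchange_rate is TWD per USD; cpi maps
    calendar year to a price-index multiplier (pass-through, default none).
    bootstrap_B: patient-level bootstrap replicates for standard errors
    (0 disables). seed drives every stochastic stage.
    """
    extrapolation: ExtrapolationConfig = field(default_factory=ExtrapolationConfig)
    n_replicates: int = 100
    age_cap: int = DEFAULT_AGE_CAP
    terminal_window_K: int = DEFAULT_TERMINAL_WINDOW
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    exchange_rate: float = DEFAULT_EXCHANGE_RATE
    cost_per_year_method: str = "undiscounted_total_over_le"
    cpi: dict[int, float] = field(default_factory=dict)
    bootstrap_B: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        extra = raw.pop("extrapolation", {})
        cfg = cls(**raw)
        cfg.extrapolation = ExtrapolationConfig(**extra)
        if cfg.cpi:
            cfg.cpi = {int(k): float(v) for k, v in cfg.cpi.items()}
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
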