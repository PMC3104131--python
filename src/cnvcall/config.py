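"""Run configuration: every tunable threshold of the calling pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Union

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Thresholds and model parameters for one pipeline run.

    Attributes
    ----------
    min_probes:
        Minimum number of probes for a call to survive filtering; events with
        fewer probes are eliminated.
    merge_gap_bp:
        Consecutive same-state probes less than this many bp apart are merged
        into one segment (strict ``<``).
    bridge_max_probes, bridge_max_bp:
        Two same-state segments separated by at most this many intervening
        probes AND at most this many bp are joined into a single variant.
    emission_mean_shift:
        Distance, in z-units, of the gain/loss emission means from the normal
        mean (gain at +shift, loss at -shift; all emission sds are 1).
    state_self_transition:
        Probability of staying in the current HMM state per probe step;
        the two off-diagonal probabilities split the remainder equally.
    common_overlap_fraction:
        Reciprocal-overlap fraction at or above which a call matches a
        control-catalog interval (common) or a parent call (inherited).
    large_event_thresholds_mb:
        Size cutoffs (Mb, strict ``>``) for the cohort burden comparison.
    """

    min_probes: int = 5
    merge_gap_bp: int = 50_000
    bridge_max_probes: int = 5
    bridge_max_bp: int = 10_000
    emission_mean_shift: float = 2.0
    state_self_transition: float = 0.99
    common_overlap_fraction: float = 0.5
    large_event_thresholds_mb: List[float] = field(default_factory=lambda: [1.0, 2.0])
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_probes", "merge_gap_bp", "bridge_max_probes", "bridge_max_bp",
                     "emission_mean_shift"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.state_self_transition < 1.0:
            raise ConfigError(
                f"state_self_transition must lie in (0, 1), got {self.state_self_transition}"
            )
        if not 0.0 < self.common_overlap_fraction <= 1.0:
            raise ConfigError(
                f"common_overlap_fraction must lie in (0, 1], got {self.common_overlap_fraction}"
            )
        if any(t <= 0 for t in self.large_event_thresholds_mb):
            raise ConfigError("large_event_thresholds_mb must all be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **overrides) -> "RunConfig":
        """Return a copy with non-None overrides applied (CLI flags beat YAML)."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
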