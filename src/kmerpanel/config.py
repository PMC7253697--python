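"""Run-wide configuration with the pipeline's default parameters."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

from .detector import DEFAULT_THRESHOLDS
from .errors import FormatError

logger = logging.getLogger("kmerpanel")

DEFAULT_SUBSAMPLE_SIZES = [
    1_000, 10_000, 100_000, 250_000, 500_000, 1_000_000, 10_000_000, 100_000_000,
]


@dataclass
class RunConfig:
    k: int = 32
    min_freq: int = 1
    removal_min_freq: int = 1
    thresholds: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    subsample_sizes: list[int] = field(
        default_factory=lambda: list(DEFAULT_SUBSAMPLE_SIZES)
    )
    seed: int = 0
    trim_quality: int = 35
    trim_min_length: int = 32
    verbosity: int = 1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load overrides from a JSON config file; unknown keys are errors."""
        with open(path) as handle:
            try:
                data = json.load(handle)
            except json.JSONDecodeError as exc:
                raise FormatError(f"bad config file: {exc}", source=path) from None
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(
                f"unknown config keys: {sorted(unknown)}", source=path
            )
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """New config with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def log_effective(self) -> None:
        logger.info("effective config: %s", dataclasses.asdict(self))
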