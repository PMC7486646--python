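"""Flat, versioned pipeline configuration with YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .arima import DifferenceSpec
from .combine import METHODS

__all__ = ["PipelineConfig"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, in one flat document.

    Unknown keys in a config file are errors, not warnings; every field is
    validated with a named message before any computation starts.
    """

    schema_version: int = SCHEMA_VERSION
    # differencing / MA model
    d: int = 1
    D: int = 1
    s: int = 7
    q: int = 7
    q_search: list | None = None        # e.g. [1, 2, ..., 7]; overrides q
    log_transform: bool = False
    # smoothing
    alpha_mode: str = "auto"            # "auto" or "manual"
    alphas: list | None = None          # 7 values when alpha_mode == "manual"
    alpha_objective: str = "mse"
    # combination
    weight_method: str = "cls"          # or "inverse-error", "bates-granger"
    manual_weights: list | None = None  # [w1, w2]; overrides weight_method
    # rolling plan
    fit_weeks: list = field(default_factory=lambda: [1, 52])
    test_weeks: list = field(default_factory=lambda: [53, 60])
    # outlier screening
    sd_multiple: float = 2.0
    replacement_mode: str = "nearest"   # or "preceding"
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"schema_version: expected {SCHEMA_VERSION}, "
                             f"got {self.schema_version}")
        if self.d < 0 or self.D < 0 or self.s < 1:
            raise ValueError("d, D must be >= 0 and s >= 1")
        if self.q < 1:
            raise ValueError(f"q: must be >= 1, got {self.q}")
        if self.q_search is not None and (
                not self.q_search or any(int(x) < 1 for x in self.q_search)):
            raise ValueError("q_search: must be a non-empty list of orders >= 1")
        if self.alpha_mode not in ("auto", "manual"):
            raise ValueError(f"alpha_mode: 'auto' or 'manual', "
                             f"got {self.alpha_mode!r}")
        if self.alpha_mode == "manual":
            if self.alphas is None or len(self.alphas) != 7:
                raise ValueError("alphas: manual mode needs exactly 7 values")
            if any(not 0 < float(a) < 1 for a in self.alphas):
                raise ValueError("alphas: values must lie in (0, 1)")
        if self.alpha_objective not in ("mse", "mape"):
            raise ValueError(f"alpha_objective: 'mse' or 'mape', "
                             f"got {self.alpha_objective!r}")
        if self.manual_weights is not None:
            if len(self.manual_weights) != 2:
                raise ValueError("manual_weights: needs exactly [w1, w2]")
            if abs(sum(map(float, self.manual_weights)) - 1.0) > 1e-9:
                raise ValueError("manual_weights: w1 + w2 must equal 1")
        elif self.weight_method not in METHODS:
            raise ValueError(f"weight_method: one of {METHODS}, "
                             f"got {self.weight_method!r}")
        for name in ("fit_weeks", "test_weeks"):
            rng = getattr(self, name)
            if len(rng) != 2 or int(rng[0]) > int(rng[1]):
                raise ValueError(f"{name}: expected [first, last] with "
                                 f"first <= last, got {rng}")
        if int(self.test_weeks[0]) != int(self.fit_weeks[1]) + 1:
            raise ValueError("test_weeks must start right after fit_weeks")
        if self.sd_multiple <= 0:
            raise ValueError(f"sd_multiple: must be > 0, got {self.sd_multiple}")
        if self.replacement_mode not in ("nearest", "preceding"):
            raise ValueError(f"replacement_mode: 'nearest' or 'preceding', "
                             f"got {self.replacement_mode!r}")

    def difference_spec(self) -> DifferenceSpec:
        return DifferenceSpec(d=self.d, D=self.D, s=self.s)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
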