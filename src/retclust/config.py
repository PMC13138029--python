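"""Analysis configuration: one validated document for the whole pipeline.

All lengths are micrometres. Defaults mirror the measurement procedure the
package implements: a 10 μm center-to-center linkage radius (~1.5 nuclear
diameters) for the proximity graph, 60 μm axial sub-stacks capped at 30
clusters each, a Gaussian KDE with Scott's bandwidth, and the calibrated
thresholds of the laminated/clustered architecture call.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Union

import pydantic
import yaml

from .errors import ConfigError


class AnalysisConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", frozen=True)

    linkage_radius_um: float = pydantic.Field(default=10.0, gt=0)
    substack_depth_um: float = pydantic.Field(default=60.0, gt=0)
    max_clusters_per_substack: int = pydantic.Field(default=30, ge=2)
    kde_bandwidth: Union[Literal["scott"], float] = "scott"
    mode_prominence: float = pydantic.Field(default=0.2, gt=0, lt=1)
    adjacency_radius_um: float = pydantic.Field(default=25.0, gt=0)
    # architecture-call thresholds (calibration parameters, not measured facts)
    fragmentation_threshold: float = pydantic.Field(default=0.5, gt=0, lt=1)
    clustered_fraction_threshold: float = pydantic.Field(default=0.5, gt=0, lt=1)
    radial_order_threshold: float = pydantic.Field(default=0.0, ge=-1, le=1)
    rng_seed: int = 0

    @pydantic.field_validator("kde_bandwidth")
    @classmethod
    def _bandwidth_positive(cls, v):
        if isinstance(v, (int, float)) and v <= 0:
            raise ValueError("numeric kde_bandwidth must be > 0")
        return v


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON document.

    Absent keys take their defaults; an empty document yields all defaults.
    Out-of-range values raise :class:`ConfigError` naming the key.
    """
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> AnalysisConfig:
    try:
        return AnalysisConfig(**raw)
    except pydantic.ValidationError as exc:
        keys = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) or "<document>"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config value(s) for key(s): {keys}") from exc
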