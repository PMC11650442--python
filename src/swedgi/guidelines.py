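"""Declarative guideline specifications for the dietary index.

Each index component is described by a :class:`GuidelineSpec`: the direction
of the recommendation (a food to reach or a food to limit), the recommended
level, the basis on which intake is compared (grams/day or grams/MJ), which
columns of the diet table feed it, and which scoring rule applies.  Two
configurations ship with the package: the 2015 Swedish food-based dietary
guidelines (``swedgi_2015``) and an NNR2023-aligned modification
(``swedgi_nnr2023``).  The shipped reference levels are sensible defaults,
not calibrated constants; any YAML file of the same shape can be supplied.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, field_validator, model_validator

__all__ = ["GuidelineSpec", "load_guidelines", "SHIPPED_CONFIGS"]

SHIPPED_CONFIGS = ("swedgi_2015", "swedgi_nnr2023")


class GuidelineSpec(BaseModel):
    """One component of the dietary guideline index."""

    name: str
    direction: Literal["encourage", "restrict"]
    basis: Literal["grams_per_day", "grams_per_MJ", "flag"]
    recommended_level: float
    recommended_level_per_mj: Optional[float] = None
    source_fields: list[str]
    scoring: Literal["proportional_5level", "salt_composite"] = "proportional_5level"
    derived: Optional[str] = None

    @field_validator("source_fields")
    @classmethod
    def _non_empty_sources(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("source_fields must be non-empty")
        return v

    @model_validator(mode="after")
    def _positive_level(self) -> "GuidelineSpec":
        if self.basis != "flag" and self.recommended_level <= 0:
            raise ValueError(
                f"component {self.name!r}: recommended_level must be > 0 "
                f"unless basis is 'flag'"
            )
        return self


def load_guidelines(config: str | Path = "swedgi_2015") -> list[GuidelineSpec]:
    """Load a guideline configuration.

    Parameters
    ----------
    config
        Name of a shipped configuration (``"swedgi_2015"`` or
        ``"swedgi_nnr2023"``) or a path to a YAML file with a top-level
        ``components`` list.
    """
    if isinstance(config, str) and config in SHIPPED_CONFIGS:
        text = (
            resources.files("swedgi").joinpath("data", f"{config}.yaml").read_text()
        )
    else:
        text = Path(config).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "components" not in raw:
        raise ValueError("guideline config must have a top-level 'components' list")
    return [GuidelineSpec(**entry) for entry in raw["components"]]
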