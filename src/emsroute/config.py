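"""Application configuration: formula mode, defaults, tie rule, logging."""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field


class FormulaMode(str, Enum):
    """How congestion scales free-flow traversal time.

    ``greenshields_division`` (default) divides free-flow time by
    (1 - k/k_max): travel slows as density approaches jam density, the
    physically meaningful reading. ``as_printed`` multiplies by
    (1 - k/k_max) instead, reproducing the source formula verbatim even
    though it shortens congested trips; it is retained for fidelity and
    comparison, never silently corrected.
    """

    greenshields_division = "greenshields_division"
    as_printed = "as_printed"


class AppConfig(BaseModel):
    """Declarative configuration; CLI flags override file values."""

    formula_mode: FormulaMode = FormulaMode.greenshields_division
    default_speed_kmh: float = Field(40.0, gt=0)
    default_k_max: float = Field(100.0, gt=0)
    saturation_clamp: float = Field(0.95, gt=0, lt=1)
    default_saturation: float = Field(0.70, ge=0, lt=1)
    tie_rule: Literal["lexicographic"] = "lexicographic"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "AppConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.model_dump_json(indent=2))
            fh.write("\n")
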