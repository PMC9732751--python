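"""Structured parameter-file reading and logging setup.

The parameter file is YAML with four optional top-level blocks — ``costs``,
``emissions``, ``extrapolation``, ``scenarios`` — and every field defaulted,
so an empty (or absent) file runs the base case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .emissions import EmissionModel, ExtrapolationScenario
from .scenarios import Scenario
from .types import CostParameters

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSettings:
    params: CostParameters
    emission_model: EmissionModel
    extrapolation: Optional[ExtrapolationScenario]  # None: derive from the cohort
    scenarios: list[Scenario]


def load_settings(path: Optional[Union[str, Path]] = None) -> AnalysisSettings:
    """Load parameters and scenario definitions; missing blocks use defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at the top level")
    unknown = set(raw) - {"costs", "emissions", "extrapolation", "scenarios"}
    if unknown:
        raise ValueError(
            f"unknown configuration blocks {sorted(unknown)}; "
            "valid: costs, emissions, extrapolation, scenarios"
        )
    params = CostParameters(**(raw.get("costs") or {}))
    emission_model = EmissionModel(**(raw.get("emissions") or {}))
    extrap_raw = raw.get("extrapolation")
    extrapolation = ExtrapolationScenario(**extrap_raw) if extrap_raw else None
    scenarios = [Scenario(**block) for block in (raw.get("scenarios") or [])]

    for name, source in (
        ("costs", params),
        ("emissions", emission_model),
    ):
        provided = set((raw.get(name) or {}))
        for field_name, value in source.model_dump().items():
            origin = "config" if field_name in provided else "default"
            logger.info("parameter %s.%s = %s (%s)", name, field_name, value, origin)
    return AnalysisSettings(
        params=params,
        emission_model=emission_model,
        extrapolation=extrapolation,
        scenarios=scenarios,
    )


def setup_logging(level: int = logging.INFO) -> None:
    """Console logging with a compact format; safe to call repeatedly."""
    root = logging.getLogger()
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)
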