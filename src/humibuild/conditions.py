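"""Experimental treatments: still humid air, fan-disturbed air, or no water."""

from __future__ import annotations

import enum
from dataclasses import dataclass


class ConditionKind(str, enum.Enum):
    STILL_WET = "still_wet"
    FAN = "fan"
    DRY = "dry"


class FanSide(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Condition:
    """One of the three treatments applied to a trial.

    STILL_WET: undisturbed outside air, agent carries water.
    FAN: a fan sweeps dry ambient air across one half of the arena
    (``fan_side``); alternated between trials in a batch.
    DRY: still air but the agent's water reservoir is empty.
    """

    kind: ConditionKind
    fan_side: FanSide | None = None

    def __post_init__(self) -> None:
        if self.kind is ConditionKind.FAN and self.fan_side is None:
            raise ValueError("FAN condition requires fan_side")
        if self.kind is not ConditionKind.FAN and self.fan_side is not None:
            raise ValueError("fan_side only applies to the FAN condition")

    @property
    def label(self) -> str:
        return self.kind.value
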