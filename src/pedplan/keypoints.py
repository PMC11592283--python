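"""Per-vertebra, per-side screw entry/exit keypoints in physical mm."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from pedplan.errors import ValidationError

__all__ = ["KeypointPair", "KeypointSet", "LEVEL_LABELS", "LEVELS", "SIDES"]

LEVELS = ("L2", "L3", "L4", "L5", "S1")
SIDES = ("left", "right")
#: integer label of each vertebral level in a LabelMap (0 is background)
LEVEL_LABELS = {"L2": 2, "L3": 3, "L4": 4, "L5": 5, "S1": 6}

MIN_CHANNEL_MM = 10.0  # anatomically plausible minimum entry-exit distance


@dataclasses.dataclass(frozen=True)
class KeypointPair:
    """Entry and exit point (mm) of one bone-screw channel."""

    entry: np.ndarray
    exit: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entry, dtype=float)
        x = np.asarray(self.exit, dtype=float)
        if e.shape != (3,) or x.shape != (3,):
            raise ValidationError("entry/exit must be 3-vectors (mm)")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(x))):
            raise ValidationError("entry/exit must be finite")
        if np.allclose(e, x):
            raise ValidationError("entry and exit coincide")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "exit", x)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.exit - self.entry))


@dataclasses.dataclass
class KeypointSet:
    """Keypoint pairs keyed by (level, side); ``missing`` records channels a
    detector failed to localize (all-zero heatmaps)."""

    pairs: dict[tuple[str, str], KeypointPair] = dataclasses.field(default_factory=dict)
    missing: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for (level, side) in self.pairs:
            if level not in LEVELS or side not in SIDES:
                raise ValidationError(f"unknown (level, side): {(level, side)}")

    def validate(self) -> None:
        """Enforce anatomical plausibility (channel longer than 10 mm)."""
        for key, pair in self.pairs.items():
            if pair.length <= MIN_CHANNEL_MM:
                raise ValidationError(
                    f"channel {key} is {pair.length:.1f} mm; expected > {MIN_CHANNEL_MM} mm"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def items(self):
        return sorted(self.pairs.items())

    # -- JSON round-trip ----------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "level": level,
                "side": side,
                "entry_mm": [float(v) for v in pair.entry],
                "exit_mm": [float(v) for v in pair.exit],
            }
            for (level, side), pair in self.items()
        ]

    @classmethod
    def from_records(cls, records) -> "KeypointSet":
        pairs = {
            (r["level"], r["side"]): KeypointPair(
                np.asarray(r["entry_mm"], float), np.asarray(r["exit_mm"], float)
            )
            for r in records
        }
        return cls(pairs)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_records(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "KeypointSet":
        return cls.from_records(json.loads(Path(path).read_text()))
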