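"""Microscope description files (YAML or JSON).

Schema::

    objective: {f_o_mm: 4.5, na: 0.65}
    wavelength_nm: 532
    channels:
      - {label: bf300, d_total_mm: 300, f_tube_mm: 45, pixel_pitch_um: 1.12}
      - ...
    reference_channel: bf300     # optional; default: shortest d_total
    estimation_channel: bf400    # optional; default: longest d_total

The reference channel anchors the normalization (the shortest path by
convention); the estimation channel (longest path — steepest normalized
curve, hence best conditioning) drives the working-distance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .channels import ChannelSpec, ObjectiveSpec
from .errors import ConfigError

__all__ = ["MicroscopeConfig"]


@dataclass(frozen=True)
class MicroscopeConfig:
    objective: ObjectiveSpec
    wavelength_nm: float
    channels: tuple[ChannelSpec, ...]
    reference_channel: str = field(default="")
    estimation_channel: str = field(default="")

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ConfigError("wavelength_nm must be positive")
        if not self.channels:
            raise ConfigError("at least one channel is required")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"channel labels must be unique, got {labels}")
        if not self.reference_channel:
            shortest = min(self.channels, key=lambda c: c.d_total)
            object.__setattr__(self, "reference_channel", shortest.label)
        if not self.estimation_channel:
            longest = max(self.channels, key=lambda c: c.d_total)
            object.__setattr__(self, "estimation_channel", longest.label)
        for role, label in (
            ("reference_channel", self.reference_channel),
            ("estimation_channel", self.estimation_channel),
        ):
            if label not in labels:
                raise ConfigError(f"{role} {label!r} is not a configured channel")

    def channel(self, label: str) -> ChannelSpec:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(label)

    @classmethod
    def from_dict(cls, data: dict) -> "MicroscopeConfig":
        try:
            objective = ObjectiveSpec(
                f_o=float(data["objective"]["f_o_mm"]),
                na=float(data["objective"]["na"]),
            )
            channels = tuple(
                ChannelSpec(
                    label=str(ch["label"]),
                    d_total=float(ch["d_total_mm"]),
                    f_t=float(ch["f_tube_mm"]),
                    pixel_pitch=float(ch["pixel_pitch_um"]),
                )
                for ch in data["channels"]
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed microscope config: {exc}") from exc
        return cls(
            objective=objective,
            wavelength_nm=float(data["wavelength_nm"]),
            channels=channels,
            reference_channel=str(data.get("reference_channel", "")),
            estimation_channel=str(data.get("estimation_channel", "")),
        )

    @classmethod
    def from_file(cls, path) -> "MicroscopeConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "objective": {"f_o_mm": self.objective.f_o, "na": self.objective.na},
            "wavelength_nm": self.wavelength_nm,
            "channels": [
                {
                    "label": c.label,
                    "d_total_mm": c.d_total,
                    "f_tube_mm": c.f_t,
                    "pixel_pitch_um": c.pixel_pitch,
                }
                for c in self.channels
            ],
            "reference_channel": self.reference_channel,
            "estimation_channel": self.estimation_channel,
        }

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def sorted_by_path(self) -> Sequence[ChannelSpec]:
        return sorted(self.channels, key=lambda c: c.d_total)
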