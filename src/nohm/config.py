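"""Run configuration: pacing specification and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = ["Stimulus", "RunConfig", "MODELS", "DIRECTIONS"]

MODELS = ("cm-clamped", "cm-gated", "lhm", "nohm")
DIRECTIONS = ("normal", "retrograde")


@dataclass(frozen=True)
class Stimulus:
    """Pulsatile boundary-current pacing.

    ``amplitude`` is the applied current flux in uA/mm^2 (the experimental
    range is 10-35), ``duration`` the pulse width in ms, ``cycle_length``
    the pacing period in ms and ``n_beats`` the number of pulses.
    """

    amplitude: float = 30.0
    duration: float = 5.0
    cycle_length: float = 800.0
    n_beats: int = 1

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.cycle_length <= 0 or self.n_beats < 0:
            raise ValueError("invalid stimulus specification")

    def start_times(self, t0: float = 0.0) -> np.ndarray:
        return t0 + self.cycle_length * np.arange(self.n_beats, dtype=float)


@dataclass
class RunConfig:
    """Flat, file-friendly description of one simulation run."""

    model: str = "nohm"
    channel: str = "Cx43-Cx43"
    regime: str = "steady_state"
    beta: float = 1.0
    direction: str = "normal"
    L: float = 6.4
    h: float = 0.1
    n_div: int = 10
    dt: float | None = None
    t_end: float | None = None
    stim_amplitude: float = 30.0
    stim_duration: float = 2.0
    cycle_length: float = 800.0
    n_beats: int = 1
    record_dt: float = 0.05
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; valid: {', '.join(MODELS)}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def stimulus(self) -> Stimulus:
        return Stimulus(
            amplitude=self.stim_amplitude,
            duration=self.stim_duration,
            cycle_length=self.cycle_length,
            n_beats=self.n_beats,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
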