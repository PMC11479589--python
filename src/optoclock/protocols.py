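"""Piecewise-constant illumination schedules.

A :class:`LightProtocol` maps time to a binary light state (green "on" or red
"off"); the simulator converts that state into the light-driven production
rate ``beta_prime`` of the optogenetic module.  Intervals are half-open
``[start, end)`` so that every instant belongs to exactly one level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["LightProtocol", "evaluate_protocol"]


@dataclass(frozen=True)
class LightProtocol:
    """An ordered set of non-overlapping green ("on") windows; red elsewhere.

    Build one with :meth:`constant`, :meth:`single_pulse` or
    :meth:`pulse_train` rather than by hand.
    """

    on_windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end in self.on_windows:
            if not (end > start):
                raise ValueError(f"empty or inverted window ({start}, {end})")
            if start < prev_end:
                raise ValueError("on-windows must be time-ordered and non-overlapping")
            prev_end = end

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, level: str) -> "LightProtocol":
        """Constant illumination, ``level`` one of ``"on"`` (green) / ``"off"`` (red)."""
        if level == "on":
            return cls(((0.0, math.inf),))
        if level == "off":
            return cls(())
        raise ValueError(f"level must be 'on' or 'off', got {level!r}")

    @classmethod
    def single_pulse(cls, t_start: float, duration: float) -> "LightProtocol":
        """One green pulse of length ``duration`` starting at ``t_start`` (hours)."""
        return cls(((float(t_start), float(t_start) + float(duration)),))

    @classmethod
    def pulse_train(
        cls, t_start: float, period: float, duration: float, count: int
    ) -> "LightProtocol":
        """``count`` green pulses of length ``duration`` every ``period`` hours."""
        if duration >= period:
            raise ValueError("pulse duration must be shorter than the train period")
        if count < 1:
            raise ValueError("count must be >= 1")
        windows = tuple(
            (float(t_start + k * period), float(t_start + k * period + duration))
            for k in range(count)
        )
        return cls(windows)

    # -- evaluation --------------------------------------------------------
    def is_on(self, t) -> np.ndarray:
        """Boolean light state at time(s) ``t`` (half-open windows)."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for start, end in self.on_windows:
            on |= (t >= start) & (t < end)
        return on

    def beta_prime(self, t, params) -> np.ndarray:
        """Light-driven production rate beta'(t) for the given parameter set."""
        return np.where(self.is_on(t), params.beta_prime_on, params.beta_prime_off)

    @property
    def pulse_starts(self) -> np.ndarray:
        return np.array([start for start, _ in self.on_windows])

    @property
    def is_constant(self) -> bool:
        """True when the light level never changes on [0, inf)."""
        if not self.on_windows:
            return True
        return (
            len(self.on_windows) == 1
            and self.on_windows[0][0] <= 0.0
            and math.isinf(self.on_windows[0][1])
        )

    # -- serialization -----------------------------------------------------
    def segments(self, t_end: float) -> list[dict]:
        """Explicit (start, end, level) listing covering ``[0, t_end)``."""
        edges = [0.0]
        for start, end in self.on_windows:
            for e in (start, end):
                if 0.0 < e < t_end:
                    edges.append(e)
        edges.append(t_end)
        edges = sorted(set(edges))
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            level = "on" if bool(self.is_on(a)) else "off"
            out.append({"start": a, "end": b, "level": level})
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {"on_windows": [list(w) for w in self.on_windows]}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LightProtocol":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(tuple(float(x) for x in w) for w in payload["on_windows"]))


def evaluate_protocol(protocol: LightProtocol, t: float, params) -> float:
    """beta'(t) under ``protocol`` for parameter set ``params`` (scalar time)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return float(protocol.beta_prime(t, params))
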