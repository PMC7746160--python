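"""Machine-readable optimization trace: per-iteration global best and events."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

__all__ = ["TraceRow", "OptimizationTrace"]

EVENTS = ("none", "first_order", "second_order")


@dataclass(frozen=True)
class TraceRow:
    """State after one optimizer iteration."""

    iteration: int
    gbest_x: float  # best spacing so far, cm
    gbest_f: float  # its fitness
    event: str  # none | first_order | second_order
    positions: tuple[float, ...] | None = None  # per-particle, optional

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ValueError(f"unknown event {self.event!r}")


@dataclass
class OptimizationTrace:
    """One row per iteration plus run metadata (seed, t_switch, config digest)."""

    rows: list[TraceRow] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def append(self, row: TraceRow) -> None:
        if self.rows and row.iteration != self.rows[-1].iteration + 1:
            raise ValueError("trace iterations must be consecutive")
        self.rows.append(row)

    def to_frame(self, include_positions: bool = False) -> pd.DataFrame:
        data = {
            "iteration": [r.iteration for r in self.rows],
            "gbest_spacing_cm": [r.gbest_x for r in self.rows],
            "gbest_fitness": [r.gbest_f for r in self.rows],
            "event": [r.event for r in self.rows],
        }
        if include_positions and self.rows and self.rows[0].positions is not None:
            n = len(self.rows[0].positions)
            for j in range(n):
                data[f"x_{j}"] = [
                    r.positions[j] if r.positions is not None else float("nan")
                    for r in self.rows
                ]
        return pd.DataFrame(data)

    def gbest_positions(self) -> list[float]:
        return [r.gbest_x for r in self.rows]

    def gbest_fitness(self) -> list[float]:
        return [r.gbest_f for r in self.rows]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OptimizationTrace):
            return NotImplemented
        return self.rows == other.rows and self.metadata == other.metadata
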