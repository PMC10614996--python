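"""Model parameters for the three-type density-dependent branching process.

A well hosts a mixture of fast, moderate and slow cells.  Each half-day
step a cell divides with probability ``g``, dies with probability ``d``
and otherwise stays quiescent.  The fast-type birth probability is

    gF(N) = clamp(g0 * (1 - N**2 / C**2) + delta, 0, 1 - d)

with total population ``N``, carrying capacity ``C`` and a per-well
random modifier ``delta ~ Uniform(-r, r)`` drawn once per well.  The
moderate and slow types divide at ``gF/1.5`` and ``gF/3``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

__all__ = ["ModelParams", "CELLS_PER_AREA_UNIT"]

#: conversion between imaged well area and cell number (1 unit ~ 500 cells)
CELLS_PER_AREA_UNIT = 500.0

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """All constants of the branching model.

    Parameters
    ----------
    pF, pM, pS
        Probabilities that a seeded cell is of fast / moderate / slow
        type.  Must sum to 1.
    d
        Death probability per half-day step (shared by all types).
    g0
        Base birth probability per half-day step of the fast type in an
        empty well.
    C
        Carrying capacity in cells: the population at which the density
        term drives the birth probability to zero.
    r
        Half-width of the uniform per-well modifier ``delta``.
    """

    pF: float = 0.4
    pM: float = 0.4
    pS: float = 0.2
    d: float = 0.01
    g0: float = 0.5
    C: int = 40000
    r: float = 0.1

    def __post_init__(self) -> None:
        for name in ("pF", "pM", "pS"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must be in [0, 1]")
        if abs(self.pF + self.pM + self.pS - 1.0) > _PROB_TOL:
            raise ValueError("type probabilities pF + pM + pS must sum to 1")
        if not 0.0 <= self.d < 1.0:
            raise ValueError(f"d={self.d} must be in [0, 1)")
        if not 0.0 <= self.g0 <= 1.0:
            raise ValueError(f"g0={self.g0} must be in [0, 1]")
        if self.r < 0.0:
            raise ValueError(f"r={self.r} must be non-negative")
        if self.C <= 0 or int(self.C) != self.C:
            raise ValueError(f"C={self.C} must be a positive integer")

    @property
    def type_probabilities(self) -> tuple[float, float, float]:
        return (self.pF, self.pM, self.pS)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)
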