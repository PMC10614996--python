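"""Three-type discrete-time branching process with density-dependent division.

Time advances in half-day steps.  Each living cell independently
divides, dies, or stays quiescent; the per-type offspring distribution
at a step is {0: d, 1: 1-g-d, 2: g}, so a type count evolves as a sum of
i.i.d. offspring draws and types never interconvert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "CELL_TYPES",
    "TYPE_DIVISORS",
    "WellState",
    "WellTrajectory",
    "draw_initial_state",
    "birth_probability",
    "half_step",
    "simulate_well",
    "simulate_final_totals",
]

CELL_TYPES = ("fast", "moderate", "slow")

#: the moderate and slow types divide at gF/1.5 and gF/3
TYPE_DIVISORS = {"fast": 1.0, "moderate": 1.5, "slow": 3.0}


@dataclass(frozen=True)
class WellState:
    """Cell counts of each type after ``t`` half-day steps."""

    F: int
    M: int
    S: int
    t: int = 0

    def __post_init__(self) -> None:
        if self.F < 0 or self.M < 0 or self.S < 0:
            raise ValueError("cell counts must be non-negative")
        if self.t < 0:
            raise ValueError("step index must be non-negative")

    @property
    def total(self) -> int:
        return self.F + self.M + self.S

    @property
    def t_days(self) -> float:
        return self.t / 2.0


@dataclass
class WellTrajectory:
    """Latent half-day states of one simulated well.

    ``states[k]`` is the state after ``k`` half-day steps; ``delta`` is
    the well's realized birth-probability modifier, fixed for the whole
    simulation.
    """

    states: list[WellState]
    delta: float
    N0: int
    seed: int | None = None
    well_id: str = ""
    params: ModelParams | None = None

    @property
    def final_state(self) -> WellState:
        return self.states[-1]

    @property
    def extinct(self) -> bool:
        return self.final_state.total == 0

    def daily_states(self) -> list[WellState]:
        """States at integer days (every second half-day step)."""
        return self.states[::2]

    def daily_totals(self) -> tuple[np.ndarray, np.ndarray]:
        """(days, total cell counts) sampled at integer days."""
        daily = self.daily_states()
        days = np.array([s.t_days for s in daily])
        totals = np.array([s.total for s in daily])
        return days, totals


def draw_initial_state(N0: int, params: ModelParams, rng: np.random.Generator) -> WellState:
    """Seed a well with ``N0`` cells of independently multinomial types."""
    if N0 < 0:
        raise ValueError(f"N0={N0} must be non-negative")
    if N0 == 0:
        return WellState(0, 0, 0, t=0)
    F, M, S = rng.multinomial(N0, params.type_probabilities)
    return WellState(int(F), int(M), int(S), t=0)


def birth_probability(
    cell_type: str, N_total: int, params: ModelParams, delta: float = 0.0
) -> float:
    """Per-half-day division probability of one cell of ``cell_type``.

    The fast-type probability g0*(1 - N^2/C^2) + delta is clamped to
    [0, 1-d] first; the moderate and slow values are the clamped value
    divided by 1.5 and 3.
    """
    if cell_type not in TYPE_DIVISORS:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if N_total < 0:
        raise ValueError("population must be non-negative")
    gF = params.g0 * (1.0 - (N_total / params.C) ** 2) + delta
    gF = min(max(gF, 0.0), 1.0 - params.d)
    return gF / TYPE_DIVISORS[cell_type]


def _offspring_count(n: int, g: float, d: float, rng: np.random.Generator) -> int:
    """Next count for one type: each of ``n`` cells leaves 0, 1 or 2
    same-type offspring with probabilities (d, 1-g-d, g)."""
    if n == 0:
        return 0
    deaths, stays, divisions = rng.multinomial(n, (d, 1.0 - g - d, g))
    return int(stays + 2 * divisions)


def half_step(
    state: WellState, params: ModelParams, delta: float, rng: np.random.Generator
) -> WellState:
    """Advance one half-day; birth probabilities use the current total."""
    N = state.total
    counts = []
    for cell_type, n in zip(CELL_TYPES, (state.F, state.M, state.S)):
        g = birth_probability(cell_type, N, params, delta)
        counts.append(_offspring_count(n, g, params.d, rng))
    return WellState(*counts, t=state.t + 1)


def simulate_well(
    N0: int,
    params: ModelParams,
    t_end_days: float = 23.0,
    rng: np.random.Generator | int | None = None,
    delta: float | None = None,
    initial_state: WellState | None = None,
    well_id: str = "",
) -> WellTrajectory:
    """Simulate one well through ``t_end_days``, recording every half day.

    ``delta`` is drawn once uniform on [-r, r] and held fixed; pass an
    explicit value to condition on it.  ``initial_state`` overrides the
    multinomial type draw (used e.g. to force a pure-type seeding).
    """
    if t_end_days <= 0:
        raise ValueError("t_end_days must be positive")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    if delta is None:
        delta = float(rng.uniform(-params.r, params.r)) if params.r > 0 else 0.0
    if initial_state is None:
        initial_state = draw_initial_state(N0, params, rng)
    n_steps = int(round(2 * t_end_days))
    states = [initial_state]
    state = initial_state
    for _ in range(n_steps):
        if state.total == 0:
            # extinction is absorbing; keep recording zeros without rng draws
            state = WellState(0, 0, 0, t=state.t + 1)
        else:
            state = half_step(state, params, delta, rng)
        states.append(state)
    return WellTrajectory(
        states=states, delta=delta, N0=N0, seed=seed, well_id=well_id, params=params
    )


def simulate_final_totals(
    n_wells: int,
    N0: int,
    params: ModelParams,
    t_end_days: float,
    rng: np.random.Generator | int | None = None,
    cell_type: str | None = None,
) -> np.ndarray:
    """Final total cell counts of ``n_wells`` independent wells.

    Vectorized over wells via the binomial-thinning construction of the
    per-type trinomial step (divisions ~ Bin(n, g), then deaths ~
    Bin(n - divisions, d/(1-g))), which has exactly the same law as the
    per-cell i.i.d. offspring draws.  ``cell_type`` forces every seeded
    cell to one type; otherwise types are multinomial.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be positive")
    rng = np.random.default_rng(rng)
    delta = rng.uniform(-params.r, params.r, size=n_wells) if params.r > 0 else np.zeros(n_wells)
    if cell_type is None:
        counts = rng.multinomial(N0, params.type_probabilities, size=n_wells).T
    else:
        counts = np.zeros((3, n_wells), dtype=np.int64)
        counts[CELL_TYPES.index(cell_type)] = N0
    F, M, S = (c.astype(np.int64) for c in counts)
    divisors = np.array([TYPE_DIVISORS[t] for t in CELL_TYPES])
    d = params.d
    for _ in range(int(round(2 * t_end_days))):
        N = F + M + S
        gF = np.clip(params.g0 * (1.0 - (N / params.C) ** 2) + delta, 0.0, 1.0 - d)
        new = []
        for idx, n in enumerate((F, M, S)):
            g = gF / divisors[idx]
            div = rng.binomial(n, g)
            remaining = n - div
            if d > 0:
                p_death = np.divide(d, 1.0 - g, out=np.ones_like(g), where=(1.0 - g) > 0)
                deaths = rng.binomial(remaining, np.clip(p_death, 0.0, 1.0))
            else:
                deaths = 0
            new.append(n + div - deaths)
        F, M, S = new
    return F + M + S
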