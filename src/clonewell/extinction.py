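"""Extinction probabilities of the branching model.

Far below the carrying capacity the density term is negligible, so each
lineage behaves as a single-type Galton-Watson process with offspring
distribution {0: d, 1: 1-g-d, 2: g}.  For g > d its extinction
probability from one cell is d/g; averaging over the per-well modifier
delta ~ Uniform(-r, r) gives

    E[gamma_F] = E[d / (g0 + delta)] = (d / 2r) * log((g0 + r) / (g0 - r))
               ~ d / g0            (first-order Taylor expansion)

and the moderate/slow lineages divide at g/1.5 and g/3, multiplying the
extinction probability by 1.5 and 3.  Seeding types are mixed with
(pF, pM, pS), and an N0-cell seeding goes extinct only if all N0
lineages do.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np
from scipy.integrate import quad

from .branching import CELL_TYPES, TYPE_DIVISORS, WellTrajectory, simulate_final_totals
from .params import ModelParams

__all__ = [
    "ExtinctionReport",
    "single_type_extinction",
    "expected_extinction_by_type",
    "mixture_extinction",
    "empirical_extinction",
]

MODES = ("taylor", "exact_integral", "monte_carlo")


@dataclass(frozen=True)
class ExtinctionReport:
    """Per-type and seeding-averaged extinction probabilities."""

    gamma_F: float
    gamma_M: float
    gamma_S: float
    gamma_mixture: float
    N0: int
    mode: str

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def single_type_extinction(g: float, d: float, N0: int) -> float:
    """Extinction probability of a single-type lineage: (d/g)^N0 if
    supercritical (g > d), else 1."""
    if N0 < 1:
        raise ValueError(f"N0={N0} must be at least 1")
    if g < 0 or d < 0 or g + d > 1:
        raise ValueError("need g, d >= 0 and g + d <= 1")
    if g <= d:
        return 1.0
    return (d / g) ** N0


def _gamma_fast_expected(params: ModelParams, mode: str) -> float:
    """E over delta of the fast-type single-cell extinction probability."""
    d, g0, r = params.d, params.g0, params.r
    if mode in ("taylor", "exact_integral"):
        if g0 - r <= d:
            raise ValueError(
                "closed forms require g0 - r > d (supercritical for every delta)"
            )
        if mode == "taylor" or r == 0.0:
            return d / g0
        return (d / (2.0 * r)) * math.log((g0 + r) / (g0 - r))
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES[:2]}")


def expected_extinction_by_type(
    params: ModelParams,
    mode: str = "taylor",
    n_wells: int = 100_000,
    t_end_days: float = 60.0,
    rng=None,
) -> ExtinctionReport:
    """Expected extinction probability of one seeded cell of each type.

    ``taylor`` reproduces the headline arithmetic d/g0, 3d/(2g0), 3d/g0;
    ``exact_integral`` evaluates the uniform average exactly;
    ``monte_carlo`` simulates the full density-dependent process.
    """
    if mode == "monte_carlo":
        gammas = {}
        rng = np.random.default_rng(rng)
        for cell_type in CELL_TYPES:
            totals = simulate_final_totals(
                n_wells, 1, params, t_end_days, rng, cell_type=cell_type
            )
            gammas[cell_type] = float(np.mean(totals == 0))
        gF, gM, gS = (gammas[t] for t in CELL_TYPES)
    else:
        gF = _gamma_fast_expected(params, mode)
        gM, gS = 1.5 * gF, 3.0 * gF
    mixture = params.pF * gF + params.pM * gM + params.pS * gS
    return ExtinctionReport(gF, gM, gS, mixture, N0=1, mode=mode)


def mixture_extinction(
    params: ModelParams,
    N0: int = 1,
    mode: str = "taylor",
    exact_power: bool = False,
    **kwargs,
) -> float:
    """Seeding-type-averaged extinction probability for N0 cells.

    Default uses the approximation E[gamma^N0] ~ E[gamma]^N0 on the
    per-type expectations from the chosen mode.  ``exact_power``
    integrates the shared-delta mixture power over delta instead
    (delta is common to all N0 lineages of a well).
    """
    if N0 < 1:
        raise ValueError(f"N0={N0} must be at least 1")
    if exact_power and mode in ("taylor", "exact_integral"):
        d, g0, r = params.d, params.g0, params.r
        if g0 - r <= d:
            raise ValueError("exact_power requires g0 - r > d")

        def mixture_at(delta: float) -> float:
            gF = g0 + delta
            return sum(
                p * (d / (gF / TYPE_DIVISORS[t]))
                for p, t in zip(params.type_probabilities, CELL_TYPES)
            )

        if r == 0.0:
            return mixture_at(0.0) ** N0
        val, _ = quad(lambda x: mixture_at(x) ** N0, -r, r)
        return val / (2.0 * r)
    report = expected_extinction_by_type(params, mode=mode, **kwargs)
    return report.gamma_mixture ** N0


def empirical_extinction(
    trajectories: Iterable[WellTrajectory] | np.ndarray,
) -> tuple[float, float]:
    """Fraction of wells with zero final population, with binomial SE.

    Accepts trajectories or an array of final total counts.
    """
    if isinstance(trajectories, np.ndarray):
        finals = trajectories
    else:
        finals = np.array([traj.final_state.total for traj in trajectories])
    n = finals.size
    if n == 0:
        raise ValueError("need at least one trajectory")
    frac = float(np.mean(finals == 0))
    se = math.sqrt(frac * (1.0 - frac) / n)
    return frac, se
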