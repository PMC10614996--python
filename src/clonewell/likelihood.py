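"""Likelihood-based parameter estimation from daily cell counts.

A well tracked at daily resolution while small (counts below ~300, so
the density term is negligible) yields exact one-day transition
probabilities: one cell leaves 0..4 descendants after two half-day
steps, and ``n1`` cells leave the n1-fold convolution of that
distribution.  The per-well likelihood is a product of daily
transitions, marginalized over the well's fixed birth-rate modifier
delta on a uniform grid, and (g0, d, r) are estimated by grid-search
maximum likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .metrics import ObservedWell, classify_growth_pattern, exponential_phase_rate
from .params import ModelParams

__all__ = [
    "DailyCountSeries",
    "MLEResult",
    "TypeProbEstimate",
    "one_day_offspring_probs",
    "one_day_transition",
    "well_log_likelihood",
    "mle_grid_search",
    "fit_replicates",
    "estimate_type_probabilities",
    "DEFAULT_G0_GRID",
    "DEFAULT_D_GRID",
    "DEFAULT_R_GRID",
]

DEFAULT_G0_GRID = np.round(np.arange(0.30, 0.70 + 1e-9, 0.01), 10)
DEFAULT_D_GRID = np.round(np.arange(0.00, 0.05 + 1e-9, 0.01), 10)
DEFAULT_R_GRID = np.round(np.arange(0.00, 0.15 + 1e-9, 0.01), 10)

DEFAULT_DELTA_GRID_SIZE = 21


@dataclass(frozen=True)
class DailyCountSeries:
    """Manually counted cells on consecutive days for one small well."""

    well_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class MLEResult:
    g0_hat: float
    d_hat: float
    r_hat: float
    log_likelihood: float
    g0_grid: tuple[float, ...]
    d_grid: tuple[float, ...]
    r_grid: tuple[float, ...]
    delta_grid_size: int


@dataclass(frozen=True)
class TypeProbEstimate:
    pF: float
    pM: float
    pS: float
    counts: dict


def one_day_offspring_probs(g: float, d: float) -> np.ndarray:
    """Distribution of descendants of one cell after one day (two
    half-day steps): P(0..4) as closed-form polynomials in (g, d)."""
    if g < 0 or d < 0 or g + d > 1 + 1e-12:
        raise ValueError("need g, d >= 0 and g + d <= 1")
    s = 1.0 - g - d
    return np.array(
        [
            g * d ** 2 + d * s + d,
            2.0 * g * d * s + s ** 2,
            g * s ** 2 + 2.0 * g ** 2 * d + g * s,
            2.0 * g ** 2 * s,
            g ** 3,
        ]
    )


def _pmf_power(pmf: np.ndarray, n: int) -> np.ndarray:
    """Distribution of the sum of ``n`` i.i.d. draws (iterated
    convolution)."""
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, pmf)
    return out


def one_day_transition(n1: int, n2: int, g: float, d: float) -> float:
    """P(N = n1 -> N = n2 | g, d) in one day: the n1-fold convolution of
    the one-day offspring distribution, evaluated at n2."""
    if n1 < 1:
        raise ValueError("n1 must be at least 1")
    if n2 < 0:
        raise ValueError("n2 must be non-negative")
    if n2 > 4 * n1:
        return 0.0
    dist = _pmf_power(one_day_offspring_probs(g, d), n1)
    return float(dist[n2])


def _delta_grid(g0: float, d: float, r: float, size: int) -> np.ndarray:
    """Equal-weight uniform grid of g* = g0 + delta over [g0-r, g0+r]."""
    if r == 0.0:
        return np.array([g0])
    grid = np.linspace(g0 - r, g0 + r, size)
    if grid[-1] + d > 1.0:
        warnings.warn("g0 + r + d exceeds 1; clamping g* to 1 - d")
        grid = np.minimum(grid, 1.0 - d)
    return np.maximum(grid, 0.0)


def _series_log_prob(counts: Sequence[int], g: float, d: float) -> float:
    """log prod_j P(n_j -> n_{j+1}) for one well at fixed (g, d)."""
    total = 0.0
    for n1, n2 in zip(counts[:-1], counts[1:]):
        if n1 == 0:
            return -math.inf  # extinction is absorbing; no continuation
        p = one_day_transition(n1, n2, g, d)
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total


def well_log_likelihood(
    series: DailyCountSeries | Sequence[int],
    g0: float,
    d: float,
    r: float,
    delta_grid_size: int = DEFAULT_DELTA_GRID_SIZE,
) -> float:
    """log P(series | g0, d, r), delta marginalized on a uniform grid.

    delta is constant within a well, so the per-grid-point likelihood is
    a product over days and the marginal is the equally-weighted average
    over grid points (computed with a log-space mixture).
    """
    counts = series.counts if isinstance(series, DailyCountSeries) else tuple(series)
    if len(counts) < 2:
        raise ValueError("series needs at least two daily counts")
    grid = _delta_grid(g0, d, r, delta_grid_size)
    logs = np.array([_series_log_prob(counts, g, d) for g in grid])
    if np.all(np.isinf(logs)):
        return -math.inf
    return float(logsumexp(logs) - math.log(len(grid)))


def _sweep_log_likelihoods(
    wells: Sequence[DailyCountSeries], pairs: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Per-well log-likelihoods at every (g*, d) pair, sharing one
    convolution sweep per pair.

    For each pair the one-day distribution is convolved up once to the
    largest observed count, and every well's daily transitions are read
    off the intermediate powers.
    """
    steps: dict[int, list[tuple[int, int]]] = {}
    impossible = np.zeros(len(wells), bool)
    for w, series in enumerate(wells):
        counts = series.counts
        for n1, n2 in zip(counts[:-1], counts[1:]):
            if n1 == 0:
                impossible[w] = True
            else:
                steps.setdefault(n1, []).append((w, n2))
    max_n1 = max(steps) if steps else 0
    out = np.zeros((len(pairs), len(wells)))
    out[:, impossible] = -np.inf
    with np.errstate(divide="ignore"):
        for i, (g, d) in enumerate(pairs):
            pmf = one_day_offspring_probs(g, d)
            cur = np.array([1.0])
            acc = out[i]
            for n1 in range(1, max_n1 + 1):
                cur = np.convolve(cur, pmf)
                for w, n2 in steps.get(n1, ()):
                    p = cur[n2] if n2 < len(cur) else 0.0
                    acc[w] += np.log(p) if p > 0.0 else -np.inf
    return out


def _grid_search(
    wells: Sequence[DailyCountSeries],
    g0_grid: np.ndarray,
    d_grid: np.ndarray,
    r_grid: np.ndarray,
    delta_grid_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-well log-likelihood tensor over the (g0, d, r) grid.

    Returns (loglik[g0, d, r, well], combo index arrays).  All (g*, d)
    pairs needed by any grid combination are evaluated once.
    """
    pair_index: dict[tuple[float, float], int] = {}
    combo_pairs = {}
    for d in d_grid:
        for g0 in g0_grid:
            for r in r_grid:
                grid = _delta_grid(float(g0), float(d), float(r), delta_grid_size)
                keys = []
                for g in grid:
                    key = (round(float(g), 9), float(d))
                    if key not in pair_index:
                        pair_index[key] = len(pair_index)
                    keys.append(pair_index[key])
                combo_pairs[(float(g0), float(d), float(r))] = np.array(keys)
    pairs = [None] * len(pair_index)
    for (g, d), idx in pair_index.items():
        pairs[idx] = (g, d)
    L = _sweep_log_likelihoods(wells, pairs)  # (n_pairs, n_wells)
    shape = (len(g0_grid), len(d_grid), len(r_grid), len(wells))
    out = np.empty(shape)
    for i, g0 in enumerate(g0_grid):
        for j, d in enumerate(d_grid):
            for k, r in enumerate(r_grid):
                idx = combo_pairs[(float(g0), float(d), float(r))]
                out[i, j, k] = logsumexp(L[idx], axis=0) - math.log(len(idx))
    return out, combo_pairs


def _argmax_with_ties(
    total: np.ndarray, g0_grid: np.ndarray, d_grid: np.ndarray, r_grid: np.ndarray
) -> tuple[int, int, int]:
    """Ties broken by smallest (d, r, |g0 - 0.5|) lexicographically."""
    best = np.max(total)
    candidates = np.argwhere(np.isclose(total, best, rtol=0, atol=1e-9))
    keyed = sorted(
        (
            (d_grid[j], r_grid[k], abs(g0_grid[i] - 0.5), (i, j, k))
            for i, j, k in candidates
        )
    )
    return keyed[0][3]


def mle_grid_search(
    wells: Sequence[DailyCountSeries],
    g0_grid: Sequence[float] | None = None,
    d_grid: Sequence[float] | None = None,
    r_grid: Sequence[float] | None = None,
    delta_grid_size: int = DEFAULT_DELTA_GRID_SIZE,
) -> MLEResult:
    """Maximum-likelihood (g0, d, r) over a Cartesian grid.

    The total log-likelihood is the sum of per-well marginal
    log-likelihoods; the argmax over the grid is returned.
    """
    results = fit_replicates([wells], g0_grid, d_grid, r_grid, delta_grid_size)
    return results[0]


def fit_replicates(
    well_groups: Sequence[Sequence[DailyCountSeries]],
    g0_grid: Sequence[float] | None = None,
    d_grid: Sequence[float] | None = None,
    r_grid: Sequence[float] | None = None,
    delta_grid_size: int = DEFAULT_DELTA_GRID_SIZE,
) -> list[MLEResult]:
    """Independent grid-search fits for several replicate well sets.

    The expensive transition tables depend only on (g*, d), not on the
    data, so all replicates share one sweep.
    """
    g0_grid = np.asarray(g0_grid if g0_grid is not None else DEFAULT_G0_GRID, float)
    d_grid = np.asarray(d_grid if d_grid is not None else DEFAULT_D_GRID, float)
    r_grid = np.asarray(r_grid if r_grid is not None else DEFAULT_R_GRID, float)
    if len(g0_grid) == 0 or len(d_grid) == 0 or len(r_grid) == 0:
        raise ValueError("grids must be non-empty")
    all_wells = [w for group in well_groups for w in group]
    if not all_wells:
        raise ValueError("no wells supplied")
    loglik, _ = _grid_search(all_wells, g0_grid, d_grid, r_grid, delta_grid_size)
    results = []
    offset = 0
    for group in well_groups:
        sl = slice(offset, offset + len(group))
        offset += len(group)
        total = loglik[..., sl].sum(axis=-1)
        i, j, k = _argmax_with_ties(total, g0_grid, d_grid, r_grid)
        results.append(
            MLEResult(
                g0_hat=float(g0_grid[i]),
                d_hat=float(d_grid[j]),
                r_hat=float(r_grid[k]),
                log_likelihood=float(total[i, j, k]),
                g0_grid=tuple(g0_grid),
                d_grid=tuple(d_grid),
                r_grid=tuple(r_grid),
                delta_grid_size=delta_grid_size,
            )
        )
    return results


def estimate_type_probabilities(
    wells: Iterable[ObservedWell],
    rate_threshold: float = 0.55,
    include_extinct: bool = False,
    params: ModelParams | None = None,
) -> TypeProbEstimate:
    """Initial-type probabilities from classified single-cell wells.

    pS is the fraction of wells that never reached exponential growth
    (extinct wells excluded from the tally by default, but both counts
    are reported); the remaining mass splits into pF : pM by comparing
    each exponential well's mid-phase rate with ``rate_threshold``.
    """
    params = params or ModelParams()
    n_extinct = n_slow = n_fast = n_moderate = n_unrated = 0
    for well in wells:
        pattern = classify_growth_pattern(well, params)
        if pattern == "extinct":
            n_extinct += 1
        elif pattern == "slow_no_exponential":
            n_slow += 1
        else:
            rate = exponential_phase_rate(well)
            if rate is None:
                n_unrated += 1
            elif rate > rate_threshold:
                n_fast += 1
            else:
                n_moderate += 1
    n_exponential = n_fast + n_moderate + n_unrated
    counts = {
        "extinct": n_extinct,
        "slow_no_exponential": n_slow,
        "exponential": n_exponential,
        "fast": n_fast,
        "moderate": n_moderate,
        "unrated_exponential": n_unrated,
    }
    if include_extinct:
        denom = n_extinct + n_slow + n_exponential
        n_s = n_extinct + n_slow
    else:
        denom = n_slow + n_exponential
        n_s = n_slow
    if denom == 0:
        raise ValueError("no wells to estimate from")
    pS = n_s / denom
    if n_fast + n_moderate == 0:
        counts["degenerate"] = True
        return TypeProbEstimate(pF=0.0, pM=0.0, pS=pS, counts=counts)
    frac_fast = n_fast / (n_fast + n_moderate)
    pF = (1.0 - pS) * frac_fast
    pM = (1.0 - pS) * (1.0 - frac_fast)
    return TypeProbEstimate(pF=pF, pM=pM, pS=pS, counts=counts)
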