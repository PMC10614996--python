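"""Robustness scan: which parameter sets reproduce the experiment's
qualitative features.

Four observable features are checked on generated ensembles:

1. every 10-cell well saturates (reaches 0.8 C by Day 23);
2. at least one 1-cell well shows delayed exponential growth;
3. at least one 1-cell well never grows exponentially (it dies out,
   or it survives but stays below 1000 cells);
4. 1-cell wells grow slower than 10-cell wells at the same population
   size (population-weighted Welch test, one direction, rates
   restricted to the exponential-phase window below C/2, at the
   Bonferroni-corrected level 0.05/3 that the underlying analysis
   applied to its three group comparisons).

Because single ensembles are stochastic, each parameter row is judged
by majority vote over replicate ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import area_to_cells, classify_growth_pattern, per_capita_rates
from .params import ModelParams
from .stats import weighted_welch_t_test
from .synthesis import ExperimentConfig, GrowthExperiment, generate_growth_experiment

__all__ = [
    "ScanRow",
    "detect_features",
    "run_scan",
    "scan_to_dataframe",
    "TABLE3_PARAM_ROWS",
    "DEFAULT_SCAN_ALPHA",
]

#: the 18 parameter sets of the published robustness table
#: (pF, pM, pS, d, g0, r)
TABLE3_PARAM_ROWS: tuple[ModelParams, ...] = tuple(
    ModelParams(pF=pF, pM=pM, pS=pS, d=d, g0=g0, r=r)
    for pF, pM, pS, d, g0, r in [
        (0.4, 0.4, 0.2, 0.01, 0.5, 0.1),
        (0.4, 0.4, 0.2, 0.0, 0.5, 0.1),
        (0.4, 0.4, 0.2, 0.05, 0.5, 0.1),
        (0.4, 0.4, 0.2, 0.1, 0.5, 0.1),
        (0.4, 0.4, 0.2, 0.01, 0.45, 0.1),
        (0.4, 0.4, 0.2, 0.01, 0.6, 0.1),
        (0.4, 0.4, 0.2, 0.01, 0.4, 0.1),
        (0.4, 0.4, 0.2, 0.01, 0.5, 0.05),
        (0.4, 0.4, 0.2, 0.01, 0.5, 0.0),
        (0.4, 0.4, 0.2, 0.01, 0.5, 0.15),
        (0.4, 0.4, 0.2, 0.01, 0.5, 0.2),
        (0.3, 0.5, 0.2, 0.01, 0.5, 0.1),
        (0.5, 0.3, 0.2, 0.01, 0.5, 0.1),
        (0.4, 0.5, 0.1, 0.01, 0.5, 0.1),
        (0.4, 0.3, 0.3, 0.01, 0.5, 0.1),
        (0.5, 0.4, 0.1, 0.01, 0.5, 0.1),
        (0.3, 0.4, 0.3, 0.01, 0.5, 0.1),
        (0.1, 0.1, 0.8, 0.01, 0.5, 0.1),
    ]
)

# A well's stationary plateau sits where birth balances death,
# N* = C * sqrt(1 - (d - delta)/g0), which is ~0.88 C for a default well
# at delta = -r.  "Saturated" therefore means reaching 0.8 C: every
# plateau of the printed Yes rows exceeds it (worst case 0.825 C at
# r = 0.15) and every No row's worst-case plateau falls below it.
SATURATION_FRACTION = 0.8

#: significance level of the feature-4 rate comparison; the source
#: analysis Bonferroni-corrected its three pairwise group tests
DEFAULT_SCAN_ALPHA = 0.05 / 3


@dataclass
class ScanRow:
    """Feature booleans plus the numeric evidence they came from."""

    params: ModelParams
    feature1: bool
    feature2: bool
    feature3: bool
    feature4: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def features(self) -> tuple[bool, bool, bool, bool]:
        return (self.feature1, self.feature2, self.feature3, self.feature4)


def _cells_at_day(well, day: float) -> float | None:
    idx = np.nonzero(well.days == day)[0]
    return float(well.cells[idx[0]]) if idx.size else None


def detect_features(
    experiment: GrowthExperiment, alpha: float = DEFAULT_SCAN_ALPHA
) -> ScanRow:
    """Evaluate the four features on one generated ensemble.

    Only the generated observables (daily areas) are used, never the
    hidden per-well truth.
    """
    params = experiment.config.params
    C = params.C
    for N0 in (10, 1):
        if not experiment.group(N0):
            raise ValueError(f"ensemble is missing the N0={N0} group")

    finals_10 = np.array([w.cells[-1] for w in experiment.group(10)])
    feature1 = bool(np.all(finals_10 >= SATURATION_FRACTION * C))

    classes = [classify_growth_pattern(w, params) for w in experiment.group(1)]
    n_delayed = classes.count("delayed_exponential")
    n_slow = classes.count("slow_no_exponential")
    n_extinct = classes.count("extinct")
    feature2 = n_delayed >= 1

    # "non-growing" wells are those that never grew exponentially:
    # extinct wells, sub-1000-cell survivors, and the alternative
    # reading (past 10 cells by Day 8 yet under 1000 cells at Day 23)
    n_stalled = 0
    for w in experiment.group(1):
        c8 = _cells_at_day(w, 8.0)
        if c8 is not None and c8 > 10 and w.cells[-1] < 1000:
            n_stalled += 1
    feature3 = n_extinct >= 1 or n_slow >= 1 or n_stalled >= 1

    # compare rates in the exponential-phase window (5-50 area units,
    # where observed rates are reliable) and below half capacity
    lo = area_to_cells(5.0)
    hi = min(area_to_cells(50.0), C / 2.0)
    rates, weights = {}, {}
    for N0 in (10, 1):
        pts = [
            p
            for w in experiment.group(N0)
            for p in per_capita_rates(w)
            if lo <= p.N < hi
        ]
        rates[N0] = [p.rate for p in pts]
        weights[N0] = [p.N for p in pts]
    # the experimental feature is that 1-cell wells grow SLOWER than
    # 10-cell wells at the same population size, so the test is
    # directional: significant and in that direction
    if len(rates[10]) >= 2 and len(rates[1]) >= 2:
        welch = weighted_welch_t_test(rates[10], weights[10], rates[1], weights[1])
        feature4 = welch.statistic > 0 and welch.p_value < alpha
        p4, t4 = welch.p_value, welch.statistic
    else:
        feature4, p4, t4 = False, float("nan"), float("nan")

    diagnostics = {
        "min_final_fraction_N10": float(finals_10.min() / C),
        "n_delayed_N1": n_delayed,
        "n_slow_N1": n_slow,
        "n_extinct_N1": n_extinct,
        "n_stalled_N1": n_stalled,
        "welch_p_value": p4,
        "welch_statistic": t4,
    }
    return ScanRow(params, feature1, feature2, feature3, feature4, diagnostics)


def run_scan(
    param_rows: tuple[ModelParams, ...] = TABLE3_PARAM_ROWS,
    wells_per_group: int = 20,
    n_replicates: int = 5,
    seed: int | None = None,
    t_end_days: float = 23.0,
    alpha: float = DEFAULT_SCAN_ALPHA,
) -> list[ScanRow]:
    """One majority-vote ScanRow per parameter set.

    Each row gets ``n_replicates`` independent ensembles of
    ``wells_per_group`` wells per seeding group, with per-row seeds
    derived deterministically from ``seed``.
    """
    if not param_rows:
        raise ValueError("no parameter rows supplied")
    root = np.random.SeedSequence(seed)
    row_seeds = root.spawn(len(param_rows))
    results = []
    for params, row_seed in zip(param_rows, row_seeds):
        rep_seeds = row_seed.spawn(n_replicates)
        votes = np.zeros(4, dtype=int)
        rep_diags = []
        for rep_seed in rep_seeds:
            config = ExperimentConfig(
                wells_per_group=wells_per_group,
                t_end_days=t_end_days,
                params=params,
                seed=None,
            )
            exp = generate_growth_experiment(config, rng=np.random.default_rng(rep_seed))
            row = detect_features(exp, alpha=alpha)
            votes += np.array(row.features, dtype=int)
            rep_diags.append(row.diagnostics)
        majority = votes * 2 > n_replicates
        diagnostics = {
            "votes": votes.tolist(),
            "n_replicates": n_replicates,
            "replicates": rep_diags,
        }
        results.append(ScanRow(params, *map(bool, majority), diagnostics))
    return results


def scan_to_dataframe(rows: list[ScanRow]) -> pd.DataFrame:
    """Scan results in the published table's layout."""
    records = []
    for row in rows:
        p = row.params
        records.append(
            {
                "pF": p.pF,
                "pM": p.pM,
                "pS": p.pS,
                "d": p.d,
                "g0": p.g0,
                "r": p.r,
                **{
                    f"feature{i+1}": "Yes" if f else "No"
                    for i, f in enumerate(row.features)
                },
            }
        )
    return pd.DataFrame.from_records(records)
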