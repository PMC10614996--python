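"""Synthetic well-plate experiments.

Generates ensembles with the structure of the wet-lab study the model
describes: plates of microwells seeded with 10, 4 or 1 cell(s), imaged
daily from Day 4 as area units; a reseeding experiment where wells
seeded with 78 cells of one type are watched for the day they exceed
half occupancy, right-censored at Day 20; and the two printed data
tables of the source study as packaged fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .branching import WellState, WellTrajectory, simulate_well
from .metrics import ObservedWell, cells_to_area
from .likelihood import DailyCountSeries
from .params import ModelParams
from .stats import CensoredValue

__all__ = [
    "ExperimentConfig",
    "ReseedingConfig",
    "ReseedingRecord",
    "GrowthExperiment",
    "Table1Fixture",
    "generate_growth_experiment",
    "generate_reseeding_experiment",
    "simulate_count_series",
    "package_fixture_table1",
    "package_fixture_table2",
    "RESEED_CAPACITY",
]

#: carrying capacity of the larger reseeding wells.  The growth
#: experiment ran in 384-well plates (0.084 cm^2, C = 40000 cells); the
#: reseeding experiment ran in 96-well plates (~0.32 cm^2), so the full
#: and half-full cell counts scale by the area ratio (~3.8x).
RESEED_CAPACITY = 152000


@dataclass
class ExperimentConfig:
    """Layout of the seeding-number growth experiment."""

    wells_per_group: int = 80
    groups: tuple[int, ...] = (10, 4, 1)
    t_end_days: float = 23.0
    observe_from_day: float = 4.0
    params: ModelParams = field(default_factory=ModelParams)
    seed: int | None = None
    seed_damage_prob: float = 0.0
    noise_sigma: float = 0.0  # optional multiplicative log-normal area noise

    def __post_init__(self) -> None:
        if self.wells_per_group < 1:
            raise ValueError("wells_per_group must be at least 1")
        if self.observe_from_day >= self.t_end_days:
            raise ValueError("observe_from_day must precede t_end_days")
        if not 0.0 <= self.seed_damage_prob <= 1.0:
            raise ValueError("seed_damage_prob must be a probability")


@dataclass
class ReseedingConfig:
    """Layout of the reseeding (growth-rate inheritance) experiment."""

    wells_per_arm: int = 32
    initial_cells: int = 78
    arm_types: tuple[str, ...] = ("fast", "moderate")
    capacity: int = RESEED_CAPACITY
    half_full_cells: float | None = None  # default: capacity / 2
    t_end_days: float = 20.0
    params: ModelParams = field(default_factory=ModelParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.wells_per_arm < 1 or self.initial_cells < 1:
            raise ValueError("counts must be positive")
        if self.half_full_cells is None:
            self.half_full_cells = self.capacity / 2.0


@dataclass(frozen=True)
class ReseedingRecord:
    """First day a reseeded well exceeded half occupancy."""

    well_id: str
    arm: str
    day: int | None  # None when right-censored at the end of observation
    t_end_days: int

    @property
    def censored(self) -> bool:
        return self.day is None

    def to_censored_value(self) -> CensoredValue:
        if self.censored:
            return CensoredValue("right_censored", self.t_end_days)
        return CensoredValue("exact", self.day)


@dataclass
class GrowthExperiment:
    """Observed wells plus the hidden simulation truth behind them."""

    wells: list[ObservedWell]
    trajectories: list[WellTrajectory]
    config: ExperimentConfig

    def group(self, N0: int) -> list[ObservedWell]:
        return [w for w in self.wells if w.group_N0 == N0]

    def group_trajectories(self, N0: int) -> list[WellTrajectory]:
        return [t for t in self.trajectories if t.N0 == N0]


def generate_growth_experiment(
    config: ExperimentConfig, rng: np.random.Generator | int | None = None
) -> GrowthExperiment:
    """Simulate the full plate and observe it as daily areas.

    Each well runs the branching model with its own child seed; observed
    area is total cells / 500 recorded daily from ``observe_from_day``.
    With probability ``seed_damage_prob`` a single-cell seeding is
    nonviable and the well starts empty.
    """
    seed = config.seed if rng is None else rng
    if isinstance(seed, np.random.Generator):
        root = np.random.SeedSequence(seed.integers(2 ** 31))
    else:
        root = np.random.SeedSequence(seed)
    n_total = len(config.groups) * config.wells_per_group
    children = root.spawn(n_total)
    wells, trajectories = [], []
    i = 0
    for N0 in config.groups:
        for w in range(config.wells_per_group):
            well_rng = np.random.default_rng(children[i])
            i += 1
            well_id = f"N{N0:02d}_w{w:03d}"
            initial = None
            if (
                N0 == 1
                and config.seed_damage_prob > 0.0
                and well_rng.random() < config.seed_damage_prob
            ):
                initial = WellState(0, 0, 0)
            traj = simulate_well(
                N0,
                config.params,
                t_end_days=config.t_end_days,
                rng=well_rng,
                initial_state=initial,
                well_id=well_id,
            )
            obs = ObservedWell.from_trajectory(traj, config.observe_from_day)
            if config.noise_sigma > 0.0:
                noise = np.exp(well_rng.normal(0.0, config.noise_sigma, size=len(obs.areas)))
                obs.areas = obs.areas * noise
            wells.append(obs)
            trajectories.append(traj)
    return GrowthExperiment(wells=wells, trajectories=trajectories, config=config)


def generate_reseeding_experiment(
    config: ReseedingConfig, rng: np.random.Generator | int | None = None
) -> list[ReseedingRecord]:
    """Simulate the reseeding arms and record half-full crossing days.

    Each well starts with ``initial_cells`` of a single stated type in a
    well of ``capacity`` cells, with its own delta draw; the record is
    the first integer day the total reaches ``half_full_cells``, or a
    right-censored record at ``t_end_days``.
    """
    seed = config.seed if rng is None else rng
    if isinstance(seed, np.random.Generator):
        root = np.random.SeedSequence(seed.integers(2 ** 31))
    else:
        root = np.random.SeedSequence(seed)
    params = config.params.replace(C=config.capacity)
    children = root.spawn(len(config.arm_types) * config.wells_per_arm)
    type_index = {"fast": 0, "moderate": 1, "slow": 2}
    records = []
    i = 0
    t_end = int(round(config.t_end_days))
    for arm in config.arm_types:
        counts = [0, 0, 0]
        counts[type_index[arm]] = config.initial_cells
        for w in range(config.wells_per_arm):
            well_rng = np.random.default_rng(children[i])
            i += 1
            traj = simulate_well(
                config.initial_cells,
                params,
                t_end_days=config.t_end_days,
                rng=well_rng,
                initial_state=WellState(*counts),
                well_id=f"{arm}_w{w:03d}",
            )
            days, totals = traj.daily_totals()
            crossed = np.nonzero(totals >= config.half_full_cells)[0]
            day = int(days[crossed[0]]) if crossed.size else None
            records.append(ReseedingRecord(traj.well_id, arm, day, t_end))
    return records


def simulate_count_series(
    n_wells: int,
    params: ModelParams | None = None,
    rng: np.random.Generator | int | None = None,
    max_count: int = 300,
    t_end_days: float = 15.0,
    cell_type: str = "fast",
) -> list[DailyCountSeries]:
    """Daily manual counts of growing single-cell wells of one type.

    Emulates the estimation data: wells seeded with one cell whose
    number is recorded daily while below ``max_count``.  Wells that die
    out or fail to reach ``max_count`` within ``t_end_days`` are
    discarded and resimulated until ``n_wells`` growing wells are
    collected (the tracked wells were chosen as growing ones).
    """
    params = params or ModelParams()
    rng = np.random.default_rng(rng)
    type_index = {"fast": 0, "moderate": 1, "slow": 2}
    counts0 = [0, 0, 0]
    counts0[type_index[cell_type]] = 1
    series: list[DailyCountSeries] = []
    attempts = 0
    while len(series) < n_wells:
        attempts += 1
        if attempts > 100 * n_wells:
            raise RuntimeError("could not collect enough growing wells")
        traj = simulate_well(
            1,
            params,
            t_end_days=t_end_days,
            rng=rng,
            initial_state=WellState(*counts0),
            well_id=f"count_w{len(series):03d}",
        )
        _, totals = traj.daily_totals()
        if np.max(totals) < max_count:
            continue
        kept = []
        for n in totals:
            if n >= max_count:
                break
            if n == 0:
                break
            kept.append(int(n))
        if len(kept) < 2:
            continue
        series.append(DailyCountSeries(traj.well_id, tuple(kept)))
    return series


# ---------------------------------------------------------------------------
# Packaged fixtures: the two data tables printed in the source study.
# ---------------------------------------------------------------------------


def package_fixture_table2() -> tuple[list[CensoredValue], list[CensoredValue]]:
    """Days-to-half-full of the two reseeding arms, verbatim.

    Faster arm: 26 wells at 11 d, 2 at 12, 1 at 13, 2 at 14, 1 at 15.
    Slower arm: 1 at 14, 1 at 15, 25 in the 16-20 d bin, 5 beyond Day 20
    (right-censored).
    """
    faster = (
        [CensoredValue("exact", 11)] * 26
        + [CensoredValue("exact", 12)] * 2
        + [CensoredValue("exact", 13)]
        + [CensoredValue("exact", 14)] * 2
        + [CensoredValue("exact", 15)]
    )
    slower = (
        [CensoredValue("exact", 14), CensoredValue("exact", 15)]
        + [CensoredValue("interval", 16, 20)] * 25
        + [CensoredValue("right_censored", 20)] * 5
    )
    return faster, slower


@dataclass
class Table1Fixture:
    """Growth-pattern bookkeeping of the 80-well single-cell group.

    ``wells`` carries the 23 individually tabulated wells (sparse
    observations at Days 1/8/14/19/23); approximate printed entries
    ("~", "<10") are stored as representative point values, flagged in
    ``approximate``.  ``class_counts`` covers the whole 80-well group
    (the remaining wells all grew normally to saturation).
    """

    wells: list[ObservedWell]
    labels: dict[str, str]
    class_counts: dict[str, int]
    group_size: int
    approximate: bool = True

    @property
    def extinct_fraction(self) -> float:
        return self.class_counts["extinct"] / self.group_size


_TABLE1_DAYS = (1.0, 8.0, 14.0, 19.0, 23.0)

# per-well cell counts at Days 1/8/14/19/23; "~x" entries as x, "<10" as 5
_TABLE1_ROWS: dict[str, tuple[str, tuple[float, ...]]] = {
    **{
        wid: ("extinct", (1, 5, 5, 0, 0))
        for wid in (
            "162", "167", "170", "176", "177", "179", "182",
            "183", "186", "201", "234", "236", "239", "240",
        )
    },
    "165": ("slow_no_exponential", (1, 89, 300, 350, 500)),
    "166": ("slow_no_exponential", (1, 36, 110, 120, 150)),
    "178": ("slow_no_exponential", (1, 43, 140, 170, 200)),
    "211": ("slow_no_exponential", (1, 16, 90, 200, 400)),
    "163": ("delayed_exponential", (1, 12, 130, 300, 5000)),
    "181": ("delayed_exponential", (1, 44, 270, 550, 5500)),
    "193": ("delayed_exponential", (1, 25, 200, 800, 9000)),
    "204": ("delayed_exponential", (1, 21, 100, 600, 6000)),
    "200": ("normal_exponential", (1, 130, 20000, 40000, 40000)),
}


def package_fixture_table1() -> Table1Fixture:
    """The printed per-well populations of the single-cell group."""
    wells, labels = [], {}
    for wid, (label, cells) in _TABLE1_ROWS.items():
        wells.append(
            ObservedWell(
                well_id=wid,
                group_N0=1,
                days=np.array(_TABLE1_DAYS),
                areas=cells_to_area(np.array(cells, dtype=float)),
            )
        )
        labels[wid] = label
    class_counts = {
        "extinct": 14,
        "slow_no_exponential": 4,
        "delayed_exponential": 4,
        "normal_exponential": 58,
    }
    return Table1Fixture(
        wells=wells, labels=labels, class_counts=class_counts, group_size=80
    )
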