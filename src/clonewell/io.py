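"""CSV/JSON readers and writers for the pipeline's tables.

All tables are tidy, comma-separated, UTF-8 with a header row; days are
integer study days and decimals use '.'.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .branching import WellTrajectory
from .likelihood import DailyCountSeries
from .metrics import ObservedWell
from .params import ModelParams
from .stats import CensoredValue
from .synthesis import ReseedingRecord

__all__ = [
    "write_observed_wells",
    "read_observed_wells",
    "write_trajectory",
    "read_trajectory_sidecar",
    "write_count_series",
    "read_count_series",
    "write_reseeding_table",
    "read_reseeding_table",
    "reseeding_records_to_table",
    "write_manifest",
]


def write_observed_wells(wells: list[ObservedWell], path) -> None:
    rows = [
        {"well_id": w.well_id, "group_N0": w.group_N0, "day": d, "area_units": a}
        for w in wells
        for d, a in zip(w.days, w.areas)
    ]
    pd.DataFrame.from_records(rows).to_csv(path, index=False)


def read_observed_wells(path) -> list[ObservedWell]:
    df = pd.read_csv(path)
    required = {"well_id", "group_N0", "day", "area_units"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    wells = []
    for (well_id, n0), sub in df.groupby(["well_id", "group_N0"], sort=False):
        sub = sub.sort_values("day")
        wells.append(
            ObservedWell(
                well_id=str(well_id),
                group_N0=int(n0),
                days=sub["day"].to_numpy(float),
                areas=sub["area_units"].to_numpy(float),
            )
        )
    return wells


def write_trajectory(traj: WellTrajectory, csv_path, sidecar_path=None) -> None:
    """Half-day states as CSV plus a JSON sidecar with params/delta/seed."""
    rows = [
        {
            "well_id": traj.well_id,
            "t_days": s.t_days,
            "F": s.F,
            "M": s.M,
            "S": s.S,
            "N": s.total,
        }
        for s in traj.states
    ]
    pd.DataFrame.from_records(rows).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        sidecar = {
            "well_id": traj.well_id,
            "N0": traj.N0,
            "delta": traj.delta,
            "seed": traj.seed,
            "params": traj.params.to_dict() if traj.params else None,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_trajectory_sidecar(sidecar_path) -> dict:
    data = json.loads(Path(sidecar_path).read_text())
    if data.get("params"):
        data["params"] = ModelParams.from_dict(data["params"])
    return data


def write_count_series(series: list[DailyCountSeries], path) -> None:
    rows = [
        {"well_id": s.well_id, "day": day, "cells": c}
        for s in series
        for day, c in enumerate(s.counts)
    ]
    pd.DataFrame.from_records(rows).to_csv(path, index=False)


def read_count_series(path) -> list[DailyCountSeries]:
    df = pd.read_csv(path)
    out = []
    for well_id, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("day")
        days = sub["day"].to_numpy(int)
        if np.any(np.diff(days) != 1):
            raise ValueError(f"{path}: well {well_id} has non-consecutive days")
        out.append(DailyCountSeries(str(well_id), tuple(sub["cells"].astype(int))))
    return out


def _censored_to_row(value: CensoredValue) -> tuple[int, int | None]:
    if value.kind == "exact":
        return value.low, value.low
    if value.kind == "interval":
        return value.low, value.high
    return value.low, None  # right-censored: empty high


def reseeding_records_to_table(records: list[ReseedingRecord]) -> dict[str, list[CensoredValue]]:
    table: dict[str, list[CensoredValue]] = {}
    for rec in records:
        table.setdefault(rec.arm, []).append(rec.to_censored_value())
    return table


def write_reseeding_table(samples: dict[str, list[CensoredValue]], path) -> None:
    """Columns group, day_low, day_high (empty = right-censored), count."""
    rows = []
    for group, values in samples.items():
        tally: dict[tuple[int, int | None], int] = {}
        for v in values:
            key = _censored_to_row(v)
            tally[key] = tally.get(key, 0) + 1
        for (low, high), count in sorted(tally.items(), key=lambda kv: kv[0][0]):
            rows.append({"group": group, "day_low": low, "day_high": high, "count": count})
    pd.DataFrame.from_records(rows).to_csv(path, index=False)


def read_reseeding_table(path) -> dict[str, list[CensoredValue]]:
    df = pd.read_csv(path)
    out: dict[str, list[CensoredValue]] = {}
    for i, row in df.iterrows():
        try:
            low = int(row["day_low"])
            count = int(row["count"])
            high = None if pd.isna(row["day_high"]) else int(row["day_high"])
        except (KeyError, ValueError) as err:
            raise ValueError(f"{path}: malformed row {i}: {err}") from err
        if high is None:
            value = CensoredValue("right_censored", low)
        elif high == low:
            value = CensoredValue("exact", low)
        else:
            value = CensoredValue("interval", low, high)
        out.setdefault(str(row["group"]), []).extend([value] * count)
    return out


def write_manifest(path, command: str, seed, params: ModelParams | None = None, **extra) -> None:
    """Every run records what produced it: command, seed, params, version."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "params": params.to_dict() if params else None,
        "package_version": __version__,
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
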